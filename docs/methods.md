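# Methods

`myelinpet` asks a single question in silico: can a small lipophilic
molecule that binds myelin basic protein (MBP) make demyelinated multiple-
sclerosis lesions visible on PET as *cold* spots inside hot white matter?
The package chains four models — tissue composition, whole-body
pharmacokinetics, PET image formation, and a detectability statistic — and
this note records what each assumes, which knobs matter, and what the
simulations can and cannot say about real data.

## Tissue composition

Each brain compartment (white matter, gray matter, lesion) is described by
its water fraction, the protein fraction of dry weight, and the MBP content
of total protein.  Derived quantities:

* protein wet fraction = protein dry fraction x (1 - water fraction),
* MBP mg per g wet = MBP mg/g protein x protein wet fraction,
* molar MBP = (mg/g wet) x density / MW, with density fixed at 1 g/mL
  (the published composition numbers are only mutually consistent under
  that assumption) and MW 18.5 kDa for the major human MBP isoform
  (isoforms span 17.2-21 kDa; the MW is an explicit parameter).

Defaults give 1.015e-3 M (WM), 1.345e-4 M (GM) and 3.61e-4 M (lesion);
the WM/GM ratio of ~7.5 falls in the 7-8x band reported for the two
tissues.  Demyelination is modelled as a fold reduction (>= 1) of the
lesion's MBP concentration; bulk protein is also expressed as a molar
concentration of a 50 kDa reference protein to parameterise nonspecific
binding sites.

## Equilibrium binding

Single-site binding L + T <-> LT with the physical root of
LT^2 - (T+L+Kd) LT + TL = 0 evaluated in the cancellation-free form
2TL/(b + sqrt(b^2-4TL)); T/Kd spans up to ~1e6 in this problem, so the
naive quadratic formula loses all precision.  Kinetics are parameterised by
(Kd, kon) with koff = kon x Kd exactly.  The key regime: with target at
1e4-1e5 x Kd and ligand at ~Kd, essentially 100% of the ligand is bound,
and a 10-fold change in target moves the bound fraction by ~1e-5 — which is
why a *weaker* binder discriminates myelin levels better than a stronger
one.

## PBPK model

A deliberately small compartmental structure that still expresses every
mechanism that matters for imaging feasibility: delivery, competition of
binding rates, partitioning, and biliary/renal clearance.

States (amounts, mol): plasma; liver, kidney, rest-of-body (flow-limited);
brain extracellular fluid (ECF); free pools and specifically-bound pools of
white matter, gray matter and lesion; cumulative hepatic and renal
clearance.  The ODE system:

```
plasma:      dA_p/dt  = -sum_t Q_t (fu C_p - C_t/Kp_t) - PS_bbb (fu C_p - C_ecf)
                        - GFR fu C_p
peripheral:  dA_t/dt  = Q_t (fu C_p - C_t/Kp_t)            (t = liver, kidney, rest)
             liver additionally loses CL_int * C_liver/Kp_liver to the hepatic sink
brain ECF:   dA_ecf/dt = PS_bbb (fu C_p - C_ecf) - sum_i PS_i (C_ecf - C_free,i)
region free: dA_i/dt  = PS_i (C_ecf - C_free,i) - v_bind,i
region bound:dB_i/dt  = v_bind,i = kon C_free,i (T_i - B_i/V_i) V_i - koff B_i
```

with C_free,i = A_i / (V_i D_i).  The distribution factor
D_i = 1 + P_i/Kd_ns + s 10^logP (1 - water_i) folds equilibrium
nonspecific protein binding (site concentration P_i from bulk protein,
Kd_ns = 1e-3 M) and lipophilic partitioning into the free pool.  All fluxes
are pairwise antisymmetric, so total mass is conserved to solver tolerance;
every simulation in the test suite checks the residual against 1e-6.

### Lipophilicity

logP enters twice:

1. **Capacity**: the partition term of D_i and of the peripheral Kp values,
   Kp = 1 + (1-water) 10^logP s with s = 1e-3.
2. **Permeability**: the BBB and cell-membrane PS products scale as
   10^(0.5 (logP - 4)).

The permeability route is what reproduces the observed logP dependence of
white-matter/lesion contrast.  Contrast is generated by *differential
washout*: white matter has an enormous binding capacity (T/Kd ~ 1000 at
micromolar affinity) and holds whatever it receives, while a demyelinated
lesion equilibrates down toward its much smaller capacity at a rate
proportional to membrane permeability.  A poorly permeant (low-logP) agent
leaves the lesion still loaded at scan time (ratio near 1); a permeant one
lets the contrast develop.  This makes the 2-h ratio monotone increasing
and saturating in logP, so a drop from logP 4 to 2 costs much more
contrast than a drop from 4 to 3.  A capacity-only logP model cannot
produce this trend: lipid capacity per unit of myelin is larger in lesions
than the MBP ratio, so it dilutes contrast.

The same washout picture explains the affinity results: at Kd = 1e-9 M the
lesion's residual capacity is still so large that nothing leaves on the
2-h timescale and the WM and lesion time-activity curves coincide; at
Kd = 1e-6 M the lesion drains and the curves separate, the more so the
deeper the demyelination, and raising Kd further raises the ratio.

### Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| dose | 1e-9 | mol | administered amount |
| agent MW | 342 | g/mol | BMB-like |
| logP | 4 | - | supported range 2-5 |
| plasma protein binding | 0.10 | fraction | baseline of the sensitivity table |
| liver microsomal CL | 8e-3 | mL/min/mg | scaled by 45 mg protein/g x 1800 g liver |
| Kd | 1e-6 | M | study range 1e-9..1e-6 |
| kon | 5.5e5 | /M/s | koff = kon Kd |
| nonspecific Kd | 1e-3 | M | all tissues |
| plasma volume | 3.0 | L | |
| brain mass | 1400 | g | 42/56/2% WM/GM/lesion split |
| brain ECF volume | 0.20 | L | |
| BBB PS (logP 4) | 3.5e-3 | L/s | x 10^(0.5(logP-4)) |
| cell PS (logP 4) | 0.025 | /s per L tissue | x 10^(0.5(logP-4)) |
| GFR | 0.125/60 | L/s | filters the free fraction |
| solver | LSODA | rtol 1e-8 | output grid 120 s |

The two PS constants are the model's calibration: they are chosen once so
that a mildly demyelinated lesion (target 3.61e-4 M, Kd 1e-6 M, logP 4)
equilibrates on the ~2 h scale — the regime in which all the qualitative
behaviour above appears.  Lesion perfusion equals white-matter perfusion
(MS plaques keep a significant vascular component, so delivery is not the
bottleneck).  The sensitivity table treats the published "log D" row and
the "log P" column header as the same lipophilicity parameter, named logP
throughout.

## Head phantom (synthetic data)

A stand-in for a voxelised anatomical head atlas: an ellipsoidal head with
a cortical gray-matter shell (inner normalised radius 0.80), white-matter
interior, two lateral-ventricle voids, and three gray-matter folds (vertical
sheets at fixed azimuths) reaching into the deep white matter.  Geometry is
defined on the 256 x 256 x 128 reference grid (voxel 1.1 mm, configurable)
and scales to other grids.  The published lesion coordinates are treated as
1-based indices on that grid; the geometry is built so each lands in its
stated placement class — the four interior sites in pure white matter, the
four border sites on a white/gray interface (the folds provide interfaces
away from the shell) — and so WM/GM voxel counts respect the 42/56 brain
mass split within 15%.

Spherical lesions relabel only WM/GM voxels (never background or CSF), so
insertion is a pure relabelling and disjoint insertions commute.  Lesion
diameters are drawn from a log-normal calibrated to the clinical size
survey: P(d < 3.5 mm) = 0.20 and P(d > 9 mm) = 0.20, which pins both
parameters (mu = 1.725, sigma = 0.561 in log-mm) and implies the observed
60% mass in 3.5-9 mm and a ~5.6 mm median.  The functional form is a
choice; only the three bin masses are constrained by data.

What the phantom does *not* emulate: real cortical folding geometry,
heterogeneous myelin density within compartments, irregular lesion shapes,
and partial-volume tissue mixtures.  Detectability numbers computed on it
are therefore cleaner than reality; the package treats scaling laws and
orderings, not absolute SNR values, as the transferable results.

## PET simulation

Per-slice 2D parallel-beam chain (the analysis works on single slices
through the lesion centers):

1. **Forward projection**: line integrals of activity (radon transform,
   180 angles over 180 degrees, bin = pixel), times the attenuation factor
   exp(-integral of mu) along the full line of response (exact for
   coincidence detection), after a 4 mm FWHM Gaussian blur applied in
   projection space as the system resolution model.
2. **Count scaling**: sensitivity x injected dose x positron yield x the
   analytic decay integral of 2^(-t/half-life) over the scan window
   (defaults: 10 mCi, 0.97, 6588 s, 2 h delay, 20 min scan).  Activity
   input is the scan-window mean tissue concentration from the PBPK curve;
   decay and concentration kinetics are treated as separable over the
   window.  The sensitivity constant (2.5e6) targets ~1e6 true counts per
   brain slice per 20-min scan; the absolute count level of a specific
   scanner is not part of the model, so absolute SNR values carry
   order-of-magnitude meaning only.
3. **Scatter + noise**: scatter (and randoms, folded together) contribute
   sf/(1-sf) of the true counts (sf = 0.15), spread uniformly over bins;
   each bin is an independent Poisson draw.  Draws use inverse-CDF sampling
   (u -> Poisson quantile), which leaves the marginals exactly Poisson but
   couples equal-seed runs bin by bin — the common-random-numbers device
   that makes the paired lesion-free/lesion-bearing protocol, and paired
   comparisons across conditions, sharp.
4. **Reconstruction**: filtered back-projection with a Hann-apodised ramp,
   after subtracting the known uniform scatter expectation and correcting
   attenuation per bin; the chain is calibrated so a noiseless uniform disk
   reconstructs to its true level within 5%.

Uniform water-equivalent attenuation (mu = 0.0096/mm) fills the head.  No
detector blocks, dead time, randoms estimation, 3D geometry, or iterative
reconstruction: FBP is sufficient for a statistic built on ROI means.

## Detectability statistic

The lesion ROI is defined on a lesion-only image (activity assigned solely
to lesion voxels, reconstructed noiselessly) by thresholding strictly above

    cutoff = baseline + (max - baseline)/4,

baseline being the whole-image mean — i.e. the 25%-of-peak-height reading.
The published formula can also be read literally as (max - baseline)/4
without the baseline offset; the two coincide when the lesion-only baseline
is ~0, which it is, and the height-anchored reading is the one implemented.
The whole-image mean includes out-of-head pixels, as written.

Scoring uses the negative-contrast statistic SNR = (mu_BGR - mu_LES) /
sigma_BGR with mu_BGR and sigma_BGR from the lesion-free image over the ROI
pixels and mu_LES from the lesion-bearing image over the same pixels.
sigma_BGR is ROI-restricted (consistent with mu_BGR's explicit ROI
restriction; a location-specific noise measure) and uses the sample (n-1)
standard deviation — immaterial at ROI sizes >= 12 px but fixed for
reproducibility.  Feasibility classes: SNR < 1 not imageable, 1-2 maybe,
>= 2 imageable (boundary inclusive); the stricter lower threshold 1.3 is
supported.  ROI inflation (the lesion-localisation experiment) dilates by
whole 8-connected rings and trims the farthest-from-centroid surplus pixels
with a scan-order tie-break, hitting the target area exactly.

## Problem sizes

Default study runs use the 256 x 256 x 128 phantom with 180 projection
angles.  The acquisition-time experiment uses 50 paired noise replicates
per duration; the detectability trend suite uses 8 paired replicates per
condition on the full-resolution grid; sampler calibration uses 1e5 draws;
the Monte-Carlo affinity x concentration sweep defaults to 500 runs (tests
use smaller sweeps since each point is an independent ODE solve).

## Known limitations

* The PBPK structure is a minimal mechanistic model, not a fitted one; its
  sensitivity-coefficient *magnitudes* are model-specific.  Only signs and
  dominance orderings are asserted.
* Separability of decay and tracer kinetics over the scan window slightly
  misweights frames within a scan; at a 1.8 h half-life and 20-min windows
  the error is well below the noise level.
* The lesion-only ROI is defined noiselessly; a clinical workflow would
  localise lesions on coregistered MRI instead, which the statistic's
  thresholds already presuppose.
* Scatter is uniform and randoms are folded into it; no energy windowing.
* One lesion is scored per slice in the bundled experiments; multi-lesion
  slices are supported (each component scored against its own ROI) but the
  published coordinate sets place one lesion per slice pair.
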