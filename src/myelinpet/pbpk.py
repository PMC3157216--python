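"""Whole-body compartmental PBPK model of a myelin-binding PET agent.

The model tracks the agent from an intravenous bolus through a small set of
mechanistically distinct compartments:

* plasma (dose entry, protein binding, renal filtration of the free fraction),
* flow-limited peripheral tissues (liver, kidney, rest of body) exchanging
  with plasma at their blood flows against a partition coefficient,
* a permeability-limited brain block: plasma <-> brain extracellular fluid
  (BBB term) <-> white matter / gray matter / lesion cellular spaces,
* kinetic specific binding to the target (MBP) in each brain region
  (mass action, kon/koff with koff = kon*Kd),
* equilibrium nonspecific binding to bulk tissue protein (Kd_ns, default
  1e-3 M) and lipophilicity-driven partitioning, folded into a per-region
  distribution factor for the free pool,
* hepatic elimination scaled up from the liver microsomal clearance rate and
  renal filtration of free plasma agent (both tracked cumulatively so that
  total mass is conserved exactly up to solver tolerance).

Lipophilicity enters twice: as partitioning capacity
(Kp = 1 + (1 - water_fraction) * 10^logP * s) and as membrane permeability
(the BBB and cell-membrane PS products scale as 10^(gamma*(logP-4))).  The
permeability scaling is what makes white-matter/lesion contrast grow with
logP: a poorly permeant agent leaves the lesion still loaded with what it
received (ratio near 1), while a permeant one lets the lesion wash out
toward its much lower binding capacity.

The ODE system is written with pairwise antisymmetric fluxes, so the sum of
all compartment amounts plus cumulative clearance equals the dose at all
times; :meth:`TimeActivityCurve.mass_balance_residual` checks this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import composition as comp
from .binding import BindingParams

LOG2 = math.log(2.0)

#: Curve compartments reported by :func:`simulate_biodistribution`.
COMPARTMENTS = ("plasma", "liver", "kidney", "rest", "brain_ecf",
                "white_matter", "gray_matter", "lesion")
BRAIN_REGIONS = ("white_matter", "gray_matter", "lesion")


@dataclass(frozen=True)
class AgentProperties:
    """Physicochemical and binding properties of the imaging agent.

    Defaults describe a BMB-like lipophilic myelin binder: MW 342 g/mol,
    logP 4, 10% plasma protein binding, liver microsomal clearance
    8e-3 mL/min/mg, Kd 1e-6 M with kon 5.5e5 /M/s, nonspecific Kd 1e-3 M
    and a 1 nmol administered dose.
    """

    mw: float = 342.0
    logp: float = 4.0
    plasma_protein_bound: float = 0.10
    liver_microsomal_cl: float = 8e-3      # mL/min/mg microsomal protein
    binding: BindingParams | None = field(default_factory=lambda: BindingParams(1e-6, 5.5e5))
    nonspecific_kd: float = 1e-3           # M
    dose_moles: float = 1e-9

    def __post_init__(self) -> None:
        if self.mw <= 0.0:
            raise ValueError("mw must be > 0")
        if not 0.0 <= self.plasma_protein_bound < 1.0:
            raise ValueError("plasma_protein_bound must be in [0, 1)")
        if self.dose_moles < 0.0:
            raise ValueError("dose_moles must be >= 0")
        if self.nonspecific_kd <= 0.0:
            raise ValueError("nonspecific_kd must be > 0")
        if self.liver_microsomal_cl < 0.0:
            raise ValueError("liver_microsomal_cl must be >= 0")


@dataclass(frozen=True)
class BrainRegion:
    name: str
    volume_l: float
    composition: comp.TissueComposition
    target_conc: float          # mol/L
    kp_override: float | None = None

    def __post_init__(self) -> None:
        if self.volume_l <= 0.0:
            raise ValueError("volume must be > 0")
        if self.target_conc < 0.0:
            raise ValueError("target_conc must be >= 0")


@dataclass(frozen=True)
class PeripheralTissue:
    name: str
    volume_l: float
    flow_l_per_s: float
    water_fraction: float = 0.75
    dry_fraction: float = 0.25
    protein_molar: float = 2e-3     # bulk protein as 50 kDa equivalents
    kp_override: float | None = None

    def __post_init__(self) -> None:
        if self.volume_l <= 0.0 or self.flow_l_per_s <= 0.0:
            raise ValueError("volume and flow must be > 0")


@dataclass(frozen=True)
class PhysiologyModel:
    """Compartment volumes, flows and transport/clearance constants."""

    peripherals: tuple[PeripheralTissue, ...]
    regions: tuple[BrainRegion, ...]
    plasma_volume_l: float = 3.0
    brain_ecf_volume_l: float = 0.20
    bbb_ps_l_per_s: float = 3.5e-3        # plasma <-> brain ECF at logP 4
    cell_ps_per_l_tissue: float = 0.025   # ECF <-> cells, 1/s per L at logP 4
    lipophilicity_slope: float = 0.5      # permeability ~ 10^(slope*(logP-4))
    kp_lipid_scale: float = 1e-3          # s in Kp = 1 + (1-water)*10^logP*s
    gfr_l_per_s: float = 0.125 / 60.0
    microsomal_protein_mg_per_g: float = 45.0
    liver_mass_g: float = 1800.0

    def __post_init__(self) -> None:
        if len(self.regions) != 3 or tuple(r.name for r in self.regions) != BRAIN_REGIONS:
            raise ValueError(f"regions must be {BRAIN_REGIONS} in order")
        total = self.plasma_volume_l + self.brain_ecf_volume_l
        if total <= 0.0:
            raise ValueError("volumes must be positive")

    def region(self, name: str) -> BrainRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


def default_physiology(lesion_demyelination_fold: float = 100.0,
                       lesion_target_conc: float | None = None,
                       brain_mass_g: float = 1400.0,
                       kp_override: float | None = None,
                       gfr_l_per_s: float | None = None,
                       **overrides) -> PhysiologyModel:
    """Standard human physiology with the three-region brain block.

    Brain regions take their volumes from the 42/56/2% white/gray/lesion mass
    split of a ``brain_mass_g`` brain at unit density.  The lesion target
    concentration defaults to the normal white-matter MBP level divided by
    ``lesion_demyelination_fold``; pass ``lesion_target_conc`` to set it
    directly (e.g. the 3.61e-4 M of a mildly demyelinated lesion).
    ``kp_override`` forces every partition/distribution factor to the given
    value (used for idealised no-partitioning scenarios).
    """
    wm_conc = comp.molar_target_concentration(comp.WHITE_MATTER)
    gm_conc = comp.molar_target_concentration(comp.GRAY_MATTER)
    if lesion_target_conc is None:
        lesion_target_conc = comp.scaled_lesion_concentration(wm_conc, lesion_demyelination_fold)
    vols = {name: brain_mass_g * frac / 1000.0 for name, frac in comp.BRAIN_MASS_FRACTIONS.items()}
    regions = (
        BrainRegion("white_matter", vols["white_matter"], comp.WHITE_MATTER, wm_conc, kp_override),
        BrainRegion("gray_matter", vols["gray_matter"], comp.GRAY_MATTER, gm_conc, kp_override),
        BrainRegion("lesion", vols["ms_lesion"], comp.MS_LESION, lesion_target_conc, kp_override),
    )
    peripherals = (
        PeripheralTissue("liver", 1.8, 1.45 / 60.0, kp_override=kp_override),
        PeripheralTissue("kidney", 0.31, 1.24 / 60.0, kp_override=kp_override),
        PeripheralTissue("rest", 35.0, 3.0 / 60.0, kp_override=kp_override),
    )
    kwargs = dict(peripherals=peripherals, regions=regions)
    if gfr_l_per_s is not None:
        kwargs["gfr_l_per_s"] = gfr_l_per_s
    kwargs.update(overrides)
    return PhysiologyModel(**kwargs)


@dataclass
class TimeActivityCurve:
    """Per-compartment total agent concentration (and optionally activity) vs time.

    ``conc`` maps compartment name to mol/L (free + specifically bound +
    nonspecifically bound).  ``amounts`` additionally carries per-compartment
    amounts (mol) including the cumulative hepatic/renal clearance sinks, which
    makes mass-balance checks possible.  ``activity`` is filled by
    :func:`activity_weight`.
    """

    times: np.ndarray
    conc: dict[str, np.ndarray]
    amounts: dict[str, np.ndarray]
    dose_moles: float
    activity: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def mass_balance_residual(self) -> float:
        """Max over time of |sum(amounts) - dose| / dose (0 for zero dose)."""
        total = sum(self.amounts.values())
        if self.dose_moles == 0.0:
            return float(np.max(np.abs(total)))
        return float(np.max(np.abs(total - self.dose_moles)) / self.dose_moles)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times}
        for name in self.conc:
            data[f"conc_{name}"] = self.conc[name]
        if self.activity is not None:
            for name in self.activity:
                data[f"activity_{name}"] = self.activity[name]
        return pd.DataFrame(data)


def simulate_biodistribution(phys: PhysiologyModel, agent: AgentProperties,
                             t_end: float = 10800.0, dt_out: float = 120.0) -> TimeActivityCurve:
    """Integrate the PBPK ODE system after an intravenous bolus.

    Output is sampled on a fixed grid of ``dt_out`` seconds (default 120 s,
    the time-activity measurement interval).  Uses a stiff-safe adaptive
    integrator (LSODA, rtol 1e-8); negative states are prevented by the flux
    formulation and asserted post hoc.
    """
    if t_end <= 0 or dt_out <= 0:
        raise ValueError("t_end and dt_out must be > 0")
    perm = 10.0 ** (phys.lipophilicity_slope * (agent.logp - 4.0))
    fu = 1.0 - agent.plasma_protein_bound
    kon = agent.binding.kon if agent.binding is not None else 0.0
    koff = agent.binding.koff if agent.binding is not None else 0.0

    # peripheral partition coefficients
    def peripheral_kp(t: PeripheralTissue) -> float:
        if t.kp_override is not None:
            return t.kp_override
        ns = t.protein_molar / agent.nonspecific_kd
        lipid = phys.kp_lipid_scale * (10.0 ** agent.logp) * t.dry_fraction
        return 1.0 + ns + lipid

    # brain distribution factor of the free pool (free + equilibrium
    # nonspecific + lipid partition per unit free concentration)
    def region_factor(r: BrainRegion) -> float:
        if r.kp_override is not None:
            return r.kp_override
        ns = comp.nonspecific_protein_molar(r.composition) / agent.nonspecific_kd
        lipid = phys.kp_lipid_scale * (10.0 ** agent.logp) * (1.0 - r.composition.water_fraction)
        return 1.0 + ns + lipid

    per = list(phys.peripherals)
    kps = np.array([peripheral_kp(t) for t in per])
    pvols = np.array([t.volume_l for t in per])
    pflows = np.array([t.flow_l_per_s for t in per])
    reg = list(phys.regions)
    rvols = np.array([r.volume_l for r in reg])
    rfac = np.array([region_factor(r) for r in reg])
    rtarget = np.array([r.target_conc for r in reg])
    ps_cell = phys.cell_ps_per_l_tissue * rvols * perm
    ps_bbb = phys.bbb_ps_l_per_s * perm
    # hepatic intrinsic clearance, mL/min -> L/s, acting on free liver conc
    cl_int = (agent.liver_microsomal_cl * phys.microsomal_protein_mg_per_g
              * phys.liver_mass_g) / 1000.0 / 60.0
    vp = phys.plasma_volume_l
    vecf = phys.brain_ecf_volume_l
    liver_kp = kps[0]

    n_per = len(per)
    # state: plasma, peripherals..., ecf, region free pools..., region bound..., cl_hep, cl_ren
    i_ecf = 1 + n_per
    i_free = i_ecf + 1
    i_bound = i_free + 3

    def rhs(t, y):
        dy = np.zeros_like(y)
        cp = y[0] / vp
        ct = y[1 : 1 + n_per] / pvols
        # flow-limited peripheral exchange against free plasma
        jper = pflows * (fu * cp - ct / kps)
        dy[1 : 1 + n_per] += jper
        dy[0] -= jper.sum()
        # BBB exchange
        cecf = y[i_ecf] / vecf
        jbbb = ps_bbb * (fu * cp - cecf)
        dy[i_ecf] += jbbb
        dy[0] -= jbbb
        # ECF <-> brain cells
        cfree = y[i_free : i_free + 3] / (rvols * rfac)
        jcell = ps_cell * (cecf - cfree)
        dy[i_free : i_free + 3] += jcell
        dy[i_ecf] -= jcell.sum()
        # specific binding kinetics
        if kon > 0.0:
            cb = y[i_bound : i_bound + 3] / rvols
            vbind = kon * cfree * (rtarget - cb) * rvols - koff * y[i_bound : i_bound + 3]
            dy[i_free : i_free + 3] -= vbind
            dy[i_bound : i_bound + 3] += vbind
        # hepatic elimination of free liver agent, renal filtration of free plasma
        jhep = cl_int * (ct[0] / liver_kp)
        dy[1] -= jhep
        dy[-2] += jhep
        jren = phys.gfr_l_per_s * fu * cp
        dy[0] -= jren
        dy[-1] += jren
        return dy

    n_state = i_bound + 3 + 2
    y0 = np.zeros(n_state)
    y0[0] = agent.dose_moles
    n_out = int(round(t_end / dt_out))
    t_eval = np.linspace(0.0, n_out * dt_out, n_out + 1)
    if agent.dose_moles == 0.0:
        sol_y = np.zeros((n_state, t_eval.size))
    else:
        sol = solve_ivp(rhs, (0.0, t_eval[-1]), y0, method="LSODA",
                        t_eval=t_eval, rtol=1e-8, atol=1e-16 * max(agent.dose_moles / 1e-9, 1.0))
        if not sol.success:
            raise RuntimeError(f"PBPK integration failed: {sol.message}")
        sol_y = sol.y
    assert sol_y.min() >= -1e-6 * max(agent.dose_moles, 1e-30), "negative state in PBPK solution"
    sol_y = np.clip(sol_y, 0.0, None)

    amounts = {"plasma": sol_y[0]}
    conc = {"plasma": sol_y[0] / vp}
    for k, t in enumerate(per):
        amounts[t.name] = sol_y[1 + k]
        conc[t.name] = sol_y[1 + k] / t.volume_l
    amounts["brain_ecf"] = sol_y[i_ecf]
    conc["brain_ecf"] = sol_y[i_ecf] / vecf
    for k, r in enumerate(reg):
        amounts[r.name] = sol_y[i_free + k] + sol_y[i_bound + k]
        conc[r.name] = amounts[r.name] / r.volume_l
    amounts["cleared_hepatic"] = sol_y[-2]
    amounts["cleared_renal"] = sol_y[-1]
    return TimeActivityCurve(t_eval, conc, amounts, agent.dose_moles)


def concentration_ratio(curve: TimeActivityCurve, num: str, den: str, t: float) -> float:
    """Ratio of total concentrations of two compartments at time ``t``.

    Concentrations are linearly interpolated on the output grid; a zero
    denominator concentration is rejected.
    """
    if not curve.times[0] <= t <= curve.times[-1]:
        raise ValueError(f"t={t} outside curve range")
    cn = float(np.interp(t, curve.times, curve.conc[num]))
    cd = float(np.interp(t, curve.times, curve.conc[den]))
    if cd <= 0.0:
        raise ZeroDivisionError(f"denominator compartment {den!r} has zero concentration at t={t}")
    return cn / cd


def activity_weight(curve: TimeActivityCurve, injected_dose_mci: float = 10.0,
                    half_life_s: float = 6588.0, positron_yield: float = 0.97) -> TimeActivityCurve:
    """Fill the activity channel: concentration scaled to dose and decayed.

    activity(t) = conc(t) * (injected_dose * positron_yield / dose_moles)
                  * 2^(-t / half_life); the decay factor is applied uniformly
    across compartments.  Units are mCi-equivalent activity per litre.
    """
    if half_life_s <= 0.0:
        raise ValueError("half_life must be > 0")
    if not 0.0 <= positron_yield <= 1.0:
        raise ValueError("positron_yield must be in [0, 1]")
    decay = np.exp(-LOG2 * curve.times / half_life_s)
    scale = injected_dose_mci * positron_yield / curve.dose_moles if curve.dose_moles > 0 else 0.0
    activity = {name: c * scale * decay for name, c in curve.conc.items()}
    return TimeActivityCurve(curve.times, curve.conc, curve.amounts, curve.dose_moles, activity)


def mean_scan_concentration(curve: TimeActivityCurve, delay_s: float, duration_s: float) -> dict[str, float]:
    """Per-compartment mean total concentration over the scan window.

    Trapezoidal average of conc(t) for t in [delay, delay + duration]; the
    radioactive-decay weighting over the same window is applied separately by
    the PET count model, which keeps the two factors separable.
    """
    t0, t1 = delay_s, delay_s + duration_s
    if t1 > curve.times[-1]:
        raise ValueError("scan window extends beyond simulated range")
    tgrid = np.linspace(t0, t1, 33)
    out = {}
    for name, c in curve.conc.items():
        vals = np.interp(tgrid, curve.times, c)
        out[name] = float(np.trapezoid(vals, tgrid) / (t1 - t0))
    return out


def agent_with(agent: AgentProperties, **changes) -> AgentProperties:
    """Copy of ``agent`` with the given fields replaced (kd/kon update binding)."""
    kd = changes.pop("kd", None)
    kon = changes.pop("kon", None)
    if kd is not None or kon is not None:
        b = agent.binding or BindingParams(1e-6, 5.5e5)
        changes["binding"] = BindingParams(kd if kd is not None else b.kd,
                                           kon if kon is not None else b.kon)
    return replace(agent, **changes)
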