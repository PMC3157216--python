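"""Synthetic voxel head phantom with demyelinated lesions.

A stand-in for the published Zubal head phantom: an ellipsoidal head with a
cortical gray-matter shell, white-matter interior, ventricle voids and a few
gray-matter folds reaching into the deep white matter.  The geometry is
designed so that the published lesion coordinates (256 x 256 x 128 grid,
1-based indices) land in regions of their stated placement class: the four
"interior" sites deep inside white matter and the four "border" sites on a
white/gray interface.

Spherical lesions of a given diameter (mm) are inserted by relabelling white-
or gray-matter voxels only; lesion labels start at 4 (0 background, 1 other
head tissue, 2 gray matter, 3 white matter).

Lesion diameters are sampled from a log-normal distribution calibrated to
the clinical size survey of MS lesions: 20% below 3.5 mm, 60% in 3.5-9 mm,
20% above 9 mm (median ~5.6 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.stats import norm

BACKGROUND = 0
OTHER = 1
GRAY = 2
WHITE = 3
LESION_BASE = 4

#: Reference grid for which the published lesion coordinates are given.
REFERENCE_SHAPE = (256, 256, 128)
DEFAULT_VOXEL_MM = 1.1

# Geometry of the synthetic head, in voxel units of the reference grid
# (0-based coordinates; scaled for other grids).
_HEAD_CENTER = (127.5, 127.5, 57.0)
_HEAD_AXES = (75.0, 95.0, 52.0)
_BRAIN_CENTER = (127.5, 127.5, 53.0)
_BRAIN_AXES = (62.0, 80.0, 40.0)
_CORTEX_INNER_RADIUS = 0.80  # normalised radius where the GM shell starts
# Lateral-ventricle voids, centers/semi-axes in reference voxels.
_VENTRICLES = (((114.5, 123.5, 51.0), (5.0, 14.0, 8.0)),
               ((140.5, 123.5, 51.0), (5.0, 14.0, 8.0)))
# Gray-matter folds (vertical sheets at fixed azimuth) reaching into deep
# white matter; these create white/gray interfaces away from the shell.
_FOLD_ANGLES_DEG = (48.0, -70.0, 147.0)
_FOLD_HALF_WIDTH = 2.2   # voxels, at reference scale
_FOLD_INNER_RHO = 0.30


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion to insert.

    center : (x, y, z) 0-based voxel indices on the phantom grid
    diameter_mm : sphere diameter in mm, in (0, 20]
    placement_class : "interior_wm" or "wm_gm_border"
    """

    center: tuple[int, int, int]
    diameter_mm: float
    placement_class: str = "interior_wm"

    def __post_init__(self) -> None:
        if not 0.0 <= self.diameter_mm <= 20.0:
            raise ValueError(f"diameter must be in [0, 20] mm, got {self.diameter_mm}")
        if self.placement_class not in ("interior_wm", "wm_gm_border"):
            raise ValueError(f"unknown placement_class {self.placement_class!r}")


@dataclass
class PhantomVolume:
    """3D integer label volume plus isotropic voxel size (mm)."""

    labels: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_MM
    lesions: dict = field(default_factory=dict)  # label id -> LesionSpec

    @property
    def shape(self):
        return self.labels.shape

    def lesion_mask(self, lesion_id: int) -> np.ndarray:
        return self.labels == lesion_id

    def copy(self) -> "PhantomVolume":
        return PhantomVolume(self.labels.copy(), self.voxel_size, dict(self.lesions))


# -- published lesion sites ------------------------------------------------

#: (diameter mm, interior-site xyz, border-site xyz) with 1-based indices on
#: the 256 x 256 x 128 reference grid.
PUBLISHED_LESION_SITES = (
    (4.0, (103, 123, 52), (142, 144, 52)),
    (6.0, (106, 84, 63), (144, 86, 63)),
    (8.0, (110, 105, 45), (139, 140, 45)),
    (10.0, (151, 127, 58), (109, 141, 58)),
)


def reference_lesions(shape=REFERENCE_SHAPE) -> list[LesionSpec]:
    """The eight published lesion sites as LesionSpecs on ``shape``.

    1-based reference coordinates are converted to 0-based indices and scaled
    to the requested grid.
    """
    sx, sy, sz = (shape[i] / REFERENCE_SHAPE[i] for i in range(3))
    specs = []
    for diam, interior, border in PUBLISHED_LESION_SITES:
        for xyz, cls in ((interior, "interior_wm"), (border, "wm_gm_border")):
            center = (
                int(round((xyz[0] - 1) * sx)),
                int(round((xyz[1] - 1) * sy)),
                int(round((xyz[2] - 1) * sz)),
            )
            specs.append(LesionSpec(center, diam, cls))
    return specs


# -- phantom generation ----------------------------------------------------

def _ellipsoid_rho2(x, y, z, center, axes, scale):
    cx, cy, cz = (center[i] * scale[i] for i in range(3))
    ax, ay, az = (axes[i] * scale[i] for i in range(3))
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2


def generate_head_phantom(shape=REFERENCE_SHAPE, voxel_size: float = DEFAULT_VOXEL_MM,
                          seed: int | None = None) -> PhantomVolume:
    """Deterministic synthetic head label volume.

    The geometry is fully deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic generators and reserved for future textured
    variants.  Grids below 64^3 cannot honour the placement classes and are
    rejected.
    """
    if min(shape) < 64:
        raise ValueError(f"grid {shape} too small; need at least 64 per axis")
    scale = tuple(shape[i] / REFERENCE_SHAPE[i] for i in range(3))
    x, y, z = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    x = x.astype(np.float32)
    y = y.astype(np.float32)
    z = z.astype(np.float32)

    labels = np.zeros(shape, dtype=np.int16)
    head = _ellipsoid_rho2(x, y, z, _HEAD_CENTER, _HEAD_AXES, scale) <= 1.0
    labels[head] = OTHER

    rho2 = _ellipsoid_rho2(x, y, z, _BRAIN_CENTER, _BRAIN_AXES, scale)
    brain = rho2 <= 1.0
    shell = brain & (rho2 > _CORTEX_INNER_RADIUS**2)
    interior = brain & ~shell
    labels[shell] = GRAY
    labels[interior] = WHITE

    # gray-matter folds: vertical sheets at fixed azimuth around the brain axis
    dx = x - _BRAIN_CENTER[0] * scale[0]
    dy = y - _BRAIN_CENTER[1] * scale[1]
    r_xy = np.sqrt(dx**2 + dy**2) + 0.0 * z  # broadcast to 3D
    half_w = _FOLD_HALF_WIDTH * 0.5 * (scale[0] + scale[1])
    fold = np.zeros(shape, dtype=bool)
    for ang in _FOLD_ANGLES_DEG:
        ux, uy = math.cos(math.radians(ang)), math.sin(math.radians(ang))
        along = dx * ux + dy * uy
        across = np.abs(-dx * uy + dy * ux) + 0.0 * z
        fold |= (along > 0) & (across <= half_w) & (rho2 >= _FOLD_INNER_RHO**2) & brain
    labels[fold & interior] = GRAY

    # ventricle voids (CSF, labelled as other head tissue)
    for center, axes in _VENTRICLES:
        vent = _ellipsoid_rho2(x, y, z, center, axes, scale) <= 1.0
        labels[vent & brain] = OTHER

    return PhantomVolume(labels, voxel_size)


def insert_spherical_lesion(vol: PhantomVolume, spec: LesionSpec,
                            lesion_id: int | None = None) -> PhantomVolume:
    """Return a new volume with the lesion sphere relabelled.

    Only voxels currently labelled white or gray matter and whose centers lie
    within diameter/2 (mm) of the lesion center are relabelled.  A zero
    diameter is a no-op.  The input volume is not modified.
    """
    cx, cy, cz = spec.center
    if not all(0 <= spec.center[i] < vol.shape[i] for i in range(3)):
        raise ValueError(f"lesion center {spec.center} outside volume {vol.shape}")
    if vol.labels[cx, cy, cz] == BACKGROUND:
        raise ValueError(f"lesion center {spec.center} lies outside the head")
    out = vol.copy()
    if spec.diameter_mm == 0.0:
        return out
    if lesion_id is None:
        lesion_id = max(LESION_BASE - 1, int(out.labels.max())) + 1
    r_vox = spec.diameter_mm / 2.0 / vol.voxel_size
    lo = [max(0, int(math.floor(c - r_vox)) - 1) for c in spec.center]
    hi = [min(vol.shape[i], int(math.ceil(spec.center[i] + r_vox)) + 2) for i in range(3)]
    xs, ys, zs = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    dist2 = (xs - cx) ** 2.0 + (ys - cy) ** 2.0 + (zs - cz) ** 2.0
    sub = out.labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    inside = (dist2 <= r_vox**2) & ((sub == WHITE) | (sub == GRAY))
    sub[inside] = lesion_id
    out.lesions[lesion_id] = spec
    return out


# -- lesion size distribution ----------------------------------------------

# Log-normal calibrated to P(d < 3.5 mm) = 0.20 and P(d > 9 mm) = 0.20; the
# middle 60% mass in [3.5, 9] mm follows by symmetry of the two quantiles.
_Z80 = norm.ppf(0.80)
LESION_LOGNORM_MU = 0.5 * (math.log(3.5) + math.log(9.0))
LESION_LOGNORM_SIGMA = 0.5 * (math.log(9.0) - math.log(3.5)) / _Z80


def sample_lesion_diameters(n: int, seed: int | None = None) -> np.ndarray:
    """Draw ``n`` i.i.d. lesion diameters (mm) from the calibrated log-normal."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(LESION_LOGNORM_MU, LESION_LOGNORM_SIGMA, size=n))


# -- activity assignment ---------------------------------------------------

def assign_activity(vol: PhantomVolume, activity_by_label: dict,
                    lesion_only: bool = False) -> np.ndarray:
    """Voxelwise activity-concentration lookup.

    Labels without an entry default to 0.  In ``lesion_only`` mode all
    non-lesion labels are zeroed regardless of the map, producing the volume
    used to define lesion ROIs.
    """
    for label, act in activity_by_label.items():
        if act < 0.0:
            raise ValueError(f"negative activity {act} for label {label}")
    out = np.zeros(vol.shape, dtype=np.float64)
    for label in np.unique(vol.labels):
        if lesion_only and label < LESION_BASE:
            continue
        out[vol.labels == label] = activity_by_label.get(int(label), 0.0)
    return out


# -- IO --------------------------------------------------------------------

def save_volume(path, array: np.ndarray, voxel_size: float) -> None:
    """Write a label or activity volume as NIfTI with an isotropic affine."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])


def lesions_to_csv(specs: list[LesionSpec], path) -> None:
    """Lesion list as CSV with the published column layout (1-based indices)."""
    rows = [
        {
            "diameter_mm": s.diameter_mm,
            "x": s.center[0] + 1,
            "y": s.center[1] + 1,
            "z": s.center[2] + 1,
            "placement_class": s.placement_class,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def lesions_from_csv(path) -> list[LesionSpec]:
    df = pd.read_csv(path)
    return [
        LesionSpec(
            (int(r.x) - 1, int(r.y) - 1, int(r.z) - 1), float(r.diameter_mm), str(r.placement_class)
        )
        for r in df.itertuples()
    ]
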