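"""Run configuration: a fully serialisable description of a feasibility study.

A study is reproducible from its config plus seed alone; the SHA-256 hash of
the canonical YAML form is recorded in every output for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Everything needed to run a lesion-detectability study.

    Lesion diameters must come from the published site table (4, 6, 8,
    10 mm), since each diameter has fixed interior/border coordinates.
    """

    seed: int = 0
    output_dir: str = "results"
    # phantom
    grid_shape: tuple[int, int, int] = (256, 256, 128)
    voxel_size_mm: float = 1.1
    diameters_mm: list[float] = field(default_factory=lambda: [4.0, 6.0, 8.0, 10.0])
    placements: list[str] = field(default_factory=lambda: ["interior_wm", "wm_gm_border"])
    # agent / physiology
    logp: float = 4.0
    plasma_protein_bound: float = 0.10
    liver_microsomal_cl: float = 8e-3
    kon: float = 5.5e5
    kds: list[float] = field(default_factory=lambda: [1e-9, 1e-6])
    demyelination_folds: list[float] = field(default_factory=lambda: [10.0, 100.0])
    dose_moles: float = 1e-9
    # acquisition
    scan_duration_s: float = 1200.0
    delay_to_scan_s: float = 7200.0
    injected_dose_mci: float = 10.0
    half_life_s: float = 6588.0
    positron_yield: float = 0.97
    scatter_fraction: float = 0.15
    sensitivity: float = 2.5e6
    n_angles: int = 180
    psf_fwhm_mm: float = 4.0
    # analysis
    snr_thresholds: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.snr_thresholds = tuple(float(v) for v in self.snr_thresholds)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(asdict(self)), sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
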