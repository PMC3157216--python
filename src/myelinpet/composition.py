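"""Brain tissue composition and myelin-basic-protein (MBP) target concentrations.

White matter, gray matter and MS lesions are described by their water
fraction, the protein fraction of their dry weight and the MBP content of
their total protein.  From those inputs the module derives the protein wet
fraction and the molar MBP concentration that seed the PBPK physiology.

All internal values are fractions (not percent); percent appears only in the
exported table.  The tissue density defaults to 1 g/mL, which is the
assumption under which mg-per-g-wet converts directly to mg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
import yaml

#: Molecular weight (g/mol) of the major human MBP isoform.  Isoforms span
#: roughly 17.2-21 kDa; pass ``target_mw`` explicitly to use another value.
MBP_MW_DEFAULT = 18_500.0

#: Reference molecular weight (g/mol) used to express bulk tissue protein as a
#: molar concentration of nonspecific binding sites.
NONSPECIFIC_PROTEIN_MW = 50_000.0


@dataclass(frozen=True)
class TissueComposition:
    """Composition of one brain compartment.

    Parameters
    ----------
    name : str
        Compartment label (e.g. ``"white_matter"``).
    water_fraction : float
        Water as a fraction of wet weight, in [0, 1].
    protein_dry_fraction : float
        Total protein as a fraction of dry weight, in [0, 1].
    target_mg_per_g_protein : float
        mg of target (MBP) per g of total protein, >= 0.
    tissue_density : float, optional
        g per mL of wet tissue (default 1.0).
    target_mw : float, optional
        Target molecular weight in g/mol (default 18.5 kDa).
    """

    name: str
    water_fraction: float
    protein_dry_fraction: float
    target_mg_per_g_protein: float
    tissue_density: float = 1.0
    target_mw: float = MBP_MW_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError(f"water_fraction must be in [0, 1], got {self.water_fraction}")
        if not 0.0 <= self.protein_dry_fraction <= 1.0:
            raise ValueError(
                f"protein_dry_fraction must be in [0, 1], got {self.protein_dry_fraction}"
            )
        if self.target_mg_per_g_protein < 0.0:
            raise ValueError("target_mg_per_g_protein must be >= 0")
        if self.target_mw <= 0.0:
            raise ValueError("target_mw must be > 0")
        if self.tissue_density <= 0.0:
            raise ValueError("tissue_density must be > 0")


def protein_wet_fraction(c: TissueComposition) -> float:
    """Total protein as a fraction of wet weight.

    ``protein_dry_fraction * (1 - water_fraction)``; multiply by 100 for the
    percent form.
    """
    return c.protein_dry_fraction * (1.0 - c.water_fraction)


def target_mg_per_g_wet(c: TissueComposition) -> float:
    """mg of target per g of wet tissue (intermediate derivation step)."""
    return c.target_mg_per_g_protein * protein_wet_fraction(c)


def molar_target_concentration(c: TissueComposition) -> float:
    """Molar target (MBP) concentration in mol/L.

    mg/g-wet is converted to g/L via the tissue density (g/mL -> x1000 for
    g/L) and divided by the target molecular weight.
    """
    return target_mg_per_g_wet(c) * c.tissue_density * 1000.0 / c.target_mw / 1000.0


def nonspecific_protein_molar(c: TissueComposition, reference_mw: float = NONSPECIFIC_PROTEIN_MW) -> float:
    """Bulk tissue protein expressed as mol/L of a reference-MW protein.

    Used as the nonspecific binding-site concentration in the PBPK model.
    """
    protein_g_per_l = protein_wet_fraction(c) * c.tissue_density * 1000.0
    return protein_g_per_l / reference_mw


def scaled_lesion_concentration(base: float, fold_reduction: float) -> float:
    """Lesion target concentration after an n-fold demyelination.

    ``fold_reduction`` must be >= 1; 1 is the identity (no myelin loss).
    """
    if fold_reduction < 1.0:
        raise ValueError(f"fold_reduction must be >= 1, got {fold_reduction}")
    return base / fold_reduction


# Default compartments: literature water/protein fractions and radioimmunoassay
# MBP levels for normal white matter, gray matter and a representative MS
# lesion (partial myelin loss relative to white matter).
WHITE_MATTER = TissueComposition("white_matter", 0.72, 0.39, 172.0)
GRAY_MATTER = TissueComposition("gray_matter", 0.82, 0.553, 25.0)
MS_LESION = TissueComposition("ms_lesion", 0.76, 0.317, 87.8)

DEFAULT_COMPOSITIONS = (WHITE_MATTER, GRAY_MATTER, MS_LESION)

#: Mass fraction of total brain occupied by each compartment.
BRAIN_MASS_FRACTIONS = {"white_matter": 0.42, "gray_matter": 0.56, "ms_lesion": 0.02}


def composition_table(comps=DEFAULT_COMPOSITIONS) -> pd.DataFrame:
    """Inputs plus derived rows for each compartment, one column per tissue.

    Mirrors the standard tissue-composition table layout: percent rows for
    display, fractions internally.
    """
    rows = {
        "water_fraction_pct": [100.0 * c.water_fraction for c in comps],
        "protein_dry_pct": [100.0 * c.protein_dry_fraction for c in comps],
        "protein_wet_pct": [100.0 * protein_wet_fraction(c) for c in comps],
        "target_mg_per_g_protein": [c.target_mg_per_g_protein for c in comps],
        "target_mg_per_g_wet": [target_mg_per_g_wet(c) for c in comps],
        "target_molar": [molar_target_concentration(c) for c in comps],
    }
    return pd.DataFrame(rows, index=[c.name for c in comps]).T


def load_compositions(path) -> list[TissueComposition]:
    """Read compartment definitions from a YAML file.

    The file maps compartment names to keyword arguments of
    :class:`TissueComposition`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [TissueComposition(name=name, **fields) for name, fields in raw.items()]


def with_target_mw(c: TissueComposition, target_mw: float) -> TissueComposition:
    """Same composition with a different target isoform molecular weight."""
    return replace(c, target_mw=target_mw)
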