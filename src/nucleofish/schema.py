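"""Allele-table schema shared by the simulator, the pipeline and the stats.

One row per allele.  Distances in micrometres, volumes in cubic
micrometres, 0-based identifiers.
"""

from __future__ import annotations

import pandas as pd

#: Genotype groups.  matrepKO / patrepKO carry the L1-repeat deletion on the
#: maternal / paternal chromosome, so the single remaining probe target is
#: the paternal / maternal allele respectively.  Zfp57KO maternalises the
#: paternal domain; matIGDMRKO paternalises the maternal domain.
GENOTYPES = ("WT", "WT2", "matrepKO", "patrepKO", "Zfp57KO", "matIGDMRKO")

#: Number of DNA-FISH probe targets per nucleus: deletion lines retain a
#: single target, all other lines two.
EXPECTED_ALLELES = {
    "WT": 2,
    "WT2": 2,
    "matrepKO": 1,
    "patrepKO": 1,
    "Zfp57KO": 2,
    "matIGDMRKO": 2,
}

#: Column dictionary of the allele table (pipeline output and simulator).
ALLELE_COLUMNS: dict[str, str] = {
    "cell_id": "unique nucleus identifier",
    "line_id": "biological replicate cell line",
    "genotype": "one of " + ", ".join(GENOTYPES),
    "allele_id": "allele identifier within the cell",
    "distance_um": "signed 3D distance to the nuclear border (um)",
    "local_radius_um": "centroid-to-border ray length through the spot (um)",
    "relative_distance": "distance_um / local_radius_um (unitless)",
    "shell": "equal-volume shell: outer | middle | inner",
    "near_far": "within-cell rank: near | far | single",
    "expressed": "nascent-RNA expression call (bool)",
    "fallback": "True when the ellipsoid-fallback mask was used",
    "volume_um3": "nuclear volume (um^3)",
}

_NUMERIC = ("distance_um", "local_radius_um", "relative_distance", "volume_um3")
_BOOL = ("expressed", "fallback")


def empty_allele_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="float64" if c in _NUMERIC else
                                      "bool" if c in _BOOL else "object")
                         for c in ALLELE_COLUMNS})


def coerce_allele_table(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce column dtypes to the schema (raises on failure)."""
    out = df.copy()
    for c in _NUMERIC:
        out[c] = pd.to_numeric(out[c], errors="raise").astype(float)
    for c in _BOOL:
        if out[c].dtype != bool:
            out[c] = out[c].map(
                {True: True, False: False, "True": True, "False": False,
                 "true": True, "false": False, 1: True, 0: False,
                 "1": True, "0": False}
            )
            if out[c].isna().any():
                raise ValueError(f"column {c!r} is not boolean-coercible")
            out[c] = out[c].astype(bool)
    for c in ("cell_id", "line_id", "genotype", "allele_id", "shell", "near_far"):
        out[c] = out[c].astype(str)
    return out
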