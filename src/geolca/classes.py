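"""Land-use/land-cover class table: per-class ecological and agronomic parameters.

Each row parameterizes one integer class code: carbon density (sum of the
above-ground, below-ground, soil and dead-matter pools, t C/ha), USLE cover
and practice factors, sediment and nitrogen retention efficiencies, baseline
nitrogen load (kg N/ha/yr), crop coefficient Kc for agricultural classes,
land-use mean-species-abundance value MSA_LU, and role flags
(``is_agriculture``, ``is_natural``, ``convertible``).

The shipped default table is an internally consistent, literature-plausible
parameterization used by the synthetic landscapes and the worked examples;
for real analyses every column is expected to be replaced with regionally
sourced values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LulcClassTable", "default_class_table", "CLASS_CODES"]

CLASS_CODES = {
    "agriculture": 1,
    "forest": 2,
    "savanna": 3,
    "grassland": 4,
    "riparian": 5,
    "urban": 6,
    "water": 7,
    "barren": 8,
}

_COLUMNS = [
    "code", "name", "is_agriculture", "is_natural", "convertible",
    "carbon_density", "usle_c", "usle_p",
    "sed_retention_eff", "n_retention_eff", "n_load", "kc", "msa_lu",
]

# code, name, is_ag, is_nat, convertible, C t/ha, usle_c, usle_p,
# sed_ret, n_ret, n_load, kc, msa_lu
_DEFAULT_ROWS = [
    (1, "agriculture", True,  False, False, 55.0, 0.20, 0.90, 0.15, 0.10, 30.0, 1.20, 0.30),
    (2, "forest",      False, True,  True,  280.0, 0.003, 1.0, 0.60, 0.50, 1.5, np.nan, 1.00),
    (3, "savanna",     False, True,  True,  120.0, 0.010, 1.0, 0.45, 0.35, 2.0, np.nan, 0.70),
    (4, "grassland",   False, True,  True,  90.0, 0.020, 1.0, 0.40, 0.30, 4.0, np.nan, 0.70),
    (5, "riparian",    False, True,  True,  200.0, 0.004, 1.0, 0.70, 0.60, 1.5, np.nan, 0.90),
    (6, "urban",       False, False, False, 10.0, 0.010, 1.0, 0.05, 0.02, 8.0, np.nan, 0.05),
    (7, "water",       False, False, False, 0.0, 0.000, 1.0, 0.00, 0.00, 0.0, np.nan, 0.90),
    (8, "barren",      False, False, False, 5.0, 0.300, 1.0, 0.05, 0.02, 1.0, np.nan, 0.60),
]


class LulcClassTable:
    """Per-class parameter table keyed by integer class code."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"class table is missing columns {missing}")
        table = table.copy()
        table["code"] = table["code"].astype(int)
        if table["code"].duplicated().any():
            raise ValueError("duplicate class codes in table")
        for col in ("sed_retention_eff", "n_retention_eff", "usle_c", "usle_p", "msa_lu"):
            vals = table[col].to_numpy(dtype=float)
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError(f"{col} must lie in [0, 1]")
        ag = table[table["is_agriculture"].astype(bool)]
        if ag["kc"].isna().any() or ag["n_load"].isna().any():
            raise ValueError("agriculture classes must define kc and n_load")
        self.table = table.set_index("code", drop=False)

    @property
    def codes(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def codes_where(self, flag: str) -> np.ndarray:
        return self.table.index[self.table[flag].astype(bool)].to_numpy()

    def code_of(self, name: str) -> int:
        hits = self.table.index[self.table["name"] == name]
        if len(hits) != 1:
            raise KeyError(f"class name {name!r} not found")
        return int(hits[0])

    def param(self, code: int, column: str) -> float:
        try:
            return self.table.at[code, column]
        except KeyError:
            raise KeyError(f"unknown class code {code}") from None

    def map_values(self, lulc_codes: np.ndarray, column: str, fill: float = np.nan) -> np.ndarray:
        """Vectorized class-code -> parameter lookup over an integer array.

        Raises on codes absent from the table; nodata/negative codes map to
        ``fill``.
        """
        codes = np.asarray(lulc_codes)
        out = np.full(codes.shape, fill, dtype=float)
        known = np.isin(codes, self.codes)
        present = codes >= 0
        unknown = present & ~known
        if unknown.any():
            bad = np.unique(codes[unknown])
            raise KeyError(f"unknown class code(s) {bad.tolist()} in land-cover grid")
        lut = self.table[column].to_dict()
        for code in np.unique(codes[known]):
            out[codes == code] = lut[int(code)]
        return out

    def mask(self, lulc_codes: np.ndarray, flag: str) -> np.ndarray:
        """Boolean mask of cells whose class has ``flag`` set."""
        codes = np.asarray(lulc_codes)
        flagged = self.codes_where(flag)
        return np.isin(codes, flagged)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.reset_index(drop=True)[_COLUMNS].to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "LulcClassTable":
        return cls(pd.read_csv(path))


def default_class_table(kc_agriculture: float | None = None) -> LulcClassTable:
    """The shipped default parameterization.

    ``kc_agriculture`` overrides the crop coefficient of the agriculture
    class (e.g. 1.20 for a maize-like crop, 1.25 for a sugarcane-like one).
    """
    df = pd.DataFrame(_DEFAULT_ROWS, columns=_COLUMNS)
    if kc_agriculture is not None:
        df.loc[df["is_agriculture"], "kc"] = kc_agriculture
    return LulcClassTable(df)
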