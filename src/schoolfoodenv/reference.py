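"""Published reference counts for Rio de Janeiro schools.

School-level contingency counts from the published ecological tables
for the city of Rio de Janeiro (3,159 public and private schools, 2019
school and establishment registries, 2010 census indicators): for each
inequality stratification, the number of schools per stratum and how
many of them sit in neighborhoods flagged as food deserts, food swamps,
or both simultaneously.

These counts are *inputs*: the tabulation stage recomputes every
prevalence percentage and chi-square p-value from them, which is the
package's regression anchor for the Rio analysis (the underlying
establishment registry itself is not openly deposited).
"""

from __future__ import annotations

import pandas as pd

from .tables import ContingencyTable

__all__ = ["rio_school_flag_counts", "rio_contingency", "RIO_TOTAL_SCHOOLS"]

RIO_TOTAL_SCHOOLS = 3159

# (stratification, stratum, n schools, deserts, swamps, both)
_ROWS = [
    ("sector", "Public", 1737, 295, 1666, 224),
    ("sector", "Private", 1422, 179, 1398, 156),
    ("tercile", "Lowest", 753, 260, 675, 182),
    ("tercile", "Middle", 1135, 104, 1130, 99),
    ("tercile", "Highest", 1271, 110, 1259, 99),
    ("deprivation_cat", "High", 538, 176, 499, 138),
    ("deprivation_cat", "Medium", 2025, 234, 1973, 182),
    ("deprivation_cat", "Low", 596, 64, 592, 60),
    ("segregation_cat", "High", 390, 133, 352, 95),
    ("segregation_cat", "Medium", 1412, 178, 1371, 137),
    ("segregation_cat", "Low", 1357, 163, 1341, 148),
    ("total", "Total", 3159, 474, 3064, 380),
]


def rio_school_flag_counts() -> pd.DataFrame:
    """Tidy frame of the published school counts per stratum and flag."""
    return pd.DataFrame(
        _ROWS,
        columns=["stratification", "stratum", "n_schools", "desert", "swamp",
                 "desert_and_swamp"],
    )


def rio_contingency(stratification: str, flag: str) -> ContingencyTable:
    """Published counts for one stratification/flag as a contingency table."""
    df = rio_school_flag_counts()
    block = df[df["stratification"] == stratification]
    if block.empty:
        raise KeyError(f"unknown stratification {stratification!r}")
    if flag not in ("desert", "swamp", "desert_and_swamp"):
        raise KeyError(f"unknown flag {flag!r}")
    return ContingencyTable(
        rows=block["stratum"].tolist(),
        flagged=block[flag].to_numpy(),
        totals=block["n_schools"].to_numpy(),
    )
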