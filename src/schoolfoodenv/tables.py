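"""Descriptive and inferential tabulation.

The row unit of every cross-tabulation is the school: each school
inherits its neighborhood's income tercile, deprivation and segregation
categories, and desert/swamp flags.  Outputs mirror the shape of the
classic ecological tables:

* sample composition (counts and % of schools per stratum);
* establishment count summaries — median and interquartile range
  (p25-p75, linear interpolation) per subcategory and macro class, per
  school group, plus the share of schools with at least one
  establishment;
* prevalence cross-tabulations of desert/swamp/both flags by stratum,
  with Pearson chi-square tests (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .food import IN_NATURA, MIXED, SUBCATEGORIES, ULTRAPROCESSED

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "build_school_table",
    "summarize_counts",
    "crosstab",
    "chi_square",
    "prevalence_table",
    "format_p",
]

STRATA_COLUMNS = ["sector", "tercile", "deprivation_cat", "segregation_cat"]
FLAG_COLUMNS = ["desert", "swamp", "desert_and_swamp"]


@dataclass
class ContingencyTable:
    """Strata x {flagged, not flagged} school counts."""

    rows: list
    flagged: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.flagged = np.asarray(self.flagged, dtype=int)
        self.totals = np.asarray(self.totals, dtype=int)
        if (self.flagged < 0).any() or (self.flagged > self.totals).any():
            raise ValueError("flagged counts must lie in [0, row total]")

    @property
    def cells(self) -> np.ndarray:
        """r x 2 array of (flagged, not flagged) counts."""
        return np.column_stack([self.flagged, self.totals - self.flagged])

    @property
    def prevalence(self) -> np.ndarray:
        """Percent flagged per stratum, rounded to 1 decimal."""
        return np.round(100.0 * self.flagged / self.totals, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.totals, "flagged": self.flagged, "prevalence_pct": self.prevalence},
            index=pd.Index(self.rows, name="stratum"),
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    def formatted_p(self) -> str:
        return format_p(self.p_value)


def format_p(p: float, decimals: int = 3) -> str:
    """Render a p-value the way epidemiological tables print them:
    3 decimals, with values below 0.0005 shown as ``< 0.001``."""
    floor = 10.0 ** (-decimals)
    if p < floor / 2:
        return f"< {floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


def build_school_table(
    schools: pd.DataFrame,
    neighborhoods: pd.DataFrame,
    metrics: pd.DataFrame,
) -> pd.DataFrame:
    """Join schools to their neighborhood's categories and flags.

    ``neighborhoods`` must be indexed by neighborhood id and carry
    ``tercile``, ``deprivation_cat`` and ``segregation_cat``; ``metrics``
    likewise with ``desert`` and ``swamp``.  Adds the combined
    ``desert_and_swamp`` flag (both at once).
    """
    out = schools.copy()
    cats = neighborhoods[["tercile", "deprivation_cat", "segregation_cat"]]
    flags = metrics[["desert", "swamp"]]
    out = out.join(cats, on="neighborhood_id").join(flags, on="neighborhood_id")
    out["desert_and_swamp"] = out["desert"] & out["swamp"]
    return out


def summarize_counts(
    school_counts: pd.DataFrame, group: pd.Series | None = None
) -> pd.DataFrame:
    """Establishment-count summaries per subcategory and macro class.

    ``school_counts`` has one row per school and one column per
    subcategory (each school's neighborhood counts).  Returns one row
    per subcategory, macro-class total and overall total with the share
    of schools having at least one establishment and, per group (plus
    the full sample), median and p25/p75 with linear interpolation.
    """
    counts = school_counts.copy()
    counts["in_natura_total"] = counts[IN_NATURA].sum(axis=1)
    counts["ultraprocessed_total"] = counts[ULTRAPROCESSED].sum(axis=1)
    counts["mixed_total"] = counts[MIXED].sum(axis=1)
    counts["total"] = counts[SUBCATEGORIES].sum(axis=1)
    order = (
        ["in_natura_total", *IN_NATURA, "ultraprocessed_total", *ULTRAPROCESSED,
         "mixed_total", *MIXED, "total"]
    )

    def _summary(block: pd.DataFrame, label: str) -> pd.DataFrame:
        # (n+1)-position linear interpolation (the convention of classic
        # stats packages' descriptives), unlike the (n-1) rule used for
        # the density/tercile percentiles
        q = np.quantile(block[order].to_numpy(), [0.25, 0.5, 0.75], axis=0,
                        method="weibull")
        return pd.DataFrame({
            f"{label}_median": q[1],
            f"{label}_p25": q[0],
            f"{label}_p75": q[2],
        }, index=order)

    pieces = [
        pd.DataFrame({
            "pct_with_at_least_one": (counts[order] > 0).mean() * 100.0,
            "n_with_at_least_one": (counts[order] > 0).sum(),
        }),
        _summary(counts, "all"),
    ]
    if group is not None:
        for label, block in counts.groupby(group.reindex(counts.index), observed=True):
            if len(block) == 0:
                continue
            pieces.append(_summary(block, str(label)))
    out = pd.concat(pieces, axis=1).loc[order]
    out.index.name = "category"
    return out


def crosstab(schools: pd.DataFrame, stratum: str, flag: str) -> ContingencyTable:
    """School counts of ``flag`` by ``stratum`` with per-stratum prevalence."""
    if schools[stratum].isna().any():
        bad = schools.loc[schools[stratum].isna(), "school_id"].tolist()
        raise ValueError(f"schools missing stratum {stratum!r}: {bad[:5]}")
    g = schools.groupby(stratum, observed=True)[flag]
    totals = g.size()
    flagged = g.sum()
    return ContingencyTable(
        rows=list(totals.index), flagged=flagged.to_numpy(), totals=totals.to_numpy()
    )


def chi_square(table: ContingencyTable | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square on a strata x flag table, no continuity
    correction; errors on zero expected counts (degenerate table)."""
    cells = table.cells if isinstance(table, ContingencyTable) else np.asarray(table)
    if cells.ndim != 2 or cells.shape[0] < 2 or cells.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    n = cells.sum()
    expected = np.outer(cells.sum(axis=1), cells.sum(axis=0)) / n
    if (expected == 0).any():
        raise ValueError("degenerate table: zero expected cell count")
    res = chi2_contingency(cells, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )


def prevalence_table(
    schools: pd.DataFrame,
    strata: list[str] = STRATA_COLUMNS,
    flags: list[str] = FLAG_COLUMNS,
) -> pd.DataFrame:
    """Long-format prevalence table: one row per (stratification,
    stratum, flag) with counts, 1-decimal prevalence and the
    school-level chi-square p for that stratification."""
    rows = []
    for flag in flags:
        for stratum in strata:
            tab = crosstab(schools, stratum, flag)
            # a saturated flag (all schools flagged, or none) has no test
            try:
                p = format_p(chi_square(tab).p_value) if len(tab.rows) > 1 else ""
            except ValueError:
                p = ""
            for label, n, k, prev in zip(tab.rows, tab.totals, tab.flagged, tab.prevalence):
                rows.append({
                    "flag": flag, "stratification": stratum, "stratum": str(label),
                    "n_schools": int(n), "n_flagged": int(k),
                    "prevalence_pct": float(prev), "p_value": p,
                })
        rows.append({
            "flag": flag, "stratification": "total", "stratum": "Total",
            "n_schools": int(len(schools)), "n_flagged": int(schools[flag].sum()),
            "prevalence_pct": float(np.round(100.0 * schools[flag].mean(), 1)),
            "p_value": "",
        })
    return pd.DataFrame(rows)
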