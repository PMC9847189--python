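"""Neighborhood socioeconomic inequality measures.

Three area-level measures, each computed over the full set of
neighborhoods and then inherited by the schools located in them:

* **per-capita income terciles** — total neighborhood income divided by
  population, cut at the empirical 33.3rd/66.7th percentiles;
* **segregation** — the Getis-Ord local Gi* Z-score of the proportion of
  household heads earning 0-3 minimum wages, over first-order rook
  contiguity weights, categorized at the standard-normal cutpoints
  (>= 1.96 High, [0, 1.96) Medium, < 0 Low);
* **deprivation** — the mean of three z-standardized indicators
  (share of households below half a minimum wage, illiteracy at age 7+,
  inadequate sanitation), categorized at the score mean +/- half a
  standard deviation.

Inputs are tidy pandas DataFrames; tract and neighborhood schemas are
documented in :mod:`schoolfoodenv.io`.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .weights import SpatialWeights

__all__ = [
    "aggregate_tracts",
    "income_terciles",
    "gi_star",
    "categorize_segregation",
    "add_segregation",
    "deprivation_scores",
    "SEGREGATION_HIGH_CUT",
    "DEPRIVATION_INDICATORS",
]

SEGREGATION_HIGH_CUT = 1.96

#: neighborhood-level columns holding the three deprivation input shares
DEPRIVATION_INDICATORS = ["dep_below_half_mw", "dep_illiteracy", "dep_sanitation"]

_TRACT_COUNT_COLS = [
    "population",
    "total_income",
    "household_heads_total",
    "household_heads_0_3_mw",
    "households_below_half_mw",
    "persons_7plus",
    "illiterate_7plus",
    "persons_inadequate_sanitation",
]


def aggregate_tracts(tracts: pd.DataFrame) -> pd.DataFrame:
    """Aggregate census tracts to neighborhoods.

    Population and income are summed; the 0-3 minimum-wage head
    proportion is pooled (sum of numerators over sum of denominators);
    the three deprivation indicators are computed per tract and then
    averaged unweighted over the neighborhood's tracts, mirroring how
    tract-level indicator values are carried up to the neighborhood
    unit of analysis.

    Returns a DataFrame indexed by ``neighborhood_id`` with columns
    ``population, total_income, per_capita_income, prop_heads_0_3_mw``
    and the three ``dep_*`` indicator shares.
    """
    missing = [c for c in ["neighborhood_id", *_TRACT_COUNT_COLS] if c not in tracts.columns]
    if missing:
        raise ValueError(f"tract table missing columns: {missing}")
    t = tracts.copy()
    if (t["population"] <= 0).any():
        bad = t.loc[t["population"] <= 0, "tract_id"].tolist()
        raise ValueError(f"tracts with non-positive population: {bad[:5]}")
    for part, total in [
        ("household_heads_0_3_mw", "household_heads_total"),
        ("households_below_half_mw", "household_heads_total"),
        ("illiterate_7plus", "persons_7plus"),
        ("persons_inadequate_sanitation", "population"),
    ]:
        if (t[part] > t[total]).any():
            raise ValueError(f"tract part count {part} exceeds its total {total}")

    t["_below_half"] = t["households_below_half_mw"] / t["household_heads_total"]
    t["_illit"] = t["illiterate_7plus"] / t["persons_7plus"]
    t["_sanit"] = t["persons_inadequate_sanitation"] / t["population"]

    g = t.groupby("neighborhood_id", sort=True)
    out = pd.DataFrame(
        {
            "population": g["population"].sum(),
            "total_income": g["total_income"].sum(),
            "prop_heads_0_3_mw": g["household_heads_0_3_mw"].sum()
            / g["household_heads_total"].sum(),
            "dep_below_half_mw": g["_below_half"].mean(),
            "dep_illiteracy": g["_illit"].mean(),
            "dep_sanitation": g["_sanit"].mean(),
        }
    )
    if (out["population"] <= 0).any():
        raise ValueError("neighborhood with zero population")
    out.insert(2, "per_capita_income", out["total_income"] / out["population"])
    return out


def income_terciles(
    neighborhoods: pd.DataFrame, column: str = "per_capita_income"
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Assign income terciles; returns (frame with ``tercile``, boundaries).

    Boundaries are the empirical 33 1/3 and 66 2/3 percentiles of the
    neighborhood per-capita-income distribution (linear interpolation,
    unweighted).  A value equal to a boundary goes to the lower tercile.
    """
    x = neighborhoods[column].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 neighborhoods for terciles")
    if np.ptp(x) == 0:
        raise ValueError("degenerate distribution: all per-capita incomes identical")
    lo, hi = np.percentile(x, [100 / 3, 200 / 3])
    out = neighborhoods.copy()
    out["tercile"] = np.where(x <= lo, "Lowest", np.where(x <= hi, "Middle", "Highest"))
    out["tercile"] = pd.Categorical(
        out["tercile"], categories=["Lowest", "Middle", "Highest"], ordered=True
    )
    return out, (float(lo), float(hi))


def gi_star(x: Iterable[float], w: SpatialWeights) -> np.ndarray:
    """Getis-Ord local Gi* Z-scores with self-inclusive binary weights.

    For unit i with weights w_ij (w_ii = 1):

        Gi* = (sum_j w_ij x_j - xbar W_i) / (S sqrt[(n S1_i - W_i^2)/(n-1)])

    where xbar and S are the global mean and population standard
    deviation of x, W_i = sum_j w_ij and S1_i = sum_j w_ij^2.  Under
    this standardization each Gi* is an asymptotically standard-normal
    Z-score, which is what the 1.96/0 category cutpoints presume.
    """
    x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if len(x) != w.n:
        raise ValueError(f"length of x ({len(x)}) != number of units ({w.n})")
    n = w.n
    if n < 2:
        raise ValueError("need at least 2 units")
    xbar = x.mean()
    s = x.std(ddof=0)  # population SD, per the Ord-Getis derivation
    if s == 0:
        raise ValueError("zero variance: x is constant across units")
    wmat = w.matrix(include_self=True)
    lag = wmat @ x
    wi = wmat.sum(axis=1)
    s1 = (wmat**2).sum(axis=1)
    denom = s * np.sqrt((n * s1 - wi**2) / (n - 1))
    return (lag - xbar * wi) / denom


def categorize_segregation(
    z, high_cut: float = SEGREGATION_HIGH_CUT, mid_cut: float = 0.0
) -> np.ndarray | str:
    """Map Gi* Z-scores to High (>= high_cut) / Medium ([mid_cut,
    high_cut)) / Low (< mid_cut); defaults are the standard-normal
    1.96/0 cutpoints."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite Gi* Z-score")
    cats = np.where(arr >= high_cut, "High", np.where(arr >= mid_cut, "Medium", "Low"))
    return cats if arr.ndim else str(cats)


def add_segregation(
    neighborhoods: pd.DataFrame,
    w: SpatialWeights,
    column: str = "prop_heads_0_3_mw",
    high_cut: float = SEGREGATION_HIGH_CUT,
    mid_cut: float = 0.0,
) -> pd.DataFrame:
    """Attach ``segregation_z`` and ``segregation_cat`` to neighborhoods.

    The frame must be indexed by neighborhood id; values are aligned to
    the order of ``w.ids``.
    """
    missing = set(w.ids) - set(neighborhoods.index)
    if missing:
        raise ValueError(f"weights reference unknown neighborhoods: {sorted(missing)[:5]}")
    x = neighborhoods.loc[list(w.ids), column]
    z = gi_star(x.to_numpy(), w)
    out = neighborhoods.copy()
    out.loc[list(w.ids), "segregation_z"] = z
    out["segregation_cat"] = pd.Categorical(
        categorize_segregation(out["segregation_z"].to_numpy(), high_cut, mid_cut),
        categories=["Low", "Medium", "High"],
        ordered=True,
    )
    return out


def deprivation_scores(
    neighborhoods: pd.DataFrame,
    indicators: list[str] = DEPRIVATION_INDICATORS,
    half_sd_width: float = 0.5,
    method: str = "z_mean",
) -> pd.DataFrame:
    """Composite deprivation score and High/Medium/Low category.

    ``z_mean`` (the only method implemented; the argument exists so the
    combination rule is an explicit, swappable choice) z-standardizes
    each indicator across neighborhoods using the population SD and
    averages them.  Categories: score above the score mean plus
    ``half_sd_width`` SD -> High, below the mean minus the same -> Low,
    otherwise Medium.
    """
    if method != "z_mean":
        raise ValueError(f"unknown deprivation combination method: {method!r}")
    z_cols = []
    for col in indicators:
        v = neighborhoods[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero variance in indicator {col!r}")
        z_cols.append((v - v.mean()) / sd)
    score = np.mean(z_cols, axis=0)
    mu, sd = score.mean(), score.std(ddof=0)
    hi, lo = mu + half_sd_width * sd, mu - half_sd_width * sd
    out = neighborhoods.copy()
    out["deprivation_score"] = score
    out["deprivation_cat"] = pd.Categorical(
        np.where(score > hi, "High", np.where(score < lo, "Low", "Medium")),
        categories=["Low", "Medium", "High"],
        ordered=True,
    )
    return out
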