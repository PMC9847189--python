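"""Community food-environment classification.

Establishments are mapped from their economic-activity code (CNAE-style)
to one of 13 food-retail subcategories, grouped into three macro
classes following the CAISAN food-desert mapping methodology:

* **in natura** — butcheries, seafood shops, fruit & vegetable markets;
* **ultraprocessed** — street vendors, bars, cafeterias ("lanchonetes",
  i.e. snack bars), convenience stores, candy shops;
* **mixed** — hyper/supermarkets, general food stores, mini markets,
  bakeries, restaurants.

Neighborhood metrics:

* ``healthy_count`` = in natura + mixed;
* ``healthy_density`` = healthy establishments per 10,000 inhabitants;
* **food desert** — healthy density strictly below the city-wide 25th
  percentile of the density distribution;
* **food swamp** — more than four establishments summed over the swamp
  subcategories (default: convenience stores, cafeterias/snack bars,
  mini markets, candy shops);
* **mRFEI** — 100 x healthy / (healthy + ultraprocessed), undefined
  (NaN) when a neighborhood has no establishments in the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryMap",
    "IN_NATURA",
    "ULTRAPROCESSED",
    "MIXED",
    "SUBCATEGORIES",
    "classify_establishments",
    "food_environment_metrics",
    "desert_flags",
    "swamp_flags",
    "mrfei",
]

IN_NATURA = ["butchery", "seafood", "fruits_vegetables"]
ULTRAPROCESSED = ["street_vendor", "bar", "cafeteria", "convenience", "candy"]
MIXED = ["hypermarket_supermarket", "food_store", "mini_market", "bakery", "restaurant"]
SUBCATEGORIES = IN_NATURA + ULTRAPROCESSED + MIXED

_MACRO = {
    **{s: "in_natura" for s in IN_NATURA},
    **{s: "ultraprocessed" for s in ULTRAPROCESSED},
    **{s: "mixed" for s in MIXED},
}

DEFAULT_SWAMP_SUBCATEGORIES = frozenset({"convenience", "cafeteria", "mini_market", "candy"})


@dataclass(frozen=True)
class CategoryMap:
    """Activity-code taxonomy: code prefixes -> subcategory -> macro class.

    Codes are matched by longest prefix; codes matching no prefix are
    counted as ``non_food``.  Registries differ in how they encode
    activities, so the mapping ships as an editable YAML file
    (``data/category_map.yaml``) rather than hard-coded constants.
    """

    code_prefixes: dict = field(default_factory=dict)
    swamp_subcategories: frozenset = DEFAULT_SWAMP_SUBCATEGORIES

    def __post_init__(self) -> None:
        bad = set(self.code_prefixes.values()) - set(SUBCATEGORIES)
        if bad:
            raise ValueError(f"unknown subcategories in code map: {sorted(bad)}")
        extra = set(self.swamp_subcategories) - (set(ULTRAPROCESSED) | set(MIXED))
        if extra:
            raise ValueError(
                f"swamp subcategories must be ultraprocessed or mixed: {sorted(extra)}"
            )

    @staticmethod
    def macro_class(subcategory: str) -> str:
        return _MACRO.get(subcategory, "non_food")

    def subcategory(self, activity_code: str) -> str:
        """Longest-prefix match of an activity code; ``non_food`` if none."""
        code = str(activity_code)
        best = ""
        hit = "non_food"
        for prefix, sub in self.code_prefixes.items():
            if code.startswith(prefix) and len(prefix) > len(best):
                best, hit = prefix, sub
        return hit

    @classmethod
    def default(cls) -> "CategoryMap":
        with resources.files("schoolfoodenv.data").joinpath("category_map.yaml").open() as fh:
            return cls.from_yaml_stream(fh)

    @classmethod
    def from_yaml(cls, path) -> "CategoryMap":
        with open(path) as fh:
            return cls.from_yaml_stream(fh)

    @classmethod
    def from_yaml_stream(cls, stream) -> "CategoryMap":
        raw = yaml.safe_load(stream)
        return cls(
            code_prefixes={str(k): v for k, v in raw["code_prefixes"].items()},
            swamp_subcategories=frozenset(
                raw.get("swamp_subcategories", DEFAULT_SWAMP_SUBCATEGORIES)
            ),
        )


def classify_establishments(
    establishments: pd.DataFrame,
    cmap: CategoryMap,
    neighborhood_ids=None,
) -> pd.DataFrame:
    """Per-neighborhood establishment counts by subcategory.

    Returns a frame indexed by neighborhood id with one integer column
    per subcategory plus ``non_food`` (zeros included for
    neighborhoods/categories with no establishments).  ``neighborhood_ids``
    fixes the output index; otherwise the ids present in the registry
    are used.  Unknown activity codes are logged and counted as
    ``non_food``.
    """
    cols = SUBCATEGORIES + ["non_food"]
    if len(establishments) and establishments["establishment_id"].duplicated().any():
        dups = establishments.loc[
            establishments["establishment_id"].duplicated(), "establishment_id"
        ]
        raise ValueError(f"duplicate establishment ids: {dups.head().tolist()}")
    if len(establishments):
        sub = establishments["activity_code"].map(cmap.subcategory)
        n_unknown = int((sub == "non_food").sum())
        if n_unknown:
            logger.warning("%d establishments with unmapped activity codes", n_unknown)
        counts = (
            pd.crosstab(establishments["neighborhood_id"], sub)
            .reindex(columns=cols, fill_value=0)
        )
    else:
        counts = pd.DataFrame(columns=cols, dtype=int)
    if neighborhood_ids is not None:
        counts = counts.reindex(list(neighborhood_ids), fill_value=0)
    counts.index.name = "neighborhood_id"
    return counts.astype(int)


def food_environment_metrics(
    counts: pd.DataFrame,
    population: pd.Series,
    cmap: CategoryMap | None = None,
    desert_percentile: float = 25.0,
    swamp_threshold: int = 4,
) -> tuple[pd.DataFrame, float]:
    """Assemble the per-neighborhood metrics table and flag deserts/swamps.

    Returns ``(metrics, desert_threshold)`` where metrics carries the
    subcategory counts plus macro-class totals, ``healthy_count``,
    ``healthy_density`` (per 10,000 inhabitants), ``desert``,
    ``swamp_count``, ``swamp`` and ``mrfei``.
    """
    cmap = cmap or CategoryMap.default()
    m = counts.copy()
    pop = population.reindex(m.index)
    if pop.isna().any() or (pop <= 0).any():
        bad = m.index[pop.isna() | (pop <= 0)].tolist()
        raise ValueError(f"missing or non-positive population for neighborhoods: {bad[:5]}")
    m["in_natura_count"] = m[IN_NATURA].sum(axis=1)
    m["ultraprocessed_count"] = m[ULTRAPROCESSED].sum(axis=1)
    m["mixed_count"] = m[MIXED].sum(axis=1)
    m["healthy_count"] = m["in_natura_count"] + m["mixed_count"]
    m["population"] = pop
    m["healthy_density"] = 1e4 * m["healthy_count"] / pop
    m, threshold = desert_flags(m, percentile=desert_percentile)
    m = swamp_flags(m, cmap, threshold=swamp_threshold)
    m["mrfei"] = mrfei(m["healthy_count"], m["ultraprocessed_count"])
    return m, threshold


def desert_flags(
    metrics: pd.DataFrame, percentile: float = 25.0
) -> tuple[pd.DataFrame, float]:
    """Flag food deserts: healthy density strictly below the empirical
    ``percentile`` (linear interpolation) of the city distribution."""
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    dens = metrics["healthy_density"].to_numpy(dtype=float)
    if len(dens) < 4:
        raise ValueError("need at least 4 neighborhoods for the desert percentile")
    if not np.all(np.isfinite(dens)):
        raise ValueError("non-finite healthy densities")
    threshold = float(np.percentile(dens, percentile))
    out = metrics.copy()
    out["desert"] = dens < threshold
    return out, threshold


def swamp_flags(
    metrics: pd.DataFrame, cmap: CategoryMap, threshold: int = 4
) -> pd.DataFrame:
    """Flag food swamps: swamp-subcategory sum strictly greater than
    ``threshold`` (i.e. at least threshold + 1 establishments)."""
    subs = sorted(cmap.swamp_subcategories)
    missing = [s for s in subs if s not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table lacks swamp subcategory counts: {missing}")
    out = metrics.copy()
    out["swamp_count"] = out[subs].sum(axis=1)
    out["swamp"] = out["swamp_count"] > threshold
    return out


def mrfei(healthy: pd.Series, unhealthy: pd.Series) -> pd.Series:
    """Modified Retail Food Environment Index: percentage of healthy
    outlets among healthy + less-healthy outlets; NaN (undefined, not
    zero) where the denominator is empty."""
    denom = healthy + unhealthy
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 100.0 * healthy / denom
    return vals.where(denom > 0)
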