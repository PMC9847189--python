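"""End-to-end pipeline: city -> inequality indices -> food environment
-> school tables.

Stages are plain functions over DataFrames so they compose identically
whether run in one process (:func:`run_all`) or as separate CLI steps
with CSV hand-offs.  All randomness flows from the scenario seed; two
runs of the same configuration produce byte-identical ``results.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import indices, tables
from .food import CategoryMap, SUBCATEGORIES, classify_establishments, food_environment_metrics
from .io import filter_schools, read_city, write_city
from .synthetic import ScenarioConfig, SyntheticCity, generate_city

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "stage_indices", "stage_foodenv", "stage_tabulate"]

CATEGORY_ORDERS = {
    "tercile": ["Lowest", "Middle", "Highest"],
    "deprivation_cat": ["Low", "Medium", "High"],
    "segregation_cat": ["Low", "Medium", "High"],
}


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis in one place."""

    input_dir: str | None = None  # read a city bundle; None -> simulate
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    category_map: str | None = None  # YAML path; None -> packaged default
    desert_percentile: float = 25.0
    swamp_threshold: int = 4
    segregation_high_cut: float = 1.96
    segregation_mid_cut: float = 0.0
    segregation_level: str = "neighborhood"  # or "tract" (majority vote)
    deprivation_half_sd: float = 0.5
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.desert_percentile < 100:
            raise ValueError("desert_percentile must be in (0, 100)")
        if self.segregation_level not in ("neighborhood", "tract"):
            raise ValueError("segregation_level must be 'neighborhood' or 'tract'")

    def load_category_map(self) -> CategoryMap:
        return CategoryMap.from_yaml(self.category_map) if self.category_map else CategoryMap.default()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = ScenarioConfig(**raw.pop("scenario", {}))
        return cls(scenario=scenario, **raw)


def coerce_categories(df: pd.DataFrame) -> pd.DataFrame:
    """Re-impose ordered categorical dtypes after a CSV round trip."""
    out = df.copy()
    for col, order in CATEGORY_ORDERS.items():
        if col in out.columns:
            out[col] = pd.Categorical(out[col], categories=order, ordered=True)
    return out


def stage_indices(city: SyntheticCity, cfg: PipelineConfig) -> pd.DataFrame:
    """Aggregate tracts and attach tercile, segregation and deprivation."""
    neigh = indices.aggregate_tracts(city.tracts)
    neigh, boundaries = indices.income_terciles(neigh)
    if cfg.segregation_level == "tract":
        neigh = _tract_level_segregation(city, neigh, cfg)
    else:
        neigh = indices.add_segregation(
            neigh, city.adjacency,
            high_cut=cfg.segregation_high_cut, mid_cut=cfg.segregation_mid_cut,
        )
    neigh = indices.deprivation_scores(neigh, half_sd_width=cfg.deprivation_half_sd)
    neigh.attrs["tercile_boundaries"] = boundaries
    return neigh


def _tract_level_segregation(
    city: SyntheticCity, neigh: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    """Tract-mode segregation: Gi* on tract adjacency, then each
    neighborhood takes the majority tract category (ties broken by the
    category of the neighborhood's mean tract Z)."""
    if city.tract_adjacency is None:
        raise ValueError("tract-level segregation requires tract adjacency")
    t = city.tracts.set_index("tract_id")
    x = (t["household_heads_0_3_mw"] / t["household_heads_total"]).loc[
        list(city.tract_adjacency.ids)
    ]
    z = indices.gi_star(x.to_numpy(), city.tract_adjacency)
    cats = pd.Series(
        indices.categorize_segregation(z, cfg.segregation_high_cut, cfg.segregation_mid_cut),
        index=x.index,
    )
    zs = pd.Series(z, index=x.index)
    out = neigh.copy()
    out["segregation_z"] = zs.groupby(t["neighborhood_id"]).mean()
    maj = []
    for nb in out.index:
        sub = cats[t["neighborhood_id"] == nb]
        vc = sub.value_counts()
        if len(vc) and (vc == vc.max()).sum() == 1:
            maj.append(vc.idxmax())
        else:  # tie -> categorize the mean tract Z
            maj.append(indices.categorize_segregation(
                float(out.loc[nb, "segregation_z"]),
                cfg.segregation_high_cut, cfg.segregation_mid_cut,
            ))
    out["segregation_cat"] = pd.Categorical(
        maj, categories=["Low", "Medium", "High"], ordered=True
    )
    return out


def stage_foodenv(
    city: SyntheticCity, neigh: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, float]:
    """Classify the registry and flag deserts/swamps."""
    cmap = cfg.load_category_map()
    counts = classify_establishments(city.establishments, cmap, neighborhood_ids=neigh.index)
    return food_environment_metrics(
        counts, neigh["population"], cmap,
        desert_percentile=cfg.desert_percentile, swamp_threshold=cfg.swamp_threshold,
    )


def stage_tabulate(
    city: SyntheticCity, neigh: pd.DataFrame, metrics: pd.DataFrame, cfg: PipelineConfig
) -> dict:
    """Build the school table, apply the sample filter and produce the
    three output tables plus a machine-readable results dict."""
    school_table = tables.build_school_table(city.schools, neigh, metrics)
    school_table, audit = filter_schools(school_table)

    table1 = _composition_table(school_table)
    school_counts = metrics.loc[
        school_table["neighborhood_id"], SUBCATEGORIES
    ].set_axis(school_table.index)
    table2 = tables.summarize_counts(school_counts, group=school_table["sector"])
    table3 = tables.prevalence_table(school_table)

    return {
        "schools": school_table,
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "audit": audit,
    }


def _composition_table(schools: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for stratum in tables.STRATA_COLUMNS:
        vc = schools[stratum].value_counts(sort=False)
        for label, n in vc.items():
            rows.append({
                "stratification": stratum, "stratum": str(label), "n": int(n),
                "pct": round(100.0 * n / len(schools), 1),
            })
    return pd.DataFrame(rows)


def run_all(cfg: PipelineConfig, write: bool = True) -> dict:
    """Execute every stage; optionally write tables under ``cfg.outdir``.

    Returns a dict with the city, indexed neighborhoods, food metrics,
    school table, the three tables and the serializable summary.
    """

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if cfg.input_dir:
        city = _stage("read", read_city, cfg.input_dir)
    else:
        city = _stage("simulate", generate_city, cfg.scenario)
    neigh = _stage("indices", stage_indices, city, cfg)
    metrics, desert_threshold = _stage("foodenv", stage_foodenv, city, neigh, cfg)
    tabs = _stage("tabulate", stage_tabulate, city, neigh, metrics, cfg)

    summary = {
        "config": {
            "desert_percentile": cfg.desert_percentile,
            "swamp_threshold": cfg.swamp_threshold,
            "segregation_cutpoints": [cfg.segregation_high_cut, cfg.segregation_mid_cut],
            "segregation_level": cfg.segregation_level,
            "deprivation_half_sd": cfg.deprivation_half_sd,
            "seed": cfg.scenario.seed if not cfg.input_dir else None,
        },
        "tercile_boundaries": [round(b, 6) for b in neigh.attrs["tercile_boundaries"]],
        "desert_threshold": round(desert_threshold, 6),
        "n_neighborhoods": int(len(neigh)),
        "n_deserts": int(metrics["desert"].sum()),
        "n_swamps": int(metrics["swamp"].sum()),
        "sample_filter": tabs["audit"],
        "table3": tabs["table3"].to_dict(orient="records"),
    }
    out = {"city": city, "neighborhoods": neigh, "metrics": metrics,
           "desert_threshold": desert_threshold, **tabs, "summary": summary}
    if write:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        neigh.to_csv(outdir / "neighborhoods_indexed.csv")
        metrics.to_csv(outdir / "food_environment.csv")
        tabs["table1"].to_csv(outdir / "table1.csv", index=False)
        tabs["table2"].to_csv(outdir / "table2.csv")
        tabs["table3"].to_csv(outdir / "table3.csv", index=False)
        with open(outdir / "results.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("wrote results to %s (desert threshold %.3f)", outdir, desert_threshold)
    return out
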