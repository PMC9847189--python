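"""File I/O: city bundles as plain CSV (plus optional GeoJSON polygons)
and the study-sample school filter.

CSV schemas (synthetic and real data are interchangeable):

* ``tracts.csv`` — tract_id, neighborhood_id, population, total_income,
  household_heads_total, household_heads_0_3_mw,
  households_below_half_mw, persons_7plus, illiterate_7plus,
  persons_inadequate_sanitation
* ``neighborhoods.csv`` — neighborhood_id [, row, col]
* ``adjacency.csv`` — src, dst (both directions required)
* ``establishments.csv`` — establishment_id, neighborhood_id, activity_code
* ``schools.csv`` — school_id, neighborhood_id, sector
  [, professional_only, special_only]
* ``city.geojson`` — optional neighborhood polygons; rook contiguity is
  derived from shared boundary segments of positive length.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from shapely.geometry import shape

from .synthetic import SyntheticCity
from .weights import SpatialWeights, polygon_rook_weights

logger = logging.getLogger(__name__)

__all__ = ["write_city", "read_city", "read_polygon_weights", "filter_schools"]

_TRACT_COLS = [
    "tract_id", "neighborhood_id", "population", "total_income",
    "household_heads_total", "household_heads_0_3_mw", "households_below_half_mw",
    "persons_7plus", "illiterate_7plus", "persons_inadequate_sanitation",
]
_SCHOOL_COLS = ["school_id", "neighborhood_id", "sector"]


def write_city(city: SyntheticCity, outdir) -> Path:
    """Write a city bundle to ``outdir`` as the documented CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    city.tracts.to_csv(outdir / "tracts.csv", index=False)
    city.neighborhoods.to_csv(outdir / "neighborhoods.csv", index=False)
    pd.DataFrame(city.adjacency.edge_list(), columns=["src", "dst"]).to_csv(
        outdir / "adjacency.csv", index=False
    )
    city.establishments.to_csv(outdir / "establishments.csv", index=False)
    city.schools.to_csv(outdir / "schools.csv", index=False)
    if city.tract_adjacency is not None:
        pd.DataFrame(city.tract_adjacency.edge_list(), columns=["src", "dst"]).to_csv(
            outdir / "tract_adjacency.csv", index=False
        )
    return outdir


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing column(s) {missing}")


def read_city(indir) -> SyntheticCity:
    """Read a city bundle; validates schemas and referential integrity.

    Adjacency comes from ``adjacency.csv`` (must contain both directions
    of every edge) or, if absent, from ``city.geojson`` polygons.
    """
    indir = Path(indir)
    tracts = pd.read_csv(indir / "tracts.csv", float_precision="round_trip")
    _require_columns(tracts, _TRACT_COLS, "tracts.csv")
    neighborhoods = pd.read_csv(indir / "neighborhoods.csv")
    _require_columns(neighborhoods, ["neighborhood_id"], "neighborhoods.csv")
    establishments = pd.read_csv(
        indir / "establishments.csv", dtype={"activity_code": str}
    )
    _require_columns(
        establishments, ["establishment_id", "neighborhood_id", "activity_code"],
        "establishments.csv",
    )
    schools = pd.read_csv(indir / "schools.csv")
    _require_columns(schools, _SCHOOL_COLS, "schools.csv")

    nb_ids = neighborhoods["neighborhood_id"].tolist()
    nb_set = set(nb_ids)
    for frame, fname in [(tracts, "tracts.csv"), (establishments, "establishments.csv"),
                         (schools, "schools.csv")]:
        unknown = set(frame["neighborhood_id"]) - nb_set
        if unknown:
            raise ValueError(f"{fname}: unknown neighborhood id(s) {sorted(unknown)[:5]}")

    adj_path = indir / "adjacency.csv"
    if adj_path.exists():
        edges = pd.read_csv(adj_path)
        _require_columns(edges, ["src", "dst"], "adjacency.csv")
        pairs = list(edges.itertuples(index=False, name=None))
        seen = set(pairs)
        missing = [e for e in pairs if (e[1], e[0]) not in seen]
        if missing:
            raise ValueError(
                f"adjacency.csv: asymmetric edge list, missing reverses for {missing[:5]}"
            )
        adjacency = SpatialWeights.from_edges(nb_ids, pairs)
    elif (indir / "city.geojson").exists():
        adjacency = read_polygon_weights(indir / "city.geojson")
        if set(adjacency.ids) != nb_set:
            raise ValueError("city.geojson: polygon ids do not match neighborhoods.csv")
    else:
        raise FileNotFoundError("need adjacency.csv or city.geojson")

    tract_adjacency = None
    t_path = indir / "tract_adjacency.csv"
    if t_path.exists():
        edges = pd.read_csv(t_path)
        tract_adjacency = SpatialWeights.from_edges(
            tracts["tract_id"].tolist(), list(edges.itertuples(index=False, name=None))
        )
    return SyntheticCity(tracts=tracts, neighborhoods=neighborhoods, adjacency=adjacency,
                         establishments=establishments, schools=schools,
                         tract_adjacency=tract_adjacency)


def read_polygon_weights(path) -> SpatialWeights:
    """Rook contiguity from a GeoJSON FeatureCollection.

    Each feature needs an ``id`` or a ``neighborhood_id`` property;
    neighbors are polygons sharing a boundary segment of positive
    length (corner-only contact does not count).
    """
    with open(path) as fh:
        gj = json.load(fh)
    geoms = {}
    for feat in gj["features"]:
        fid = feat.get("id") or feat.get("properties", {}).get("neighborhood_id")
        if fid is None:
            raise ValueError("GeoJSON feature without id or neighborhood_id property")
        geoms[fid] = shape(feat["geometry"])
    return polygon_rook_weights(geoms)


def filter_schools(
    schools: pd.DataFrame, category_columns=("tercile", "deprivation_cat", "segregation_cat")
) -> tuple[pd.DataFrame, dict]:
    """Apply the study-sample exclusions; returns (kept, audit counts).

    Excluded, in order and each school counted once: schools offering
    only professional education, only special education, and schools
    whose neighborhood lacks any of the inherited index categories
    (e.g. missing segregation data).  Flag columns are optional; a
    missing flag column excludes nobody.
    """
    df = schools.copy()
    audit = {"input": int(len(df))}
    for col, reason in [("professional_only", "professional_education"),
                        ("special_only", "special_education")]:
        if col in df.columns:
            mask = df[col].fillna(False).astype(bool)
        else:
            mask = pd.Series(False, index=df.index)
        audit[reason] = int(mask.sum())
        df = df[~mask]
    present = [c for c in category_columns if c in df.columns]
    missing_mask = df[present].isna().any(axis=1) if present else pd.Series(False, index=df.index)
    audit["missing_index_data"] = int(missing_mask.sum())
    df = df[~missing_mask]
    audit["retained"] = int(len(df))
    if len(df) == 0:
        logger.warning("all schools excluded by the sample filter")
    return df.reset_index(drop=True), audit
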