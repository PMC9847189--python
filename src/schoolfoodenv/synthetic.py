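"""Synthetic city generator.

Builds a full synthetic study area — census tracts, neighborhoods on a
rectangular lattice with first-order rook adjacency, a food
establishment registry and a school roster — with controllable planted
structure: a spatial cluster of low-income neighborhoods, cells forced
to be food deserts and cells forced to be food swamps.  Every
downstream stage of the pipeline is testable against what was planted.

Model choices (see docs/methods.md):

* household-head incomes are lognormal per neighborhood; the planted
  share of heads earning 0-3 minimum wages fixes the lognormal location
  analytically, so planted proportions are exact in expectation;
* establishment counts per subcategory are independent Poisson draws
  around configured per-neighborhood rates;
* deprivation indicators (illiteracy, sanitation) rise linearly with
  the neighborhood low-income share plus tract-level noise, so planted
  income clusters are also deprivation clusters;
* a single seed expands into independent substreams per component, so
  e.g. adding schools never perturbs establishment draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .food import IN_NATURA, MIXED, SUBCATEGORIES, ULTRAPROCESSED
from .weights import SpatialWeights, lattice_rook_weights

__all__ = ["ScenarioConfig", "SyntheticCity", "generate_city", "plant_desert_swamp"]

#: default expected establishment counts per neighborhood, by subcategory —
#: round numbers on the scale of a large Brazilian city's neighborhoods
DEFAULT_ESTABLISHMENT_RATES: dict[str, float] = {
    "butchery": 5.0,
    "seafood": 1.0,
    "fruits_vegetables": 3.0,
    "street_vendor": 2.0,
    "bar": 4.0,
    "cafeteria": 20.0,
    "convenience": 0.5,
    "candy": 3.0,
    "hypermarket_supermarket": 8.0,
    "food_store": 6.0,
    "mini_market": 12.0,
    "bakery": 6.0,
    "restaurant": 12.0,
}

#: one representative activity code per subcategory (default code map prefixes)
_REPRESENTATIVE_CODE = {
    "hypermarket_supermarket": "4711301",
    "mini_market": "4712100",
    "bakery": "4721102",
    "candy": "4721104",
    "butchery": "4722101",
    "seafood": "4722200",
    "fruits_vegetables": "4724500",
    "food_store": "4729699",
    "convenience": "4729701",
    "restaurant": "5611201",
    "cafeteria": "5611301",
    "bar": "5611401",
    "street_vendor": "5612100",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic city.

    The income model is parameterized by the planted proportion of
    household heads earning 0-3 minimum wages (the segregation input
    variable) rather than by stratum means: with lognormal incomes of
    scale ``income_sigma``, the location is set per neighborhood so the
    0-3 MW share equals the configured proportion in expectation.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    tracts_per_neighborhood: int = 5
    population_per_tract: float = 1000.0  # Poisson mean, persons
    minimum_wage: float = 510.0  # BRL/month (2010 statutory value)
    income_sigma: float = 0.8  # lognormal scale of head incomes
    background_low_income_prop: float = 0.5
    cluster_low_income_prop: float = 0.85
    low_income_cluster: frozenset = frozenset()  # set of (row, col) cells
    establishment_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ESTABLISHMENT_RATES)
    )
    #: rates used inside the low-income cluster instead of the
    #: background rates (None -> no variation with income stratum)
    cluster_establishment_rates: Mapping[str, float] | None = None
    cell_rate_overrides: Mapping[tuple, Mapping[str, float]] = field(default_factory=dict)
    schools_per_neighborhood: int = 3
    public_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols", "tracts_per_neighborhood",
                     "schools_per_neighborhood"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("population_per_tract", "minimum_wage", "income_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.public_fraction <= 1:
            raise ValueError("public_fraction must be in [0, 1]")
        for name in ("background_low_income_prop", "cluster_low_income_prop"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be strictly inside (0, 1)")
        for cells, name in [
            (self.low_income_cluster, "low_income_cluster"),
            (self.cell_rate_overrides, "cell_rate_overrides"),
        ]:
            for r, c in cells:
                if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                    raise ValueError(f"{name} cell {(r, c)} outside the lattice")
        for label, rates in [("establishment_rates", self.establishment_rates),
                             ("cluster_establishment_rates",
                              self.cluster_establishment_rates or {})]:
            for sub, rate in rates.items():
                if sub not in SUBCATEGORIES:
                    raise ValueError(f"{label}: unknown subcategory {sub!r}")
                if rate < 0:
                    raise ValueError(f"{label}[{sub!r}] must be >= 0")
        for cell, rates in self.cell_rate_overrides.items():
            for sub, rate in rates.items():
                if sub not in SUBCATEGORIES or rate < 0:
                    raise ValueError(f"invalid override {sub!r}={rate} at cell {cell}")

    def rates_for_cell(self, cell: tuple) -> dict[str, float]:
        base = self.establishment_rates
        if self.cluster_establishment_rates is not None and cell in self.low_income_cluster:
            base = self.cluster_establishment_rates
        rates = {s: float(base.get(s, 0.0)) for s in SUBCATEGORIES}
        rates.update({k: float(v) for k, v in self.cell_rate_overrides.get(cell, {}).items()})
        return rates


@dataclass
class SyntheticCity:
    """A generated study area; frames use the CSV schemas of :mod:`.io`."""

    tracts: pd.DataFrame
    neighborhoods: pd.DataFrame
    adjacency: SpatialWeights
    establishments: pd.DataFrame
    schools: pd.DataFrame
    tract_adjacency: SpatialWeights | None = None

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticCity):
            return NotImplemented
        frames = ["tracts", "neighborhoods", "establishments", "schools"]
        return (
            all(getattr(self, f).equals(getattr(other, f)) for f in frames)
            and self.adjacency == other.adjacency
            and self.tract_adjacency == other.tract_adjacency
        )


def _lognormal_mu(low_income_prop: float, minimum_wage: float, sigma: float) -> float:
    # P(X <= 3 MW) = Phi((ln 3MW - mu)/sigma) = p  =>  mu = ln 3MW - sigma Phi^-1(p)
    return float(np.log(3.0 * minimum_wage) - sigma * norm.ppf(low_income_prop))


def generate_city(config: ScenarioConfig) -> SyntheticCity:
    """Generate a synthetic city; deterministic given ``config.seed``."""
    rows, cols, tpn = config.grid_rows, config.grid_cols, config.tracts_per_neighborhood
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_pop, rng_inc, rng_est, rng_sch = (np.random.default_rng(s) for s in streams)

    cells = [(r, c) for r in range(rows) for c in range(cols)]
    nb_ids = [f"N{r}_{c}" for r, c in cells]
    neighborhoods = pd.DataFrame({"neighborhood_id": nb_ids,
                                  "row": [r for r, _ in cells],
                                  "col": [c for _, c in cells]})
    adjacency = lattice_rook_weights(rows, cols)
    # tracts tile each neighborhood cell as a horizontal strip of the fine
    # lattice, so tract-level rook adjacency is exact as well
    tract_adjacency = lattice_rook_weights(
        rows, cols * tpn, id_fn=lambda r, c: f"T{r}_{c // tpn}_{c % tpn}"
    )

    records = []
    for (r, c), nb in zip(cells, nb_ids):
        in_cluster = (r, c) in config.low_income_cluster
        p_low = config.cluster_low_income_prop if in_cluster else config.background_low_income_prop
        mu = _lognormal_mu(p_low, config.minimum_wage, config.income_sigma)
        for k in range(tpn):
            pop = int(max(1, rng_pop.poisson(config.population_per_tract)))
            heads = int(max(1, rng_pop.binomial(pop, 1.0 / 3.0)))
            incomes = rng_inc.lognormal(mu, config.income_sigma, size=heads)
            persons_7plus = int(round(0.9 * pop))
            illit_rate = float(np.clip(0.01 + 0.09 * p_low + rng_pop.normal(0, 0.01), 0, 1))
            san_rate = float(np.clip(0.02 + 0.25 * p_low + rng_pop.normal(0, 0.02), 0, 1))
            records.append({
                "tract_id": f"T{r}_{c}_{k}",
                "neighborhood_id": nb,
                "population": pop,
                "total_income": float(incomes.sum()),
                "household_heads_total": heads,
                "household_heads_0_3_mw": int((incomes <= 3 * config.minimum_wage).sum()),
                "households_below_half_mw": int((incomes <= 0.5 * config.minimum_wage).sum()),
                "persons_7plus": persons_7plus,
                "illiterate_7plus": int(rng_pop.binomial(persons_7plus, illit_rate)),
                "persons_inadequate_sanitation": int(rng_pop.binomial(pop, san_rate)),
            })
    tracts = pd.DataFrame.from_records(records)

    est_records = []
    for (r, c), nb in zip(cells, nb_ids):
        rates = config.rates_for_cell((r, c))
        for sub in SUBCATEGORIES:
            n = int(rng_est.poisson(rates[sub])) if rates[sub] > 0 else 0
            for k in range(n):
                est_records.append({
                    "establishment_id": f"E{nb}_{sub}_{k}",
                    "neighborhood_id": nb,
                    "activity_code": _REPRESENTATIVE_CODE[sub],
                })
    establishments = pd.DataFrame.from_records(
        est_records, columns=["establishment_id", "neighborhood_id", "activity_code"]
    )

    sch_records = []
    for nb in nb_ids:
        for k in range(config.schools_per_neighborhood):
            public = rng_sch.random() < config.public_fraction
            sch_records.append({
                "school_id": f"S{nb}_{k}",
                "neighborhood_id": nb,
                "sector": "Public" if public else "Private",
                "professional_only": False,
                "special_only": False,
            })
    schools = pd.DataFrame.from_records(sch_records)

    return SyntheticCity(tracts=tracts, neighborhoods=neighborhoods, adjacency=adjacency,
                         establishments=establishments, schools=schools,
                         tract_adjacency=tract_adjacency)


def plant_desert_swamp(
    config: ScenarioConfig,
    desert_cells: frozenset | set = frozenset(),
    swamp_cells: frozenset | set = frozenset(),
    healthy_scale: float = 0.0,
    swamp_rate: float = 12.0,
) -> ScenarioConfig:
    """Return a config with cells forced toward desert/swamp status.

    Desert cells have all healthy (in natura + mixed) subcategory rates
    multiplied by ``healthy_scale`` (default 0, an establishment-free
    healthy sector).  Swamp cells have their ultraprocessed swamp
    subcategories (convenience, cafeteria, candy) rescaled to sum to
    ``swamp_rate`` expected establishments; mixed-class swamp
    subcategories are left untouched so a cell planted as both desert
    and swamp stays healthy-poor.  With no cells given, the config is
    returned unchanged.
    """
    if healthy_scale < 0 or swamp_rate < 0:
        raise ValueError("healthy_scale and swamp_rate must be >= 0")
    for cell in list(desert_cells) + list(swamp_cells):
        r, c = cell
        if not (0 <= r < config.grid_rows and 0 <= c < config.grid_cols):
            raise ValueError(f"planted cell {cell} outside the lattice")
    if not desert_cells and not swamp_cells:
        return config
    overrides = {k: dict(v) for k, v in config.cell_rate_overrides.items()}
    healthy_subs = IN_NATURA + MIXED
    up_swamp = [s for s in ("convenience", "cafeteria", "candy") if s in ULTRAPROCESSED]
    for cell in desert_cells:
        ov = overrides.setdefault(tuple(cell), {})
        cell_rates = config.rates_for_cell(tuple(cell))
        for sub in healthy_subs:
            ov[sub] = ov.get(sub, cell_rates[sub]) * healthy_scale
    for cell in swamp_cells:
        ov = overrides.setdefault(tuple(cell), {})
        cell_rates = config.rates_for_cell(tuple(cell))
        base = {s: ov.get(s, cell_rates[s]) for s in up_swamp}
        total = sum(base.values())
        if total > 0:
            for s in up_swamp:
                ov[s] = swamp_rate * base[s] / total
        else:
            ov["cafeteria"] = swamp_rate
    return replace(config, cell_rate_overrides=overrides)
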