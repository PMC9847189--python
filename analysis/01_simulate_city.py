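"""Generate the synthetic study city.

A 10x10 neighborhood lattice with a central 3x3 low-income cluster
(0-3 minimum-wage head share 0.85 vs 0.5 background), two cells planted
as food deserts (healthy rates zeroed) and one as an extreme food
swamp, written as a CSV bundle under results/synthetic_city/.
"""

import sys

from schoolfoodenv.io import write_city
from schoolfoodenv.synthetic import ScenarioConfig, generate_city, plant_desert_swamp

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260925

CLUSTER = frozenset((r, c) for r in range(3, 6) for c in range(3, 6))
DESERT_CELLS = {(0, 0), (0, 1)}
SWAMP_CELLS = {(9, 9)}

# the low-income cluster has fewer establishments of every kind, the
# usual pattern in deprived areas of large Brazilian cities
CLUSTER_RATES = {
    "butchery": 2.0, "seafood": 0.3, "fruits_vegetables": 1.0,
    "street_vendor": 2.0, "bar": 3.0, "cafeteria": 3.0,
    "convenience": 0.1, "candy": 0.8,
    "hypermarket_supermarket": 2.0, "food_store": 1.5, "mini_market": 2.5,
    "bakery": 2.0, "restaurant": 3.0,
}


def scenario(seed: int = SEED) -> ScenarioConfig:
    cfg = ScenarioConfig(low_income_cluster=CLUSTER,
                         cluster_establishment_rates=CLUSTER_RATES, seed=seed)
    return plant_desert_swamp(cfg, desert_cells=DESERT_CELLS, swamp_cells=SWAMP_CELLS,
                              swamp_rate=30.0)


def main() -> None:
    cfg = scenario()
    city = generate_city(cfg)
    outdir = write_city(city, "results/synthetic_city")
    print(f"seed {cfg.seed}: {len(city.neighborhoods)} neighborhoods, "
          f"{len(city.tracts)} tracts, {len(city.establishments)} establishments, "
          f"{len(city.schools)} schools -> {outdir}/")
    print(f"planted: low-income cluster {sorted(CLUSTER)[:3]}..., "
          f"deserts {sorted(DESERT_CELLS)}, swamp {sorted(SWAMP_CELLS)}")


if __name__ == "__main__":
    main()
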