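"""Classify the establishment registry and flag food deserts/swamps.

Reads results/synthetic_city/ and results/neighborhoods_indexed.csv,
writes results/food_environment.csv, and reports the desert threshold
plus whether the planted desert/swamp cells were recovered.
"""

import pandas as pd

from schoolfoodenv.io import read_city
from schoolfoodenv.pipeline import PipelineConfig, coerce_categories, stage_foodenv


def main() -> None:
    city = read_city("results/synthetic_city")
    neigh = coerce_categories(
        pd.read_csv("results/neighborhoods_indexed.csv", index_col="neighborhood_id")
    )
    metrics, threshold = stage_foodenv(city, neigh, PipelineConfig())
    metrics.to_csv("results/food_environment.csv")

    n = len(metrics)
    print(f"desert threshold (25th pct of healthy density): "
          f"{threshold:.2f} per 10,000 inhabitants")
    print(f"{int(metrics['desert'].sum())}/{n} deserts, "
          f"{int(metrics['swamp'].sum())}/{n} swamps")
    for nb in ("N0_0", "N0_1"):
        row = metrics.loc[nb]
        print(f"planted desert {nb}: density {row['healthy_density']:.2f}, "
              f"desert={bool(row['desert'])}")
    row = metrics.loc["N9_9"]
    print(f"planted swamp N9_9: swamp count {int(row['swamp_count'])}, "
          f"swamp={bool(row['swamp'])}, mRFEI {row['mrfei']:.1f}%")


if __name__ == "__main__":
    main()
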