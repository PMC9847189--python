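"""Inequality indices: aggregation, terciles, Gi* (against a
brute-force oracle), segregation categories, deprivation."""

import math

import numpy as np
import pandas as pd
import pytest

from schoolfoodenv.indices import (
    add_segregation,
    aggregate_tracts,
    categorize_segregation,
    deprivation_scores,
    gi_star,
    income_terciles,
)
from schoolfoodenv.weights import SpatialWeights, lattice_rook_weights


def gi_star_bruteforce(x, w):
    """Independent scalar evaluation of the self-inclusive Gi* formula:

        (sum_j w_ij x_j - xbar W_i) / (S sqrt[(n S1_i - W_i^2)/(n-1)])

    with binary weights, w_ii = 1, and X bar / S the global mean and
    population standard deviation.  Deliberately written as plain loops.
    """
    ids = list(w.ids)
    n = len(ids)
    xmap = dict(zip(ids, x))
    xbar = sum(x) / n
    s = math.sqrt(sum((v - xbar) ** 2 for v in x) / n)
    out = []
    for i in ids:
        js = set(w.neighbors[i]) | {i}
        lag = sum(xmap[j] for j in js)
        wi = float(len(js))
        s1 = float(len(js))  # binary weights: sum of squares == sum
        denom = s * math.sqrt((n * s1 - wi**2) / (n - 1))
        out.append((lag - xbar * wi) / denom)
    return np.array(out)


def _tract(tid, nb, pop, income, heads, heads03, below_half, p7, illit, san):
    return {
        "tract_id": tid, "neighborhood_id": nb, "population": pop,
        "total_income": income, "household_heads_total": heads,
        "household_heads_0_3_mw": heads03, "households_below_half_mw": below_half,
        "persons_7plus": p7, "illiterate_7plus": illit,
        "persons_inadequate_sanitation": san,
    }


class TestAggregation:
    def test_identical_tracts_per_capita_income(self):
        tracts = pd.DataFrame([
            _tract("t1", "A", 100, 50_000.0, 30, 10, 5, 90, 5, 10),
            _tract("t2", "A", 100, 50_000.0, 30, 10, 5, 90, 5, 10),
        ])
        neigh = aggregate_tracts(tracts)
        assert neigh.loc["A", "per_capita_income"] == pytest.approx(500.0)

    def test_deprivation_input_is_tract_average(self):
        # below-half-MW shares 0.2 and 0.4 -> unweighted mean 0.3
        tracts = pd.DataFrame([
            _tract("t1", "A", 100, 1.0, 50, 0, 10, 90, 0, 0),
            _tract("t2", "A", 100, 1.0, 50, 0, 20, 90, 0, 0),
        ])
        assert aggregate_tracts(tracts).loc["A", "dep_below_half_mw"] == pytest.approx(0.3)

    def test_heads_proportion_is_pooled_not_averaged(self):
        # (10/50, 20/50, 0/100) pooled -> 30/200 = 0.15 (tract mean would be 0.2)
        tracts = pd.DataFrame([
            _tract("t1", "A", 100, 1.0, 50, 10, 0, 90, 0, 0),
            _tract("t2", "A", 100, 1.0, 50, 20, 0, 90, 0, 0),
            _tract("t3", "A", 100, 1.0, 100, 0, 0, 90, 0, 0),
        ])
        assert aggregate_tracts(tracts).loc["A", "prop_heads_0_3_mw"] == pytest.approx(0.15)

    def test_part_exceeding_total_rejected(self):
        tracts = pd.DataFrame([_tract("t1", "A", 100, 1.0, 50, 60, 0, 90, 0, 0)])
        with pytest.raises(ValueError, match="exceeds"):
            aggregate_tracts(tracts)

    def test_zero_population_rejected(self):
        tracts = pd.DataFrame([_tract("t1", "A", 0, 1.0, 10, 0, 0, 0, 0, 0)])
        with pytest.raises(ValueError, match="population"):
            aggregate_tracts(tracts)


class TestTerciles:
    @staticmethod
    def _frame(values):
        return pd.DataFrame({"per_capita_income": values},
                            index=[f"n{i}" for i in range(len(values))])

    def test_balanced_split_one_to_nine(self):
        out, (lo, hi) = income_terciles(self._frame(range(1, 10)))
        groups = out.groupby("tercile", observed=True).groups
        assert sorted(out.loc[groups["Lowest"], "per_capita_income"]) == [1, 2, 3]
        assert sorted(out.loc[groups["Middle"], "per_capita_income"]) == [4, 5, 6]
        assert sorted(out.loc[groups["Highest"], "per_capita_income"]) == [7, 8, 9]

    def test_boundary_tie_goes_to_lower_tercile(self):
        values = [1.0, 2.0, 2.0, 2.0, 3.0, 4.0]
        out, (lo, hi) = income_terciles(self._frame(values))
        at_boundary = out["per_capita_income"] == lo
        assert (out.loc[at_boundary, "tercile"] == "Lowest").all()

    def test_continuous_sample_splits_in_thirds(self):
        rng = np.random.default_rng(3)
        out, _ = income_terciles(self._frame(rng.lognormal(6, 1, 300)))
        counts = out["tercile"].value_counts()
        assert counts.max() - counts.min() <= 1  # no ties in a continuous draw

    def test_constant_incomes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            income_terciles(self._frame([5.0] * 6))


class TestGiStar:
    def test_matches_bruteforce_on_3x3_spike(self):
        w = lattice_rook_weights(3, 3)
        x = np.array([1.0] + [0.0] * 8)
        np.testing.assert_allclose(gi_star(x, w), gi_star_bruteforce(x, w), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_6x6(self, seed):
        w = lattice_rook_weights(6, 6)
        x = np.random.default_rng(seed).normal(size=36)
        np.testing.assert_allclose(gi_star(x, w), gi_star_bruteforce(x, w), atol=1e-8)

    def test_isolated_spike_is_positive_maximum(self):
        # one unit with no neighbors carrying the only spike
        ids = ["iso", "a", "b", "c"]
        w = SpatialWeights.from_edges(ids, [("a", "b"), ("b", "c")])
        z = gi_star([5.0, 1.0, 1.0, 1.0], w)
        assert z[0] > 0
        assert z[0] == max(z)

    def test_cluster_center_hot_far_corner_cold(self):
        w = lattice_rook_weights(5, 5)
        x = np.array([
            1.0 if (1 <= r <= 3 and 1 <= c <= 3) else 0.0
            for r in range(5) for c in range(5)
        ])
        z = gi_star(x, w)
        center = w.ids.index("N2_2")
        corner = w.ids.index("N4_4")
        np.testing.assert_allclose(z, gi_star_bruteforce(x, w), atol=1e-10)
        assert z[center] > 1.96
        assert z[corner] < 0

    def test_torus_numerator_sums_to_zero(self):
        """With equal W_i everywhere (torus) the Gi* numerators cancel."""
        w = lattice_rook_weights(4, 4, torus=True)
        x = np.random.default_rng(0).normal(size=16)
        wmat = w.matrix(include_self=True)
        numerators = wmat @ x - x.mean() * wmat.sum(axis=1)
        assert abs(numerators.sum()) < 1e-10

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            gi_star([2.0] * 9, lattice_rook_weights(3, 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            gi_star([1.0, 2.0], lattice_rook_weights(3, 3))

    def test_shuffling_destroys_planted_cluster(self):
        """Permutation sanity: after shuffling x, High categorizations at
        the planted cluster occur at about the global base rate."""
        w = lattice_rook_weights(5, 5)
        x = np.array([
            1.0 if (1 <= r <= 3 and 1 <= c <= 3) else 0.0
            for r in range(5) for c in range(5)
        ])
        cluster_idx = [w.ids.index(f"N{r}_{c}") for r in range(1, 4) for c in range(1, 4)]
        rng = np.random.default_rng(11)
        cluster_high, global_high = [], []
        for _ in range(100):
            xs = rng.permutation(x)
            high = gi_star(xs, w) >= 1.96
            cluster_high.append(high[cluster_idx].mean())
            global_high.append(high.mean())
        assert abs(np.mean(cluster_high) - np.mean(global_high)) < 0.05


class TestSegregationCategories:
    @pytest.mark.parametrize("z, cat", [
        (1.96, "High"), (5.0, "High"), (0.0, "Medium"), (1.95, "Medium"),
        (-0.01, "Low"), (-3.0, "Low"),
    ])
    def test_cutpoints(self, z, cat):
        assert categorize_segregation(z) == cat

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            categorize_segregation(float("nan"))

    def test_add_segregation_attaches_columns(self, small_city):
        neigh = aggregate_tracts(small_city.tracts)
        out = add_segregation(neigh, small_city.adjacency)
        assert {"segregation_z", "segregation_cat"} <= set(out.columns)
        assert out["segregation_cat"].notna().all()


class TestDeprivation:
    @staticmethod
    def _frame(a, b, c):
        return pd.DataFrame({
            "dep_below_half_mw": a, "dep_illiteracy": b, "dep_sanitation": c,
        })

    def test_identical_inputs_rejected(self):
        df = self._frame([0.2] * 5, [0.1] * 5, [0.3] * 5)
        with pytest.raises(ValueError, match="zero variance"):
            deprivation_scores(df)

    def test_extreme_neighborhood_is_high(self):
        rng = np.random.default_rng(5)
        df = self._frame(rng.uniform(0, 0.5, 50), rng.uniform(0, 0.3, 50),
                         rng.uniform(0, 0.6, 50))
        df.loc[0] = [0.5, 0.3, 0.6]  # maximum of every indicator's range
        out = deprivation_scores(df)
        assert out.loc[0, "deprivation_cat"] == "High"

    def test_normal_scores_category_shares(self):
        """Half-SD cutpoints on a normal score give ~30.9/38.3/30.9%
        Low/Medium/High (normal CDF at +-0.5)."""
        rng = np.random.default_rng(7)
        n = 100_000
        df = self._frame(rng.normal(0.3, 0.05, n), rng.normal(0.1, 0.02, n),
                         rng.normal(0.2, 0.04, n))
        shares = (
            deprivation_scores(df)["deprivation_cat"].value_counts(normalize=True)
        )
        assert shares["Low"] == pytest.approx(0.3085, abs=0.01)
        assert shares["Medium"] == pytest.approx(0.3829, abs=0.01)
        assert shares["High"] == pytest.approx(0.3085, abs=0.01)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            deprivation_scores(self._frame([0.1, 0.2], [0.1, 0.2], [0.1, 0.2]),
                               method="pca")
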