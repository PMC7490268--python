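"""Genotype comparisons, dispersal-mode clustering, effect scatter, PCA."""

import numpy as np
import pandas as pd
import pytest

from sporefit.fitness import (
    cluster_dispersal,
    compare_genotypes,
    genotype_effect_scatter,
    growth_auc,
    pca_projection,
)

from test_fitness_expression import brute_force_complete_linkage


def toy_table(groups):
    rows = [
        {"genotype": g, "value": v} for g, values in groups.items() for v in values
    ]
    return pd.DataFrame(rows)


class TestCompareGenotypes:
    def test_f_statistic_matches_hand_computed_sums_of_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [11.0, 12.0, 13.0], "c": [2.0, 3.0, 4.0]}
        result = compare_genotypes(toy_table(groups))
        all_values = np.concatenate(list(groups.values()))
        grand = all_values.mean()
        ss_between = sum(
            len(v) * (np.mean(v) - grand) ** 2 for v in groups.values()
        )
        ss_within = sum(
            ((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values()
        )
        f_manual = (ss_between / 2) / (ss_within / 6)
        assert result.f_statistic == pytest.approx(f_manual)

    def test_identically_drawn_groups_share_one_letter(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(10, 1, size=8).tolist() for g in "abcd"}
        result = compare_genotypes(toy_table(groups))
        assert len(set(result.letters.values())) == 1

    def test_letters_are_consistent_with_the_tukey_pairwise_matrix(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": (rng.normal(0, 1, 6)).tolist(),
            "b": (rng.normal(0.5, 1, 6)).tolist(),
            "c": (rng.normal(8, 1, 6)).tolist(),
            "d": (rng.normal(8.2, 1, 6)).tolist(),
        }
        result = compare_genotypes(toy_table(groups))
        tk = result.tukey_table
        for _, row in tk.iterrows():
            shared = set(result.letters[row["group1"]]) & set(
                result.letters[row["group2"]]
            )
            if row["reject"]:
                assert not shared
            else:
                assert shared

    def test_zero_variance_groups_with_different_means(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}
        result = compare_genotypes(toy_table(groups))
        assert result.p_value < 1e-300
        assert result.letters["a"] != result.letters["b"]

    def test_insufficient_groups_or_replicates_rejected(self):
        with pytest.raises(ValueError, match="two genotypes"):
            compare_genotypes(toy_table({"a": [1, 2, 3]}))
        with pytest.raises(ValueError, match="two replicates"):
            compare_genotypes(toy_table({"a": [1.0], "b": [2.0, 3.0]}))


class TestClusterDispersal:
    def test_identical_rows_merge_at_distance_zero(self):
        m = pd.DataFrame(
            {"air": [10.0, 10.0, 50.0], "water": [40.0, 40.0, 5.0]},
            index=["wt", "twin", "mut"],
        )
        Z, _ = cluster_dispersal(m)
        assert Z[0, 2] == 0.0

    def test_mode_swapped_mutant_joins_the_opposite_dispersal_group(self):
        """A genotype whose air/water indices are swapped relative to its
        wild type clusters with the genotypes of the other dispersal mode."""
        m = pd.DataFrame(
            {
                "air": [80.0, 85.0, 10.0, 12.0, 11.0],
                "water": [10.0, 12.0, 75.0, 80.0, 78.0],
            },
            index=["air_wt1", "air_wt2", "water_wt1", "water_wt2", "swapped_mutant"],
        )
        _, flat = cluster_dispersal(m, height=40.0)
        assert flat["swapped_mutant"] == flat["water_wt1"] == flat["water_wt2"]
        assert flat["swapped_mutant"] != flat["air_wt1"]

    def test_merge_heights_equal_brute_force_complete_linkage(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(
            rng.uniform(0, 100, size=(6, 2)), columns=["air", "water"],
            index=[f"g{i}" for i in range(6)],
        )
        Z, _ = cluster_dispersal(m)
        oracle = brute_force_complete_linkage(m.to_numpy())
        assert np.allclose(sorted(Z[:, 2]), sorted(oracle))

    def test_single_genotype_is_a_trivial_cluster(self):
        m = pd.DataFrame({"air": [10.0], "water": [5.0]}, index=["wt"])
        Z, flat = cluster_dispersal(m)
        assert Z.shape == (0, 4)
        assert flat == {"wt": 1}

    def test_incomplete_matrix_rejected(self):
        m = pd.DataFrame({"air": [1.0, np.nan], "water": [2.0, 3.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="complete"):
            cluster_dispersal(m)


class TestEffectScatter:
    def test_identical_mutant_has_unit_slope_and_all_no_effect(self):
        wt = {"glucose": 10.0, "sucrose": 20.0, "xylose": 5.0}
        res = genotype_effect_scatter(wt, dict(wt))
        assert res.slope == pytest.approx(1.0)
        assert res.pairs.no_effect.all()

    def test_doubled_mutant_has_slope_two_and_no_flags_in_10pct_band(self):
        wt = {"glucose": 10.0, "sucrose": 20.0, "xylose": 5.0}
        mut = {k: 2 * v for k, v in wt.items()}
        res = genotype_effect_scatter(wt, mut, no_effect_band=0.10)
        assert res.slope == pytest.approx(2.0)
        assert not res.pairs.no_effect.any()

    def test_slope_equals_regression_through_origin_closed_form(self):
        rng = np.random.default_rng(3)
        sources = [f"s{i}" for i in range(12)]
        wt = {s: float(rng.uniform(1, 50)) for s in sources}
        mut = {s: float(rng.uniform(1, 50)) for s in sources}
        res = genotype_effect_scatter(wt, mut)
        x = np.array([wt[s] for s in sorted(sources)])
        y = np.array([mut[s] for s in sorted(sources)])
        assert res.slope == pytest.approx((x * y).sum() / (x * x).sum())

    def test_unpaired_sources_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="unpaired"):
            res = genotype_effect_scatter({"a": 1.0, "b": 2.0}, {"a": 1.5, "c": 2.0})
        assert res.pairs.carbon_source.tolist() == ["a"]


class TestPCA:
    def test_duplicated_rows_get_identical_scores(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(4, 3))
        m = pd.DataFrame(np.vstack([base, base[0]]), columns=list("xyz"))
        res = pca_projection(m)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[4])

    def test_leading_component_matches_closed_form_2x2_eigenvector(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = 0.8 * x + 0.2 * rng.normal(size=300)
        m = pd.DataFrame({"x": x, "y": y})
        res = pca_projection(m, scale=False)
        X = m.to_numpy() - m.to_numpy().mean(axis=0)
        cov = X.T @ X / (len(m) - 1)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        got = res.loadings["PC1"].to_numpy()
        assert abs(abs(lead @ got)) == pytest.approx(1.0, abs=1e-10)

    def test_all_components_reconstruct_the_centered_matrix(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        res = pca_projection(m, scale=False)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, m.to_numpy() - m.to_numpy().mean(axis=0))

    def test_variance_percentages_sum_to_100_and_order_decreasing(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        res = pca_projection(m)
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert (np.diff(res.pct_variance) <= 1e-9).all()

    def test_constant_column_dropped_with_warning_under_scaling(self):
        m = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [5.0, 5.0, 5.0],
                          "z": [2.0, 1.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            res = pca_projection(m)
        assert list(res.loadings.index) == ["x", "z"]


class TestGrowthAUC:
    def test_trapezoid_on_a_known_curve(self):
        t = np.array([0.0, 1.0, 2.0])
        od = np.array([0.0, 1.0, 2.0])
        assert growth_auc(t, od) == pytest.approx(2.0)

    def test_time_order_invariance(self):
        t = np.array([2.0, 0.0, 1.0])
        od = np.array([2.0, 0.0, 1.0])
        assert growth_auc(t, od) == pytest.approx(2.0)
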