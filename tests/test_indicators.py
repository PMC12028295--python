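import numpy as np
import pytest

from ecmassembly.indicators import (
    indicator_analysis,
    lnrr_effects,
    per_asv_tests,
    rf_classify,
)
from ecmassembly.io import AsvTable


def planted_table(seed, n_asvs=60, n_per_group=12, fold=10.0, n_planted=1, depth=4000):
    """Two groups of multinomial samples; first ``n_planted`` ASVs enriched in A."""
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_asvs, 0.5)) + 1e-4
    base /= base.sum()
    shifted = base.copy()
    shifted[:n_planted] *= fold
    shifted /= shifted.sum()
    A = np.array([rng.multinomial(depth, shifted) for _ in range(n_per_group)]).T
    B = np.array([rng.multinomial(depth, base) for _ in range(n_per_group)]).T
    table = AsvTable(
        np.hstack([A, B]),
        [f"A{i}" for i in range(n_asvs)],
        [f"S{j}" for j in range(2 * n_per_group)],
    )
    labels = np.array(["grpA"] * n_per_group + ["grpB"] * n_per_group)
    return table, labels


class TestRfClassify:
    def test_planted_feature_ranks_first(self):
        # one perfectly separating ASV among iid noise features
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise = rng.poisson(20, size=(40, 24))
            planted = np.r_[rng.poisson(80, 12), np.zeros(12, int)]
            table = AsvTable(
                np.vstack([planted, noise]),
                [f"A{i}" for i in range(41)],
                [f"S{j}" for j in range(24)],
            )
            labels = ["grpA"] * 12 + ["grpB"] * 12
            rf = rf_classify(table, labels, n_trees=200, seed=seed)
            hits += rf.top(1)[0] == "A0"
        assert hits >= 9

    def test_shuffled_labels_oob_near_chance(self):
        table, labels = planted_table(3, fold=25.0)
        rng = np.random.default_rng(0)
        accs = [
            rf_classify(table, rng.permutation(labels), n_trees=200, seed=s).oob_accuracy
            for s in range(5)
        ]
        # binomial(24, 0.5) 95% band on the mean of 5 runs, generous
        assert 0.2 < np.mean(accs) < 0.8

    def test_seed_reproducibility(self):
        table, labels = planted_table(1)
        r1 = rf_classify(table, labels, n_trees=100, seed=9)
        r2 = rf_classify(table, labels, n_trees=100, seed=9)
        assert r1.importances.equals(r2.importances)
        assert r1.oob_accuracy == r2.oob_accuracy

    def test_permutation_importance_optional(self):
        table, labels = planted_table(2, n_asvs=20)
        rf = rf_classify(
            table, labels, n_trees=50, seed=0, n_permutation_repeats=3
        )
        assert rf.ranking_metric == "permutation_importance"
        assert "permutation_importance" in rf.importances

    def test_single_class_error(self):
        table, _ = planted_table(0)
        with pytest.raises(ValueError):
            rf_classify(table, ["x"] * table.n_samples, n_trees=10, seed=0)


class TestLnrrEffects:
    def test_equal_groups_give_zero(self):
        counts = np.tile([[5], [10]], (1, 8))
        table = AsvTable(counts, ["a", "b"], [f"s{i}" for i in range(8)])
        labels = ["g1"] * 4 + ["g2"] * 4
        eff = lnrr_effects(table, labels, ["a", "b"], n_boot=100, seed=0)
        assert eff.loc["a", "lnrr"] == 0.0
        assert eff.loc["a", "ci_lower"] <= 0 <= eff.loc["a", "ci_upper"]

    def test_reported_group_means_match_table_values(self):
        # means 3.069% vs 0.1417% -> lnrr = ln(3.069/0.1417) ~ 3.075
        lnrr = np.log(3.069 / 0.1417)
        assert lnrr == pytest.approx(3.0753, abs=5e-4)
        table, labels = planted_table(5, n_asvs=10, fold=8.0)
        eff = lnrr_effects(table, labels, ["A0"], n_boot=200, seed=1)
        rel = table.counts / table.counts.sum(axis=0)
        ma = rel[0, labels == "grpA"].mean()
        mb = rel[0, labels == "grpB"].mean()
        assert eff.loc["A0", "lnrr"] == pytest.approx(np.log(ma / mb), abs=1e-12)
        assert eff.loc["A0", "mean_a_pct"] == pytest.approx(100 * ma, abs=1e-12)
        se = rel[0, labels == "grpA"].std(ddof=1) / np.sqrt((labels == "grpA").sum())
        assert eff.loc["A0", "se_a_pct"] == pytest.approx(100 * se, abs=1e-12)

    def test_zero_group_mean_flagged_one_sided(self):
        counts = np.array([[0, 0, 0, 4, 6, 8], [10, 10, 10, 10, 10, 10]])
        table = AsvTable(counts, ["absent_in_a", "ref"], [f"s{i}" for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        eff = lnrr_effects(table, labels, ["absent_in_a"], n_boot=50, seed=0)
        assert eff.loc["absent_in_a", "lnrr"] == -np.inf
        assert bool(eff.loc["absent_in_a", "one_sided"])

    def test_antisymmetric_under_label_swap(self):
        table, labels = planted_table(7, n_asvs=15, fold=6.0)
        kw = dict(n_boot=2000, seed=3)
        fwd = lnrr_effects(table, labels, ["A0", "A5"], group_a="grpA", group_b="grpB", **kw)
        rev = lnrr_effects(table, labels, ["A0", "A5"], group_a="grpB", group_b="grpA", **kw)
        for asv in ("A0", "A5"):
            assert fwd.loc[asv, "lnrr"] == pytest.approx(-rev.loc[asv, "lnrr"], abs=1e-12)
            assert fwd.loc[asv, "ci_lower"] == pytest.approx(
                -rev.loc[asv, "ci_upper"], abs=0.25
            )
            assert fwd.loc[asv, "ci_upper"] == pytest.approx(
                -rev.loc[asv, "ci_lower"], abs=0.25
            )

    def test_both_zero_skipped(self):
        counts = np.array([[0, 0, 0, 0], [5, 5, 5, 5]])
        table = AsvTable(counts, ["gone", "ref"], list("wxyz"))
        eff = lnrr_effects(table, ["a", "a", "b", "b"], ["gone", "ref"], n_boot=20, seed=0)
        assert list(eff.index) == ["ref"]


class TestPerAsvTests:
    def test_identical_groups_p_near_one(self):
        counts = np.tile([[3], [7], [2]], (1, 12))
        counts = counts + np.arange(12) % 3  # variation shared by both groups
        table = AsvTable(counts, ["a", "b", "c"], [f"s{i}" for i in range(12)])
        res = per_asv_tests(table, ["x"] * 6 + ["y"] * 6)
        assert (res["p_value"] > 0.5).all()
        assert "p_adjusted" in res.columns

    def test_tenfold_shift_detected_with_stated_power(self):
        detected = 0
        for seed in range(100):
            table, labels = planted_table(seed, n_asvs=30, n_per_group=10, fold=10.0)
            res = per_asv_tests(table, labels, asvs=["A0"])
            detected += bool(len(res)) and res.loc["A0", "p_value"] < 0.01
        assert detected >= 90

    def test_constant_relative_abundances_skipped(self):
        counts = np.array([[1, 2, 3, 1, 2, 3], [1, 2, 3, 1, 2, 3]])
        table = AsvTable(counts, ["a", "b"], [f"s{i}" for i in range(6)])
        res = per_asv_tests(table, ["x"] * 3 + ["y"] * 3)
        assert len(res) == 0


class TestIndicatorAnalysis:
    def test_end_to_end_orientation_and_join(self, small_study):
        _, table, metadata, taxonomy, _ = small_study
        result, rf = indicator_analysis(
            table, metadata, "stage", taxonomy=taxonomy,
            top_n=15, n_trees=100, n_boot=100, seed=0,
        )
        assert len(result) <= 15
        assert (result["group_a"] == "juvenile").all()
        assert (result["group_b"] == "adult").all()
        assert "impurity_importance" in result.columns
        assert "genus" in result.columns
        assert rf.oob_accuracy > 0.5  # stage signal is strong by design
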