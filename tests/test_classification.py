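"""Ranks, thresholds, dependency probability, class assignment, agreement."""

import numpy as np
import pandas as pd
import pytest

from depscreen import classification as cls
from depscreen.synthetic import SyntheticConfig, generate_gene_effects


class TestNormalizedRanks:
    def test_basic_definition(self):
        m = pd.DataFrame([[-2.0, -1.0, 0.0]], index=["c"], columns=list("abc"))
        out = cls.normalized_ranks(m)
        np.testing.assert_allclose(out.loc["c"], [1 / 3, 2 / 3, 1.0])

    def test_missing_value_shrinks_denominator(self):
        m = pd.DataFrame([[-2.0, np.nan, 0.0]], index=["c"], columns=list("abc"))
        out = cls.normalized_ranks(m)
        assert out.loc["c", "a"] == 0.5 and out.loc["c", "c"] == 1.0
        assert np.isnan(out.loc["c", "b"])

    def test_ties_get_average_ranks(self):
        m = pd.DataFrame([[-1.0, -1.0, 0.0]], index=["c"], columns=list("abc"))
        np.testing.assert_allclose(cls.normalized_ranks(m).loc["c"], [0.5, 0.5, 1.0])

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(5, 20)))
        pd.testing.assert_frame_equal(
            cls.normalized_ranks(m), cls.normalized_ranks(np.exp(m) * 3 - 1)
        )

    def test_permutation_of_unit_fractions(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(3, 15)))
        out = cls.normalized_ranks(m)
        for _, row in out.iterrows():
            np.testing.assert_allclose(sorted(row), np.arange(1, 16) / 15)

    def test_all_missing_line_rejected(self):
        m = pd.DataFrame([[np.nan, np.nan]], index=["c"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cls.normalized_ranks(m)


class TestBimodalMinimum:
    def test_symmetric_mixture_threshold_near_midpoint(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.05, 5000), rng.normal(1, 0.05, 5000)])
        t = cls.bimodal_minimum(x)
        assert 0.25 < t < 0.75
        assert t == pytest.approx(0.5, abs=0.1)

    def test_unimodal_sample_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(cls.BimodalityError):
            cls.bimodal_minimum(rng.normal(0, 1, 5000))


class TestPanDependencyCall:
    def test_explicit_threshold_trivial_calls(self):
        ranks = pd.DataFrame(
            np.column_stack([np.full(20, 0.01), np.full(20, 1.0)]),
            columns=["first", "last"],
        )
        res = cls.pan_dependency_call(ranks, threshold=0.5)
        assert bool(res.is_pan["first"]) and not bool(res.is_pan["last"])
        assert res.rank90["last"] == 1.0

    def test_planted_pan_recovery_with_derived_threshold(self):
        cfg = SyntheticConfig(
            n_cell_lines=200, n_genes=400, seed=21,
            mechanism_counts={}, n_modules=2, module_size=5,
        )
        eff, truth = generate_gene_effects(cfg, "A")
        res = cls.pan_dependency_call(cls.normalized_ranks(eff))
        called = set(res.is_pan.index[res.is_pan])
        truth_pan = set(truth.genes_of("pan"))
        assert called == truth_pan


def make_controlled_line(rng, n_null=120, n_pos=120, sep=1.0, sd=0.12):
    null = rng.normal(0.0, sd, n_null)
    pos = rng.normal(-sep, sd, n_pos)
    return null, pos


class TestProbabilityOfDependency:
    @pytest.fixture(scope="class")
    def prob_setup(self):
        rng = np.random.default_rng(4)
        null, pos = make_controlled_line(rng)
        # empirical equal-density point of the two control KDEs
        from scipy.optimize import brentq
        from scipy.stats import gaussian_kde

        f0 = gaussian_kde(null, bw_method="silverman")
        f1 = gaussian_kde(pos, bw_method="silverman")
        x_star = brentq(lambda x: f1(x)[0] - f0(x)[0], -0.9, -0.1)
        extra = np.array([x_star, -3.0, 1.5])  # equal-density point, far tails
        effects = np.concatenate([null, pos, extra])
        genes = (
            [f"n{i}" for i in range(len(null))]
            + [f"p{i}" for i in range(len(pos))]
            + ["mid", "deep", "enriched"]
        )
        mat = pd.DataFrame([effects], index=["c"], columns=genes)
        prob = cls.probability_of_dependency(
            mat, {g for g in genes if g.startswith("n")}, {g for g in genes if g.startswith("p")}
        )
        return mat, prob

    def test_equal_density_point_near_half(self, prob_setup):
        _, prob = prob_setup
        assert prob.loc["c", "mid"] == pytest.approx(0.5, abs=0.15)

    def test_monotone_tails(self, prob_setup):
        _, prob = prob_setup
        assert prob.loc["c", "deep"] == 1.0
        assert prob.loc["c", "enriched"] == 0.0

    def test_calibration_on_control_draws(self, prob_setup):
        _, prob = prob_setup
        pos_cols = [c for c in prob.columns if c.startswith("p")]
        null_cols = [c for c in prob.columns if c.startswith("n")]
        assert prob.loc["c", pos_cols].mean() > 0.9
        assert prob.loc["c", null_cols].mean() < 0.1

    def test_monotone_nonincreasing_in_effect(self, prob_setup):
        mat, prob = prob_setup
        order = mat.loc["c"].sort_values().index
        p = prob.loc["c", order].to_numpy()
        assert (np.diff(p) <= 1e-12).all()

    def test_values_in_unit_interval_and_missing_propagates(self):
        rng = np.random.default_rng(5)
        null, pos = make_controlled_line(rng)
        mat = pd.DataFrame([np.concatenate([null, pos, [np.nan]])],
                           index=["c"],
                           columns=[f"n{i}" for i in range(len(null))]
                           + [f"p{i}" for i in range(len(pos))] + ["gap"])
        prob = cls.probability_of_dependency(
            mat, {f"n{i}" for i in range(len(null))}, {f"p{i}" for i in range(len(pos))}
        )
        assert np.isnan(prob.loc["c", "gap"])
        vals = prob.drop(columns="gap").to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_degenerate_controls_rejected(self):
        mat = pd.DataFrame([np.concatenate([np.zeros(30), -np.ones(30)])],
                           index=["c"],
                           columns=[f"n{i}" for i in range(30)] + [f"p{i}" for i in range(30)])
        with pytest.raises(ValueError):
            cls.probability_of_dependency(
                mat, {f"n{i}" for i in range(30)}, {f"p{i}" for i in range(30)}
            )


class TestHighVariance:
    def test_constant_gene_never_flagged(self):
        prob = pd.DataFrame({"const": np.full(50, 0.7), "ne": np.random.default_rng(6).uniform(0, 0.05, 50)})
        res = cls.high_variance_call(prob, {"ne"})
        assert not bool(res.is_high_variance["const"])

    def test_alternating_gene_has_maximal_variance(self):
        probs = pd.DataFrame(
            {"alt": np.tile([0.0, 1.0], 25), "ne": np.linspace(0, 0.1, 50)}
        )
        res = cls.high_variance_call(probs, {"ne"})
        assert res.variance["alt"] == pytest.approx(0.25, abs=0.01)
        assert bool(res.is_high_variance["alt"])

    def test_empty_control_set_rejected(self):
        with pytest.raises(ValueError):
            cls.high_variance_call(pd.DataFrame({"g": [0.1, 0.2]}), set())


def oracle_classify(row, lrt_cutoff=100.0):
    """Literal sequential re-evaluation of the ordered rule list."""
    label = None
    if row["n_dependent"] == 0:
        label = "non_dependent"
    if row["n_dependent"] >= 1:
        label = "weakly_selective"
    if row["lrt"] >= lrt_cutoff:
        label = "strongly_selective"
    if row["is_pan"]:
        label = "pan_dependent"
    if row["is_high_variance"]:
        label = "high_variance"
    if row["lrt"] >= lrt_cutoff and row["skew_sign"] == "negative":
        label = "strongly_selective"
    return label


def random_statistics(rng, n):
    return pd.DataFrame(
        {
            "n_dependent": rng.integers(0, 5, n),
            "lrt": rng.choice([0.0, 50.0, 100.0, 150.0], n),
            "skew_sign": rng.choice(["negative", "nonnegative"], n),
            "is_pan": rng.random(n) < 0.3,
            "is_high_variance": rng.random(n) < 0.3,
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestClassify:
    def test_trivial_rules(self):
        stats = random_statistics(np.random.default_rng(0), 3)
        stats.loc["g0", ["n_dependent", "lrt", "is_pan", "is_high_variance"]] = [0, 0.0, False, False]
        stats.loc["g1", ["n_dependent", "lrt", "is_pan", "is_high_variance"]] = [2, 50.0, True, False]
        stats.loc["g2", ["n_dependent", "lrt", "is_pan", "is_high_variance"]] = [2, 150.0, True, True]
        stats.loc["g2", "skew_sign"] = "negative"
        out = cls.classify_dependency(stats)["dependency_class"]
        assert out["g0"] == "non_dependent"
        assert out["g1"] == "pan_dependent"
        assert out["g2"] == "strongly_selective"

    def test_matches_rule_list_oracle_exactly(self):
        rng = np.random.default_rng(7)
        stats = random_statistics(rng, 200)
        out = cls.classify_dependency(stats)["dependency_class"]
        for g, row in stats.iterrows():
            assert out[g] == oracle_classify(row), g

    def test_first_match_order_variant(self):
        stats = random_statistics(np.random.default_rng(8), 50)
        out = cls.classify_dependency(stats, order="first_match")["dependency_class"]
        # first-match: any gene with zero dependent lines keeps rule 1
        zero = stats.index[stats["n_dependent"] == 0]
        assert (out[zero] == "non_dependent").all()

    def test_classes_partition_gene_set(self):
        stats = random_statistics(np.random.default_rng(9), 100)
        out = cls.classify_dependency(stats)
        assert out["dependency_class"].notna().all()
        assert len(out) == 100

    def test_missing_statistics_dropped_with_warning(self):
        stats = random_statistics(np.random.default_rng(10), 10)
        stats.loc["g0", "lrt"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            out = cls.classify_dependency(stats)
        assert "g0" not in out.index


def _mini_dataset(effects, is_pan, classes):
    return {
        "effects": effects,
        "is_pan": is_pan,
        "classes": pd.DataFrame({"dependency_class": classes}),
    }


class TestHighConfidence:
    def test_identical_datasets_agree_everywhere(self):
        rng = np.random.default_rng(11)
        eff = pd.DataFrame(rng.normal(size=(30, 12)), columns=[f"g{i}" for i in range(12)])
        pan = pd.Series(False, index=eff.columns)
        classes = pd.Series("weakly_selective", index=eff.columns)
        d = _mini_dataset(eff, pan, classes)
        res = cls.high_confidence_set({"A": [d, d], "B": [d, d]})
        assert res.in_set.all()

    def test_shared_nondependent_rule(self):
        rng = np.random.default_rng(12)
        eff1 = pd.DataFrame(rng.normal(size=(30, 6)), columns=[f"g{i}" for i in range(6)])
        eff2 = pd.DataFrame(rng.normal(size=(30, 6)), columns=eff1.columns)
        pan = pd.Series(False, index=eff1.columns)
        classes = pd.Series("non_dependent", index=eff1.columns)
        d1, d2 = _mini_dataset(eff1, pan, classes), _mini_dataset(eff2, pan, classes)
        res = cls.high_confidence_set({"A": [d1, d2], "B": [d1, d2]})
        assert res.in_set.all()  # all non-dependent in every dataset

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(50)]
        base = pd.DataFrame(rng.normal(size=(40, 50)), columns=genes)
        # second dataset: half the genes keep their profile (plus noise),
        # half are permuted
        other = base + rng.normal(0, 0.4, base.shape)
        shuffled = genes[25:]
        other[shuffled] = other[list(rng.permutation(shuffled))].to_numpy()
        pan = pd.Series(rng.random(50) < 0.2, index=genes)
        classes = pd.Series(
            np.where(rng.random(50) < 0.3, "non_dependent", "weakly_selective"),
            index=genes,
        )
        d1 = _mini_dataset(base, pan, classes)
        d2 = _mini_dataset(other, pan, classes)
        res = cls.high_confidence_set({"A": [d1, d2], "B": [d1, d2]})
        corr = pd.DataFrame(
            np.corrcoef(base.T.to_numpy(), other.T.to_numpy())[:50, 50:],
            index=genes, columns=genes,
        )
        for g in genes:
            top = corr.loc[g].idxmax() == g
            agree = (pan[g] and pan[g]) or classes[g] == "non_dependent" or top
            assert bool(res.in_set[g]) == bool(agree), g


class TestClassMapping:
    def test_identical_tables_diagonal(self):
        t = pd.DataFrame({"dependency_class": ["pan_dependent", "non_dependent", "high_variance"]},
                         index=["g1", "g2", "g3"])
        _, cont = cls.map_classes_cross_perturbation(t, t)
        assert cont.to_numpy().sum() == 3
        assert np.trace(cont.to_numpy()) == 3

    def test_row_sums_conserve_class_counts(self):
        rng = np.random.default_rng(14)
        from depscreen.containers import DEPENDENCY_CLASSES
        idx = [f"g{i}" for i in range(40)]
        ta = pd.DataFrame({"dependency_class": rng.choice(DEPENDENCY_CLASSES, 40)}, index=idx)
        tb = pd.DataFrame({"dependency_class": rng.choice(DEPENDENCY_CLASSES, 40)}, index=idx)
        _, cont = cls.map_classes_cross_perturbation(ta, tb)
        counts = ta["dependency_class"].value_counts()
        for c in DEPENDENCY_CLASSES:
            assert cont.loc[c].sum() == counts.get(c, 0)

    def test_axis_mismatch_rejected(self):
        ta = pd.DataFrame({"dependency_class": ["pan_dependent"]}, index=["g1"])
        tb = pd.DataFrame({"dependency_class": ["pan_dependent"]}, index=["g2"])
        with pytest.raises(ValueError):
            cls.map_classes_cross_perturbation(ta, tb)
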