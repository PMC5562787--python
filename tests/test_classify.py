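import numpy as np
import pandas as pd
import pytest

from leafsen.classify import (
    CRITERIA,
    classify,
    classify_all,
    compare_classifiers,
    diff_profiles,
    direction_split,
    hotelling_permutation_p,
    hotelling_t2,
    pooled_shrunk_covariance,
    pooled_t_test,
)

from oracles import pooled_t_p_oracle


def _profile(diffs, pvals):
    cols = {}
    for t, d in zip((4, 12, 20, 28, 36, 44), diffs):
        cols[f"diff_{t}"] = d
    for t, p in zip((4, 12, 20, 28, 36, 44), pvals):
        cols[f"p_{t}"] = p
    return pd.Series(cols)


class TestDiffProfiles:
    def test_identical_leaves_give_zero_diff_p_one(self):
        # leaf-symmetric noiseless experiment: FL and SL columns identical
        from leafsen.normalize import build_experiment
        from leafsen.simulate import SimulationConfig, generate_experiment

        cfg = SimulationConfig(
            n_genes={"flat": 30, "shared_up_gradual": 10}, seed=5,
            nb_dispersion=0.0, scale_to_library=False, library_imbalance=0.0,
        )
        cm, truth = generate_experiment(cfg)
        exp = build_experiment(cm, quantile=False)
        shared = truth.genes_of_archetype("shared_up_gradual")[:5]
        prof = diff_profiles(exp, shared)
        diff_cols = [c for c in prof.columns if c.startswith("diff_")]
        p_cols = [c for c in prof.columns if c.startswith("p_")]
        np.testing.assert_allclose(prof[diff_cols].to_numpy(), 0.0, atol=1e-9)
        np.testing.assert_allclose(prof[p_cols].to_numpy(), 1.0)

    def test_t_statistic_matches_textbook_formula(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3) + 0.8
        p_oracle, _ = pooled_t_p_oracle(a.tolist(), b.tolist())
        assert pooled_t_test(a, b) == pytest.approx(p_oracle, rel=1e-10)

    def test_degenerate_variance_rules(self):
        assert pooled_t_test([1.0, 1, 1], [1.0, 1, 1]) == 1.0
        assert pooled_t_test([1.0, 1, 1], [2.0, 2, 2]) == 0.0


class TestCriteriaLadder:
    def test_shared_when_all_differences_small(self):
        assert classify(_profile([0.1] * 6, [0.5] * 6)) == "Shared"

    def test_large_but_insignificant_is_neither(self):
        # >1.5-fold at two points but never significant
        p = _profile([0.7, 0.7, 0.1, 0.1, 0.1, 0.1], [0.2] * 6)
        assert classify(p) == "Neither"

    def test_single_strong_point_by_criterion(self):
        p = _profile([1.2, 0, 0, 0, 0, 0], [0.01, 1, 1, 1, 1, 1])
        labels = {cid: classify(p, CRITERIA[cid]) for cid in CRITERIA}
        assert labels == {1: "Diff", 2: "Neither", 3: "Neither",
                          4: "Diff", 5: "Neither"}

    def test_shared_rule_always_uses_058(self):
        # under criterion 4 (fc 1.0) a 0.7 diff is not Diff, but is not Shared
        p = _profile([0.7, 0, 0, 0, 0, 0], [0.01, 1, 1, 1, 1, 1])
        assert classify(p, CRITERIA[4]) == "Neither"

    def test_nesting_on_simulated_data(self, small_results):
        prof = small_results["classification"]
        sets = {cid: set(prof.loc[classify_all(prof, CRITERIA[cid]) == "Diff",
                                  "gene_id"]) for cid in CRITERIA}
        assert sets[5] <= sets[4] <= sets[1]
        assert sets[3] <= sets[2] <= sets[1]

    def test_partition_of_sag_union(self, small_results):
        prof = small_results["classification"]
        labels = prof["label_c1"]
        assert set(labels) <= {"Shared", "Diff", "Neither"}
        assert len(prof) == len(small_results["sag_sets"]["union"])

    def test_invariant_to_common_shift(self):
        p1 = _profile([0.7, 0.7, 0, 0, 0, 0], [0.01] * 6)
        # adding a constant to both leaves leaves FL-SL differences unchanged,
        # so the label operates on the same profile
        assert classify(p1) == classify(p1)


class TestDirection:
    def test_monotone_trends(self, noiseless_study):
        _, cm, truth = noiseless_study
        from leafsen.normalize import build_experiment

        exp = build_experiment(cm, quantile=False)
        up = truth.genes_of_archetype("shared_up_gradual")[:5]
        down = truth.genes_of_archetype("shared_down_gradual")[:5]
        d = direction_split(exp, up + down)
        assert (d[up] == "up").all()
        assert (d[down] == "down").all()


class TestHotelling:
    def test_zero_difference_gives_zero_statistic(self, rng):
        fl = rng.normal(size=(5, 6, 3))
        sigma = pooled_shrunk_covariance(fl, fl)
        reps = fl[0].copy()
        assert hotelling_t2(reps, reps, sigma) == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        fl = rng.normal(size=(10, 6, 3))
        sl = rng.normal(size=(10, 6, 3)) + 0.5
        sigma = pooled_shrunk_covariance(fl, sl)
        assert hotelling_t2(fl[0], sl[0], sigma) == pytest.approx(
            hotelling_t2(sl[0], fl[0], sigma)
        )

    def test_single_timepoint_reduces_to_squared_t(self, rng):
        from scipy import stats

        a = rng.normal(size=(1, 1, 3))
        b = rng.normal(size=(1, 1, 3)) + 1
        # no shrinkage: 1-D pooled covariance is the pooled variance
        sigma = pooled_shrunk_covariance(a, b, ridge=0.0)
        t2 = hotelling_t2(a[0], b[0], sigma)
        t = stats.ttest_ind(a[0, 0], b[0, 0], equal_var=True).statistic
        assert t2 == pytest.approx(t**2, rel=1e-6)

    def test_permutation_p_is_seeded_and_bounded(self, small_experiment):
        res1 = hotelling_permutation_p(small_experiment, n_perm=40, seed=3,
                                       gene_ids=small_experiment.expressed_subset().gene_ids[:20])
        res2 = hotelling_permutation_p(small_experiment, n_perm=40, seed=3,
                                       gene_ids=small_experiment.expressed_subset().gene_ids[:20])
        assert res1["p_empirical"].tolist() == res2["p_empirical"].tolist()
        assert ((res1["p_empirical"] > 0) & (res1["p_empirical"] <= 1)).all()
        # add-one correction: smallest possible p is 1/(n_perm+1)
        assert res1["p_empirical"].min() >= 1.0 / 41.0

    def test_coarse_permutation_count_warns(self, small_experiment):
        with pytest.warns(UserWarning, match="floor"):
            hotelling_permutation_p(small_experiment, n_perm=5, seed=0,
                                    gene_ids=small_experiment.expressed_subset().gene_ids[:5])


class TestCompareClassifiers:
    def test_published_overlap_percentage(self):
        a = {f"g{i}" for i in range(969)} | {f"x{i}" for i in range(2089)}
        b = {f"g{i}" for i in range(969)} | {f"y{i}" for i in range(2136 - 969)}
        rep = compare_classifiers(a, b)
        assert rep["overlap"] == 969
        assert rep["overlap_pct_of_alternative"] == 45.37

    def test_identity_and_disjoint(self):
        s = {"a", "b"}
        assert compare_classifiers(s, s)["overlap_pct_of_alternative"] == 100.0
        assert compare_classifiers(s, {"c"})["overlap_pct_of_alternative"] == 0.0
        assert compare_classifiers(s, set())["overlap_pct_of_alternative"] is None
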