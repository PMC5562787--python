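import numpy as np
import pytest

from leafsen.io import ct_to_relative_expression
from leafsen.simulate import (
    ArchetypeSpec,
    SimulationConfig,
    default_archetypes,
    generate_annotation,
    generate_experiment,
    generate_perturbation,
    generate_qpcr,
    perturbation_rules,
    study_archetype_counts,
)


class TestArchetypeInvariants:
    def test_flat_must_be_zero(self):
        with pytest.raises(ValueError, match="flat"):
            ArchetypeSpec("bad", "flat", (0, 0, 1, 0, 0, 0), (0,) * 6, "early")

    def test_diff_needs_real_offset(self):
        with pytest.raises(ValueError, match="offset"):
            ArchetypeSpec("bad", "diff_up", (0, 1, 2, 2, 2, 2),
                          (0, 0.1, 0.2, 0.1, 0, 0), "early")

    def test_shared_offset_stays_below_diff_threshold(self):
        with pytest.raises(ValueError, match="shared"):
            ArchetypeSpec("bad", "shared_up", (0, 1, 2, 2, 2, 2),
                          (0, 1.0, 0, 0, 0, 0), "early")

    def test_default_archetypes_self_consistent(self):
        for arch in default_archetypes():
            offset = np.asarray(arch.offset_profile)
            if arch.cls.startswith("diff"):
                assert np.sum(np.abs(offset) >= 1.0) >= 2


class TestGenerateExperiment:
    def test_class_counts_match_request_exactly(self):
        counts = study_archetype_counts(500)
        cfg = SimulationConfig(n_genes=counts, seed=1)
        _, truth = generate_experiment(cfg)
        got = truth.table["archetype"].value_counts().to_dict()
        assert got == counts
        assert truth.table["class"].value_counts()["flat"] == counts["flat"]

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genes={"flat": 30, "shared_up_early": 10}, seed=42)
        cm1, _ = generate_experiment(cfg)
        cm2, _ = generate_experiment(cfg)
        np.testing.assert_array_equal(cm1.counts, cm2.counts)

    def test_zero_dispersion_flat_genes_constant(self):
        cfg = SimulationConfig(n_genes={"flat": 20}, seed=0, nb_dispersion=0.0,
                               library_imbalance=0.0)
        cm, _ = generate_experiment(cfg)
        assert np.allclose(cm.counts, cm.counts[:, :1], rtol=1e-12)

    def test_zero_dispersion_offset_recovered_exactly(self, noiseless_study):
        """Sign convention: FL - SL log2 difference equals minus the offset."""
        _, cm, truth = noiseless_study
        frame = cm.to_frame()
        meta = cm.meta_frame().set_index("sample_id")
        for arch in default_archetypes():
            if not arch.cls.startswith("diff"):
                continue
            genes = truth.genes_of_archetype(arch.name)[:3]
            for ti, t in enumerate(truth.times):
                fl_cols = [s for s in frame.columns
                           if meta.loc[s, "leaf"] == "FL" and meta.loc[s, "time_dah"] == t]
                sl_cols = [s for s in frame.columns
                           if meta.loc[s, "leaf"] == "SL" and meta.loc[s, "time_dah"] == t]
                diff = (np.log2(frame.loc[genes, fl_cols]).median(axis=1)
                        - np.log2(frame.loc[genes, sl_cols]).median(axis=1))
                np.testing.assert_allclose(diff, -arch.offset_profile[ti], atol=1e-9)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes={"flat": 0})


class TestAnnotation:
    def test_infinite_odds_confines_term_to_class(self):
        cfg = SimulationConfig(n_genes=study_archetype_counts(400), seed=3,
                               planted_term_size=20, planted_class="diff_up")
        _, truth = generate_experiment(cfg)
        ann = generate_annotation(truth, cfg, enrichment_odds=np.inf)
        assert ann.term_genes["T0001"] <= set(truth.genes_of_class("diff_up"))
        assert len(ann.term_genes["T0001"]) == 20

    def test_unit_odds_is_uniform_draw(self):
        cfg = SimulationConfig(n_genes=study_archetype_counts(400), seed=3)
        _, truth = generate_experiment(cfg)
        ann = generate_annotation(truth, cfg, enrichment_odds=1.0)
        # a uniform 30-gene draw lands mostly outside the 60-gene target class
        inside = len(ann.term_genes["T0001"] & set(truth.genes_of_class("diff_up")))
        assert inside < 15

    def test_deterministic_and_size_checked(self):
        cfg = SimulationConfig(n_genes={"flat": 10, "diff_up_fl_high": 5}, seed=3,
                               planted_term_size=30)
        _, truth = generate_experiment(cfg)
        with pytest.raises(ValueError, match="universe|class"):
            generate_annotation(truth, cfg)
        cfg2 = SimulationConfig(n_genes={"flat": 40, "diff_up_fl_high": 10}, seed=3,
                                planted_term_size=5)
        _, truth2 = generate_experiment(cfg2)
        a = generate_annotation(truth2, cfg2, seed=8)
        b = generate_annotation(truth2, cfg2, seed=8)
        assert a.term_genes == b.term_genes


class TestPerturbation:
    def test_zero_rules_reproduce_means(self):
        cfg = SimulationConfig(n_genes={"flat": 10, "diff_up_fl_high": 10}, seed=4,
                               nb_dispersion=0.0, library_imbalance=0.0)
        cm, truth = generate_experiment(cfg)
        zeros = (np.zeros(6), np.zeros(6))
        pr, _ = generate_perturbation(cfg, truth,
                                      rules={"diff_up_fl_high": zeros, "flat": zeros},
                                      seed=cfg.seed)
        np.testing.assert_allclose(pr.counts, cm.counts, rtol=1e-12)

    def test_full_shrink_closes_integrated_gap(self):
        from leafsen.metrics import integrated_difference

        cfg = SimulationConfig(n_genes={"flat": 50, "diff_up_fl_high": 10}, seed=4,
                               nb_dispersion=0.0, library_imbalance=0.0,
                               scale_to_library=False)
        cm, truth = generate_experiment(cfg)
        rules = perturbation_rules(None, {"diff_up_fl_high": "shrink"})
        pr, pr_truth = generate_perturbation(cfg, truth, rules=rules, seed=cfg.seed)
        gi = truth.table.index[truth.table["archetype"] == "diff_up_fl_high"][0]
        d = integrated_difference(pr_truth.fl_profiles[gi], pr_truth.sl_profiles[gi],
                                  truth.times)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_unknown_class_in_rules_rejected(self):
        cfg = SimulationConfig(n_genes={"flat": 10}, seed=0)
        _, truth = generate_experiment(cfg)
        with pytest.raises(ValueError, match="unknown"):
            perturbation_rules(None, {"nonexistent": "shrink"})


class TestQpcr:
    def test_noiseless_ct_rank_matches_truth(self):
        cfg = SimulationConfig(n_genes={"shared_up_gradual": 3}, seed=6)
        _, truth = generate_experiment(cfg)
        q = generate_qpcr(truth, noise_sd=0.0, seed=1, replicates=(1,))
        g = truth.table["gene_id"].iloc[0]
        sub = q.table[(q.table.gene_id == g) & (q.table.leaf == "FL")].sort_values("time_dah")
        rel = ct_to_relative_expression(sub["ct_gene"].to_numpy(),
                                        sub["ct_reference"].to_numpy())
        true_profile = truth.fl_profiles[0]
        assert np.all(np.argsort(rel) == np.argsort(true_profile))

    def test_deterministic_and_validated(self):
        cfg = SimulationConfig(n_genes={"flat": 2}, seed=6)
        _, truth = generate_experiment(cfg)
        a = generate_qpcr(truth, seed=5)
        b = generate_qpcr(truth, seed=5)
        assert a.table.equals(b.table)
        with pytest.raises(ValueError):
            generate_qpcr(truth, noise_sd=-1.0)
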