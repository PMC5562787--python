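"""End-to-end orchestration of the time-course senescence analysis.

One call runs normalization -> per-leaf SAG detection -> shared/differential
classification -> pattern clustering -> enrichment on a count matrix, with
every threshold taken from the flat config (see :mod:`leafsen.config`).
Evaluation helpers score the run against a planted truth table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as cls
from . import cluster as clu
from . import enrich as enr
from . import sag
from .config import DEFAULTS, stage_seed
from .io import CountMatrix
from .normalize import TimeCourseExperiment, build_experiment


def fold_change_profiles(experiment: TimeCourseExperiment, gene_ids) -> np.ndarray:
    """Per-gene 12-feature log2-FC profile (FL then SL) vs the 4 DAH FL mean."""
    sub = experiment.expressed_subset()
    idx = {g: i for i, g in enumerate(sub.gene_ids)}
    rows = np.array([idx[g] for g in gene_ids])
    rep_mean = sub.log2_cpm[rows].mean(axis=3)         # (gene, leaf, time)
    base = rep_mean[:, 0, 0]                           # FL mean at 4 DAH
    fc = rep_mean - base[:, None, None]
    return np.concatenate([fc[:, 0, :], fc[:, 1, :]], axis=1)


def difference_matrix(profiles: pd.DataFrame, gene_ids) -> np.ndarray:
    """FL-SL median difference profiles in gene order, from diff_profiles."""
    diff_cols = [c for c in profiles.columns if c.startswith("diff_")]
    lut = profiles.set_index("gene_id")[diff_cols]
    return lut.loc[list(gene_ids)].to_numpy()


def run_pipeline(cm: CountMatrix, config: dict | None = None) -> dict:
    """Full analysis on a count matrix; returns a dict of result tables."""
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    experiment = build_experiment(
        cm,
        expression_threshold=cfg["expression_threshold"],
        expression_scope=cfg["expression_filter_scope"],
        logratio_trim=cfg["tmm_logratio_trim"],
        abundance_trim=cfg["tmm_abundance_trim"],
    )
    results: dict = {"experiment": experiment, "config": cfg}

    # reproducibility cutoff: fixed operative value or permutation-derived
    pcc_cutoff = float(cfg["pcc_cutoff"])
    if cfg["pcc_cutoff_mode"] == "permutation":
        block = experiment.expressed_subset().leaf_values("FL")
        null = sag.permutation_pcc_cutoff(
            block, n_perm=int(cfg["n_perm_pcc"]), seed=stage_seed(seed, "pcc_null"),
            window=int(cfg["savgol_window"]), order=int(cfg["savgol_order"]),
        )
        pcc_cutoff = null.operative_cutoff
        results["pcc_null"] = null
    results["pcc_cutoff"] = pcc_cutoff

    calls = {}
    for leaf in ("FL", "SL"):
        calls[leaf] = sag.call_sags(
            experiment, leaf, pcc_cutoff=pcc_cutoff, alpha=cfg["sag_alpha"],
            fc_min=cfg["sag_fc_min"], fc_baseline=cfg["fc_baseline"],
            anova_on_smoothed=cfg["anova_on_smoothed"],
            window=int(cfg["savgol_window"]), order=int(cfg["savgol_order"]),
        )
    results["fl_calls"], results["sl_calls"] = calls["FL"], calls["SL"]
    sets = sag.sag_sets(calls["FL"], calls["SL"])
    results["sag_sets"] = sets

    union = sorted(sets["union"])
    profiles = cls.diff_profiles(experiment, union, equal_var=cfg["t_equal_var"])
    for cid, spec in cls.CRITERIA.items():
        profiles[f"label_c{cid}"] = cls.classify_all(profiles, spec, cfg["t_alpha"]).to_numpy()
    shared_genes = list(profiles.loc[profiles["label_c1"] == "Shared", "gene_id"])
    diff_genes = list(profiles.loc[profiles["label_c1"] == "Diff", "gene_id"])
    if diff_genes:
        direction = cls.direction_split(experiment, diff_genes)
        profiles["direction"] = profiles["gene_id"].map(direction).fillna("")
    results["classification"] = profiles
    results["shared_genes"], results["diff_genes"] = shared_genes, diff_genes

    k = int(cfg["kmeans_k"])
    patterns = []
    if len(shared_genes) >= k:
        fc_shared = fold_change_profiles(experiment, shared_genes)
        patterns.append(
            clu.assign_patterns(
                "shared", shared_genes, fc_shared, fc_shared,
                k=k, seed=stage_seed(seed, "kmeans_shared"),
                n_restarts=int(cfg["kmeans_restarts"]),
                n_up_patterns=int(cfg["n_shared_up_patterns"]),
                n_down_patterns=int(cfg["n_shared_down_patterns"]),
            )
        )
    if len(diff_genes) >= k:
        fc_diff = fold_change_profiles(experiment, diff_genes)
        dmat = difference_matrix(profiles, diff_genes)
        patterns.append(
            clu.assign_patterns(
                "diff", diff_genes, np.concatenate([fc_diff, dmat], axis=1), fc_diff,
                diff_profiles=dmat, k=k, seed=stage_seed(seed, "kmeans_diff"),
                n_restarts=int(cfg["kmeans_restarts"]),
                n_up_patterns=int(cfg["n_diff_up_patterns"]),
                n_down_patterns=int(cfg["n_diff_down_patterns"]),
                n_groups=int(cfg["n_groups"]),
                major_fraction=float(cfg["major_fraction"]),
            )
        )
    results["patterns"] = (
        pd.concat(patterns, ignore_index=True) if patterns
        else pd.DataFrame(columns=["gene_id", "track", "cluster_id", "direction",
                                   "pattern_id", "group", "major"])
    )
    return results


def enrich_groups(results: dict, annotation, config: dict | None = None) -> pd.DataFrame:
    """EASE enrichment of every pattern/group gene set in a pipeline result."""
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    experiment: TimeCourseExperiment = results["experiment"]
    if cfg["enrichment_universe"] == "expressed":
        universe = set(experiment.expressed_subset().gene_ids)
    elif cfg["enrichment_universe"] == "annotated":
        universe = annotation.annotated_genes()
    else:
        raise ValueError(f"unknown universe policy {cfg['enrichment_universe']!r}")
    patterns = results["patterns"]
    frames = []
    group_cols = [("pattern_id", "pattern"), ("group", "group")]
    for col, kind in group_cols:
        for label, sub in patterns.groupby(col):
            if label in ("", "none"):
                continue
            rows = enr.enrich_group(set(sub["gene_id"]), annotation, universe,
                                    alpha=cfg["ease_alpha"], min_hits=int(cfg["ease_min_hits"]))
            rows.insert(0, "set_kind", kind)
            rows.insert(1, "set_id", label)
            frames.append(rows)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def evaluate_sag_calls(results: dict, truth) -> dict:
    """Precision/recall of the SAG union against the planted truth."""
    called = results["sag_sets"]["union"]
    expressed = set(results["experiment"].expressed_subset().gene_ids)
    true_sags = truth.sag_genes & expressed
    tp = len(called & true_sags)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(true_sags) if true_sags else float("nan")
    return {"precision": precision, "recall": recall,
            "n_called": len(called), "n_true": len(true_sags)}


def evaluate_diff_classification(results: dict, truth) -> dict:
    """Recall/precision of the Criteria-1 differential call vs the truth."""
    called = set(results["diff_genes"])
    expressed = set(results["experiment"].expressed_subset().gene_ids)
    true_diff = truth.diff_genes & expressed
    tp = len(called & true_diff)
    return {
        "recall": tp / len(true_diff) if true_diff else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
        "n_called": len(called), "n_true": len(true_diff),
    }
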