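"""Run configuration: flat key/value YAML with every analysis threshold named.

Defaults are the published study's operating values: PCC cutoff 0.7 derived
from a 100-round permutation null, ANOVA alpha 0.05 after Bonferroni,
|log2FC| >= 1 over the course, shared/differential threshold 0.58
(= log2 1.5), k = 30 clusters per track, 1000 Hotelling permutations, and
the >10% major-group rule.
"""

from __future__ import annotations

import numpy as np
import yaml

DEFAULTS: dict = {
    # normalization
    "expression_threshold": 1.0,       # replicate-mean CPM in >=1 time point
    "expression_filter_scope": "timepoint_mean",  # or "replicate"
    "tmm_logratio_trim": 0.30,
    "tmm_abundance_trim": 0.05,
    # SAG detection
    "pcc_cutoff": 0.7,                 # fixed operative cutoff (paper: 0.71 -> 0.7)
    "pcc_cutoff_mode": "fixed",        # or "permutation" (floor of 95th pct)
    "n_perm_pcc": 100,
    "sag_alpha": 0.05,                 # Bonferroni-adjusted ANOVA p
    "sag_fc_min": 1.0,                 # max |log2FC| over the six time points
    "fc_baseline": "own_4dah",         # or "fl_4dah"
    "anova_on_smoothed": False,
    "savgol_order": 2,
    "savgol_window": 5,
    # classification
    "shared_fc_threshold": 0.58,       # log2(1.5), always governs the Shared rule
    "diff_fc_threshold": 0.58,
    "diff_min_timepoints": 1,
    "t_alpha": 0.05,
    "t_equal_var": True,
    "n_perm_hotelling": 1000,
    "hotelling_ridge": 0.5,            # shrinkage weight toward the diagonal
    "hotelling_alpha": 0.05,
    # clustering
    "kmeans_k": 30,
    "kmeans_restarts": 20,
    "n_shared_up_patterns": 4,
    "n_shared_down_patterns": 3,
    "n_diff_up_patterns": 10,
    "n_diff_down_patterns": 6,
    "n_groups": 5,
    "major_fraction": 0.10,
    # enrichment
    "ease_alpha": 0.05,
    "ease_min_hits": 5,
    "enrichment_universe": "expressed",  # or "annotated"
    # global
    "seed": 0,
}

#: stable per-stage streams fanned out from the single top-level seed
STAGES = (
    "simulate",
    "annotation",
    "perturbation",
    "qpcr",
    "pcc_null",
    "hotelling",
    "kmeans_shared",
    "kmeans_diff",
)


def load_config(path=None, **overrides) -> dict:
    """Merge defaults <- YAML file <- keyword overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a flat key/value mapping")
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    cfg.update(overrides)
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent integer seed (< 2**31) for a named stage."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; known: {STAGES}")
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
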