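"""Synthetic two-leaf time-course experiments with planted ground truth.

Genes follow archetypal log2 trajectories over the 4-44 DAH grid: flat
non-senescence genes, shared up/down archetypes (early, gradual, peaked)
identical in both leaves, and differential archetypes where the second
leaf's profile is offset from the flag leaf's at early or middle stages.
Counts are negative-binomial around library-scaled means, so the
dispersion -> 0 limit is an exact deterministic testing regime.  A planted
enriched annotation term, a panicle-removal-style perturbation and paired
qPCR readouts make every downstream stage testable without any download.

Sign convention, stated once and tested everywhere: ``offset_profile`` is
SL minus FL in log2 units, so downstream FL-SL differences equal -offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEFAULT_TIMES, CountMatrix, GeneAnnotation, QpcrTable, SampleMeta

CLASSES = ("shared_up", "shared_down", "diff_up", "diff_down", "flat")
DIFF_OFFSET_MIN = 0.58  # a differential archetype must exceed this somewhere


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted trajectory family.

    ``base_profile`` is the flag-leaf log2 trajectory (relative to its own
    4 DAH level); ``offset_profile`` (SL - FL) is added to obtain the
    second leaf's trajectory.
    """

    name: str
    cls: str
    base_profile: tuple
    offset_profile: tuple
    timing: str  # early | gradual | middle-peak

    def __post_init__(self):
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")
        base = np.asarray(self.base_profile, dtype=float)
        offset = np.asarray(self.offset_profile, dtype=float)
        if base.shape != offset.shape:
            raise ValueError("base and offset profiles must align")
        if self.cls == "flat" and (np.any(base != 0) or np.any(offset != 0)):
            raise ValueError("flat archetypes must have all-zero profiles")
        if self.cls.startswith("diff") and np.max(np.abs(offset)) < DIFF_OFFSET_MIN:
            raise ValueError(
                f"differential archetype {self.name!r} needs |offset| >= "
                f"{DIFF_OFFSET_MIN} at >= 1 time point"
            )
        if self.cls.startswith("shared") and np.max(np.abs(offset)) >= DIFF_OFFSET_MIN:
            raise ValueError(
                f"shared archetype {self.name!r} must keep |offset| < {DIFF_OFFSET_MIN}"
            )

    @property
    def sl_profile(self) -> np.ndarray:
        return np.asarray(self.base_profile) + np.asarray(self.offset_profile)


def default_archetypes() -> list[ArchetypeSpec]:
    """The study conditions: flat non-senescence genes, three shared shapes
    per direction (early, gradual, peaked trajectories spanning 4 log2
    units, i.e. ~16-fold, typical of senescence programs such as collapsing
    photosynthesis transcripts), and differential archetypes whose SL-FL
    offsets reach 1.5 log2 units with magnitude >= 1 at two or more time
    points (early or middle stages), mirroring the five major difference
    groups."""
    z = (0.0,) * 6
    return [
        ArchetypeSpec("flat", "flat", z, z, "gradual"),
        ArchetypeSpec("shared_up_early", "shared_up",
                      (0.0, 2.4, 4.0, 4.0, 4.0, 4.0), z, "early"),
        ArchetypeSpec("shared_up_gradual", "shared_up",
                      (0.0, 0.8, 1.6, 2.4, 3.2, 4.0), z, "gradual"),
        ArchetypeSpec("shared_up_peak", "shared_up",
                      (0.0, 2.0, 4.0, 4.0, 2.0, 0.4), z, "middle-peak"),
        ArchetypeSpec("shared_down_early", "shared_down",
                      (0.0, -2.4, -4.0, -4.0, -4.0, -4.0), z, "early"),
        ArchetypeSpec("shared_down_gradual", "shared_down",
                      (0.0, -0.8, -1.6, -2.4, -3.2, -4.0), z, "gradual"),
        ArchetypeSpec("diff_up_fl_high", "diff_up",
                      (0.0, 0.8, 1.6, 2.4, 3.2, 4.0),
                      (0.0, -1.1, -1.5, -1.5, -1.1, -0.6), "early"),
        ArchetypeSpec("diff_up_sl_high", "diff_up",
                      (0.0, 0.8, 1.6, 2.4, 3.2, 4.0),
                      (0.0, 0.6, 1.1, 1.5, 1.5, 1.1), "middle-peak"),
        ArchetypeSpec("diff_down_fl_high", "diff_down",
                      (0.0, -0.8, -1.6, -2.4, -3.2, -4.0),
                      (0.0, -0.6, -1.1, -1.5, -1.5, -1.1), "middle-peak"),
        ArchetypeSpec("diff_down_sl_high", "diff_down",
                      (0.0, -0.8, -1.6, -2.4, -3.2, -4.0),
                      (0.0, 1.1, 1.5, 1.5, 1.1, 0.6), "early"),
    ]


def study_archetype_counts(n_genes: int = 2000) -> dict[str, int]:
    """40% flat, 30% shared (split over 5 shapes), 30% differential (4)."""
    n_flat = int(round(0.4 * n_genes))
    n_shared, n_diff = int(round(0.3 * n_genes)), n_genes - n_flat - int(round(0.3 * n_genes))
    shared_names = ["shared_up_early", "shared_up_gradual", "shared_up_peak",
                    "shared_down_early", "shared_down_gradual"]
    diff_names = ["diff_up_fl_high", "diff_up_sl_high",
                  "diff_down_fl_high", "diff_down_sl_high"]
    counts = {"flat": n_flat}
    for i, name in enumerate(shared_names):
        counts[name] = n_shared // len(shared_names) + (1 if i < n_shared % len(shared_names) else 0)
    for i, name in enumerate(diff_names):
        counts[name] = n_diff // len(diff_names) + (1 if i < n_diff % len(diff_names) else 0)
    return counts


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_genes: dict[str, int] = field(default_factory=study_archetype_counts)
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    library_size: float = 4e7         # ~40M reads, typical bulk RNA-seq depth
    library_imbalance: float = 0.30   # library sizes uniform in (1 +/- this) x nominal
    nb_dispersion: float = 0.05       # variance = mu + dispersion * mu^2
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 3.0     # wide spread, as in real log2-CPM distributions
    seed: int = 0
    times: tuple = DEFAULT_TIMES
    replicates: tuple = (1, 2, 3)
    scale_to_library: bool = True     # False: absolute means, no composition term
    n_terms: int = 50
    planted_term_size: int = 30
    planted_class: str = "diff_up"

    def __post_init__(self):
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        known = {a.name for a in self.archetypes}
        unknown = set(self.n_genes) - known
        if unknown:
            raise ValueError(f"counts requested for unknown archetypes: {sorted(unknown)}")
        if any(n < 0 for n in self.n_genes.values()):
            raise ValueError("archetype counts must be >= 0")
        if sum(self.n_genes.values()) == 0:
            raise ValueError("at least one gene must be requested")


@dataclass
class TruthTable:
    """Planted labels plus the noiseless log2 profiles behind them."""

    table: pd.DataFrame  # gene_id, archetype, class, is_sag_fl, is_sag_sl, is_diff, group
    baselines: np.ndarray            # (gene,)
    fl_profiles: np.ndarray          # (gene, time)
    sl_profiles: np.ndarray          # (gene, time)
    times: tuple = DEFAULT_TIMES

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.table.loc[self.table["class"] == cls, "gene_id"])

    def genes_of_archetype(self, name: str) -> list[str]:
        return list(self.table.loc[self.table["archetype"] == name, "gene_id"])

    @property
    def sag_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_sag_fl"] | t["is_sag_sl"], "gene_id"])

    @property
    def diff_genes(self) -> set[str]:
        return set(self.table.loc[self.table["is_diff"], "gene_id"])


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return mu.copy()  # exact deterministic limit
    if dispersion < 1e-8:
        return rng.poisson(mu).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(float)


def _sample_grid(times, replicates):
    metas = []
    for leaf in ("FL", "SL"):
        for t in times:
            for r in replicates:
                metas.append(SampleMeta(f"{leaf}_t{t}_r{r}", leaf, int(t), int(r)))
    return metas


def generate_experiment(config: SimulationConfig,
                        profile_overrides: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                        seed: int | None = None) -> tuple[CountMatrix, TruthTable]:
    """Draw one two-leaf experiment and its truth table.

    ``profile_overrides`` (archetype name -> (fl_shift, sl_shift) in log2
    units) supports perturbation variants; ``seed`` overrides the config
    seed for condition-specific streams.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arch_by_name = {a.name: a for a in config.archetypes}
    names, fl_rows, sl_rows = [], [], []
    records = []
    fc_min = 1.0  # SAG truth uses the pipeline's own fold-change rule
    for arch_name in sorted(config.n_genes):
        arch = arch_by_name[arch_name]
        fl = np.asarray(arch.base_profile, dtype=float)
        sl = arch.sl_profile.astype(float)
        if profile_overrides and arch_name in profile_overrides:
            fl_shift, sl_shift = profile_overrides[arch_name]
            fl = fl + np.asarray(fl_shift, dtype=float)
            sl = sl + np.asarray(sl_shift, dtype=float)
        for i in range(config.n_genes[arch_name]):
            gid = f"{arch_name}_{i + 1:05d}"
            names.append(gid)
            fl_rows.append(fl)
            sl_rows.append(sl)
            records.append(
                {
                    "gene_id": gid,
                    "archetype": arch_name,
                    "class": arch.cls,
                    "is_sag_fl": bool(np.max(np.abs(fl - fl[0])) >= fc_min),
                    "is_sag_sl": bool(np.max(np.abs(sl - sl[0])) >= fc_min),
                    "is_diff": arch.cls.startswith("diff"),
                    "group": arch_name if arch.cls.startswith("diff") else "none",
                }
            )
    fl_prof = np.vstack(fl_rows)
    sl_prof = np.vstack(sl_rows)
    n_genes = len(names)
    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    metas = _sample_grid(config.times, config.replicates)
    lib_factor = rng.uniform(1 - config.library_imbalance, 1 + config.library_imbalance,
                             len(metas))
    mu = np.empty((n_genes, len(metas)))
    for j, meta in enumerate(metas):
        ti = list(config.times).index(meta.time_dah)
        profile = fl_prof[:, ti] if meta.leaf == "FL" else sl_prof[:, ti]
        rel = np.power(2.0, baselines + profile)
        if config.scale_to_library:
            mu[:, j] = rel / rel.sum() * config.library_size * lib_factor[j]
        else:
            mu[:, j] = rel
    counts = _nb_counts(rng, mu, config.nb_dispersion)
    truth = TruthTable(pd.DataFrame(records), baselines, fl_prof, sl_prof, config.times)
    return CountMatrix(names, metas, counts), truth


def generate_annotation(truth: TruthTable, config: SimulationConfig,
                        enrichment_odds: float = np.inf,
                        seed: int | None = None) -> GeneAnnotation:
    """Random flat annotation with one planted enriched term (T0001).

    The planted term's genes are drawn without replacement with odds
    ``enrichment_odds`` favoring the chosen class; odds 1 is a uniform
    (null) draw, odds -> infinity confines the term to the class.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    universe = list(truth.table["gene_id"])
    if config.planted_term_size > len(universe):
        raise ValueError("planted term size exceeds the gene universe")
    in_class = truth.table["class"].eq(config.planted_class).to_numpy()
    if np.isinf(enrichment_odds):
        pool = [g for g, m in zip(universe, in_class) if m]
        if config.planted_term_size > len(pool):
            raise ValueError("planted term size exceeds the chosen class")
        planted = set(rng.choice(pool, config.planted_term_size, replace=False))
    else:
        weights = np.where(in_class, float(enrichment_odds), 1.0)
        weights = weights / weights.sum()
        planted = set(rng.choice(universe, config.planted_term_size,
                                 replace=False, p=weights))
    term_genes = {"T0001": planted}
    for t in range(2, config.n_terms + 1):
        size = int(rng.integers(10, 41))
        term_genes[f"T{t:04d}"] = set(rng.choice(universe, size, replace=False))
    names = {"T0001": f"planted term ({config.planted_class})"}
    return GeneAnnotation(term_genes, names)


#: behavior of each planted class under sink removal
DEFAULT_PERTURBATION_BEHAVIOR = {
    "diff_up_fl_high": "shrink",     # FL pulled down to the SL level
    "diff_down_fl_high": "shrink",
    "diff_up_sl_high": "amplify",    # hormone-like: the gap widens
    "diff_down_sl_high": "unchanged",  # transport-like: sink-independent
}


def perturbation_rules(truth_archetypes, behavior: dict[str, str] | None = None,
                       archetypes: list[ArchetypeSpec] | None = None,
                       amplify_factor: float = 0.5) -> dict:
    """Translate per-class behaviors into (fl_shift, sl_shift) log2 rules.

    shrink: FL moves by the full offset so the FL-SL gap closes; amplify:
    SL moves by ``amplify_factor`` x offset, widening the gap; unchanged:
    no shift.  Unknown classes in ``behavior`` are an error.
    """
    behavior = dict(DEFAULT_PERTURBATION_BEHAVIOR if behavior is None else behavior)
    archetypes = default_archetypes() if archetypes is None else archetypes
    by_name = {a.name: a for a in archetypes}
    unknown = set(behavior) - set(by_name)
    if unknown:
        raise ValueError(f"perturbation rules reference unknown classes: {sorted(unknown)}")
    zeros = np.zeros(6)
    rules = {}
    for name, how in behavior.items():
        offset = np.asarray(by_name[name].offset_profile, dtype=float)
        if how == "shrink":
            rules[name] = (offset.copy(), zeros)        # FL + offset == SL level
        elif how == "amplify":
            rules[name] = (zeros, amplify_factor * offset)
        elif how == "unchanged":
            rules[name] = (zeros, zeros)
        else:
            raise ValueError(f"unknown behavior {how!r} for {name!r}")
    return rules


def generate_perturbation(config: SimulationConfig, truth: TruthTable,
                          rules: dict | None = None,
                          seed: int | None = None) -> tuple[CountMatrix, TruthTable]:
    """Re-draw the experiment under panicle-removal-style profile shifts.

    ``rules`` maps archetype name -> (fl_shift, sl_shift) in log2 units;
    defaults emulate the published directionality (FL-high gaps shrink, a
    hormone-like class amplifies, a transport-like class is untouched).
    """
    if rules is None:
        present = set(truth.table["archetype"])
        behavior = {k: v for k, v in DEFAULT_PERTURBATION_BEHAVIOR.items() if k in present}
        rules = perturbation_rules(present, behavior, config.archetypes)
    else:
        unknown = set(rules) - {a.name for a in config.archetypes}
        if unknown:
            raise ValueError(f"perturbation rules reference unknown classes: {sorted(unknown)}")
    return generate_experiment(config, profile_overrides=rules, seed=seed)


def generate_qpcr(truth: TruthTable, noise_sd: float = 0.25, seed: int = 0,
                  gene_ids=None, replicates=(1, 2, 3),
                  ct_intercept: float = 30.0, ct_slope: float = 1.0,
                  ct_reference: float = 20.0) -> QpcrTable:
    """Paired qRT-PCR readouts from the noiseless profiles.

    Ct is an affine transform of true log2 abundance (higher abundance,
    earlier cycle): ct = intercept - slope * (baseline-centered profile),
    plus Gaussian cycle noise; the actin reference Ct is constant in
    expectation with the same noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    table = truth.table.set_index("gene_id")
    gene_ids = list(table.index) if gene_ids is None else list(gene_ids)
    rows = []
    for gid in gene_ids:
        gi = truth.table.index[truth.table["gene_id"] == gid][0]
        for leaf, prof in (("FL", truth.fl_profiles[gi]), ("SL", truth.sl_profiles[gi])):
            for ti, t in enumerate(truth.times):
                for rep in replicates:
                    ct_g = ct_intercept - ct_slope * prof[ti] + rng.normal(0, noise_sd)
                    ct_r = ct_reference + rng.normal(0, noise_sd)
                    rows.append((gid, leaf, int(t), int(rep), ct_g, ct_r))
    frame = pd.DataFrame(rows, columns=["gene_id", "leaf", "time_dah", "replicate",
                                        "ct_gene", "ct_reference"])
    return QpcrTable(frame)
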