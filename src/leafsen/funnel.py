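"""Staged set-filtering ("funnel") bookkeeping for gene families.

Generalizes the amino-acid-transporter selection procedure: a seed family
is pushed through an ordered list of named predicates (expressed, SAG in
any leaf, shared, differential, membership of a specific group or
subfamily) and the surviving set plus per-subfamily counts are recorded at
every stage.  Predicates are declared by name in config, so a family
analysis is one config block rather than code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable


@dataclass
class FunnelStage:
    name: str
    description: str
    surviving: set[str]

    @property
    def count(self) -> int:
        return len(self.surviving)


@dataclass
class FunnelReport:
    stages: list[FunnelStage]
    subfamily_counts: dict[str, list[int]] = field(default_factory=dict)

    def counts(self) -> list[int]:
        return [s.count for s in self.stages]

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, stage in enumerate(self.stages):
            row = {"stage": stage.name, "description": stage.description,
                   "count": stage.count}
            for fam, per_stage in self.subfamily_counts.items():
                row[f"n_{fam}"] = per_stage[i]
            rows.append(row)
        return pd.DataFrame(rows)


class PredicateRegistry:
    """Named, pure predicates over upstream pipeline outputs."""

    def __init__(self):
        self._predicates: dict[str, Callable[[str], bool]] = {}

    def register(self, name: str, fn: Callable[[str], bool]) -> None:
        self._predicates[name] = fn

    def register_sets(self, *, expressed=None, sag_any_leaf=None, shared=None,
                      diff=None, groups: dict | None = None,
                      subfamilies: dict | None = None) -> None:
        """Register the standard pipeline predicates from plain gene sets."""
        if expressed is not None:
            self.register("expressed", lambda g, s=set(expressed): g in s)
        if sag_any_leaf is not None:
            self.register("is_sag_any_leaf", lambda g, s=set(sag_any_leaf): g in s)
        if shared is not None:
            self.register("is_shared", lambda g, s=set(shared): g in s)
        if diff is not None:
            self.register("is_diff", lambda g, s=set(diff): g in s)
        for label, genes in (groups or {}).items():
            self.register(f"in_group:{label}", lambda g, s=set(genes): g in s)
        for label, genes in (subfamilies or {}).items():
            self.register(f"subfamily:{label}", lambda g, s=set(genes): g in s)

    def resolve(self, spec: str) -> Callable[[str], bool]:
        """Resolve a predicate name; `a|b` is the union (either passes)."""
        parts = spec.split("|")
        missing = [p for p in parts if p not in self._predicates]
        if missing:
            raise KeyError(
                f"predicate(s) {missing} reference missing upstream results; "
                f"known: {sorted(self._predicates)}"
            )
        fns = [self._predicates[p] for p in parts]
        return lambda g: any(fn(g) for fn in fns)


def run_funnel(seed_set, stages: list[tuple[str, str]], registry: PredicateRegistry,
               subfamily_map: dict[str, str] | None = None) -> FunnelReport:
    """Monotone filtration of ``seed_set`` through named predicate stages.

    ``stages`` is an ordered list of (stage name, predicate spec); the
    report records the surviving set and per-subfamily counts at the seed
    stage and after every filter.
    """
    current = set(seed_set)
    report_stages = [FunnelStage("seed", "input family", set(current))]
    for name, spec in stages:
        predicate = registry.resolve(spec)
        current = {g for g in current if predicate(g)}
        report_stages.append(FunnelStage(name, spec, set(current)))
    subfam_counts: dict[str, list[int]] = {}
    if subfamily_map:
        families = sorted(set(subfamily_map.values()))
        for fam in families:
            members = {g for g, f in subfamily_map.items() if f == fam}
            subfam_counts[fam] = [len(stage.surviving & members) for stage in report_stages]
    return FunnelReport(report_stages, subfam_counts)
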