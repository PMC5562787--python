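"""Tabular input/output and shared domain containers.

All tables are tab-separated UTF-8 with a header row; gene order is
preserved from input.  The containers are thin dataclasses over pandas /
numpy objects so that every downstream module works on plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEAVES = ("FL", "SL")
#: Grain-filling sampling grid in days after heading.
DEFAULT_TIMES = (4, 12, 20, 28, 36, 44)
DEFAULT_REPLICATES = (1, 2, 3)


@dataclass(frozen=True)
class SampleMeta:
    """One RNA-seq library: which leaf, when, and which biological replicate."""

    sample_id: str
    leaf: str
    time_dah: int
    replicate: int

    def __post_init__(self):
        if self.leaf not in LEAVES:
            raise ValueError(f"leaf must be one of {LEAVES}, got {self.leaf!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class CountMatrix:
    """Gene-level counts, genes x samples, with per-sample metadata.

    Counts are non-negative numeric; the TSV reader enforces integers, but
    in-memory matrices may hold exact real-valued means (the deterministic
    zero-dispersion simulation limit).
    """

    gene_ids: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Series(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        triples = [(s.leaf, s.time_dah, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("(leaf, time_dah, replicate) triples must be unique")
        times = {
            leaf: sorted({s.time_dah for s in self.samples if s.leaf == leaf})
            for leaf in LEAVES
        }
        present = [t for t in times.values() if t]
        if len(present) == 2 and present[0] != present[1]:
            raise ValueError("FL and SL must share an identical ordered time grid")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "leaf": [s.leaf for s in self.samples],
                "time_dah": [s.time_dah for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


@dataclass
class GeneAnnotation:
    """Flat term -> gene-set annotation (e.g. GO biological processes)."""

    term_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, genes in self.term_genes.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return out


@dataclass
class QpcrTable:
    """Long-format qRT-PCR cycle-threshold readouts with a reference gene."""

    table: pd.DataFrame  # gene_id, leaf, time_dah, replicate, ct_gene, ct_reference

    REQUIRED = ("gene_id", "leaf", "time_dah", "replicate", "ct_gene", "ct_reference")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns: {missing}")
        vals = self.table[["ct_gene", "ct_reference"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("qPCR Ct values must be finite")


def ct_to_relative_expression(ct_gene, ct_reference):
    """Actin-normalized relative expression 2**-(Ct_gene - Ct_reference).

    Accepts scalars or arrays; inputs must be finite.
    """
    ct_gene = np.asarray(ct_gene, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_gene)) and np.all(np.isfinite(ct_reference))):
        raise ValueError("Ct values must be finite")
    out = np.power(2.0, -(ct_gene - ct_reference))
    return float(out) if out.ndim == 0 else out


def read_sample_meta(meta_path) -> list[SampleMeta]:
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "leaf": str})
    required = ["sample_id", "leaf", "time_dah", "replicate"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return [
        SampleMeta(r.sample_id, r.leaf, int(r.time_dah), int(r.replicate))
        for r in meta.itertuples()
    ]


def read_count_matrix(path, meta_path) -> CountMatrix:
    """Read a genes x samples count TSV plus its sample-metadata TSV.

    Columns are reordered to match the metadata order.  Any sample listed in
    the metadata but absent from the count file (or vice versa) is a hard
    error naming the sample; non-integer counts are a hard error naming the
    offending row and column.
    """
    samples = read_sample_meta(meta_path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    wanted = [s.sample_id for s in samples]
    for sid in wanted:
        if sid not in table.columns:
            raise ValueError(f"sample {sid!r} listed in metadata but missing from count file")
    extra = [c for c in table.columns if c not in set(wanted)]
    if extra:
        raise ValueError(f"sample {extra[0]!r} present in count file but not in metadata")
    table = table[wanted]
    values = table.to_numpy()
    frac = values - np.floor(values)
    if np.any(frac != 0) or not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(frac != 0)[0]
        raise ValueError(
            f"non-integer count at gene {table.index[bad[0]]!r}, "
            f"sample {table.columns[bad[1]]!r}"
        )
    return CountMatrix(list(table.index), samples, values)


def write_count_matrix(cm: CountMatrix, path, meta_path) -> None:
    frame = cm.to_frame()
    # integer formatting when the matrix is integral, else full precision
    if np.all(frame.to_numpy() == np.floor(frame.to_numpy())):
        frame = frame.astype(np.int64)
    frame.to_csv(path, sep="\t", index_label="gene_id")
    cm.meta_frame().to_csv(meta_path, sep="\t", index=False)


def read_annotation(path, names_path=None) -> GeneAnnotation:
    """Two-column TSV (term_id, gene_id), one pair per row."""
    pairs = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if pairs.shape[1] < 2:
        raise ValueError("annotation TSV must have two columns: term_id, gene_id")
    term_col, gene_col = pairs.columns[:2]
    term_genes: dict[str, set[str]] = {}
    for term, gene in zip(pairs[term_col], pairs[gene_col]):
        term_genes.setdefault(term, set()).add(gene)
    names = {}
    if names_path is not None:
        nm = pd.read_csv(names_path, sep="\t", header=0, dtype=str)
        names = dict(zip(nm.iloc[:, 0], nm.iloc[:, 1]))
    return GeneAnnotation(term_genes, names)


def write_annotation(ann: GeneAnnotation, path) -> None:
    rows = [
        {"term_id": term, "gene_id": gene}
        for term in sorted(ann.term_genes)
        for gene in sorted(ann.term_genes[term])
    ]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_qpcr(path) -> QpcrTable:
    return QpcrTable(pd.read_csv(path, sep="\t"))


def write_qpcr(q: QpcrTable, path) -> None:
    q.table.to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)
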