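"""Binary gene-by-sample mutation data and its bipartite-graph view.

The central container is :class:`MutationMatrix`: a binary incidence matrix
``D`` over genes (rows) and samples (columns), where ``D[g, s] = 1`` records
that a protein-altering mutation of gene ``g`` was observed in sample ``s``.
Samples carry a tumor/normal label, partitioning the sample set into the
tumor view used by community detection and the normal samples used only for
tumor-ratio filtering and classifier evaluation.

The same data is equivalently an unweighted bipartite graph with gene and
sample vertex classes and an edge per observed mutation; its adjacency
matrix has the symmetric block form ``[[0, D], [D^T, 0]]``.
"""

from __future__ import annotations

import gzip
import math
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

__all__ = [
    "MutationMatrix",
    "MutationDataError",
    "MalformedEntryError",
    "LabelMismatchError",
    "DuplicateIdError",
    "UnknownIdError",
    "EmptyClassError",
    "load_mutation_matrix",
    "write_mutation_matrix",
    "build_graph",
    "joint_mutation_samples",
    "chance_containment_probability",
    "combination_space_size",
]


class MutationDataError(ValueError):
    """Base error for invalid mutation data."""


class MalformedEntryError(MutationDataError):
    """A matrix entry is not 0/1."""


class LabelMismatchError(MutationDataError):
    """Sample sets of the matrix and the labels file disagree."""


class DuplicateIdError(MutationDataError):
    """A gene or sample identifier occurs more than once."""


class UnknownIdError(MutationDataError):
    """A referenced gene or sample is not present in the matrix."""


class EmptyClassError(MutationDataError):
    """An operation requires a sample class that is empty."""


class MutationMatrix:
    """Validated binary mutation matrix with tumor/normal sample labels.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (matrix rows).
    sample_ids
        Ordered, unique sample identifiers (matrix columns).
    labels
        Per-sample class, each ``"tumor"`` or ``"normal"``.
    data
        Binary array of shape ``(n_genes, n_samples)``.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        labels: Sequence[str],
        data: np.ndarray,
    ) -> None:
        self.gene_ids = tuple(str(g) for g in gene_ids)
        self.sample_ids = tuple(str(s) for s in sample_ids)
        labels = list(labels)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DuplicateIdError("duplicate gene identifiers in matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("duplicate sample identifiers in matrix")
        if len(labels) != len(self.sample_ids):
            raise LabelMismatchError(
                f"{len(labels)} labels for {len(self.sample_ids)} samples"
            )
        bad = [lab for lab in labels if lab not in (TUMOR, NORMAL)]
        if bad:
            raise LabelMismatchError(f"labels must be tumor|normal, got {bad[0]!r}")
        data = np.asarray(data)
        if data.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise MutationDataError(
                f"data shape {data.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if data.size and not np.isin(data, (0, 1)).all():
            g, s = np.argwhere(~np.isin(data, (0, 1)))[0]
            raise MalformedEntryError(
                f"non-binary entry {data[g, s]!r} at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        self.data = data.astype(np.uint8)
        self.is_tumor = np.array([lab == TUMOR for lab in labels], dtype=bool)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    # -- basic queries ----------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.is_tumor, TUMOR, NORMAL)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_tumor(self) -> int:
        return int(self.is_tumor.sum())

    @property
    def tumor_sample_ids(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.sample_ids)[self.is_tumor])

    @property
    def normal_sample_ids(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.sample_ids)[~self.is_tumor])

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise UnknownIdError(f"unknown gene {gene!r}") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise UnknownIdError(f"unknown sample {sample!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "MutationMatrix":
        """Induced matrix on the given samples, preserving gene order."""
        idx = [self.sample_index(s) for s in sample_ids]
        return MutationMatrix(
            self.gene_ids,
            [self.sample_ids[j] for j in idx],
            [TUMOR if self.is_tumor[j] else NORMAL for j in idx],
            self.data[:, idx],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MutationMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"{self.n_tumor} tumor)"
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, labels: Sequence[str]) -> "MutationMatrix":
        return cls(list(frame.index), list(frame.columns), labels, frame.to_numpy())


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def load_mutation_matrix(matrix_path, labels_path) -> MutationMatrix:
    """Read a matrix TSV (gene rows, sample-ID header) and a labels TSV.

    The labels file is two columns, ``sampleID<TAB>tumor|normal``, without a
    header. Both files may be gzip-compressed. Gene and sample order is
    preserved from the files.
    """
    with _open_text(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise DuplicateIdError(f"duplicate sample identifiers in {matrix_path}")
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    frame.columns = sample_ids  # undo any pandas de-duplication mangling
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise DuplicateIdError(f"duplicate gene identifier {dup!r} in {matrix_path}")
    values = frame.to_numpy()
    ok = np.isin(values, ("0", "1"))
    if values.size and not ok.all():
        g, s = np.argwhere(~ok)[0]
        raise MalformedEntryError(
            f"non-binary entry {values[g, s]!r} at gene {frame.index[g]!r}, "
            f"sample {sample_ids[s]!r} in {matrix_path}"
        )
    data = (values == "1").astype(np.uint8)

    lab = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    if lab["sample"].duplicated().any():
        dup = lab["sample"][lab["sample"].duplicated()].iloc[0]
        raise DuplicateIdError(f"duplicate sample {dup!r} in {labels_path}")
    label_map = dict(zip(lab["sample"], lab["label"]))
    missing = [s for s in sample_ids if s not in label_map]
    extra = [s for s in label_map if s not in set(sample_ids)]
    if missing or extra:
        raise LabelMismatchError(
            f"matrix/labels sample mismatch: missing labels for {missing[:3]}, "
            f"labels without matrix column for {extra[:3]}"
        )
    labels = [label_map[s] for s in sample_ids]
    return MutationMatrix(list(frame.index), sample_ids, labels, data)


def write_mutation_matrix(matrix: MutationMatrix, matrix_path, labels_path) -> None:
    """Write the matrix and labels in the TSV layout read by the loader."""
    frame = pd.DataFrame(
        matrix.data, index=list(matrix.gene_ids), columns=list(matrix.sample_ids)
    )
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample": matrix.sample_ids, "label": matrix.labels}).to_csv(
        labels_path, sep="\t", header=False, index=False
    )


def _scope_sample_indices(matrix: MutationMatrix, scope: str) -> np.ndarray:
    if scope == "all":
        return np.arange(matrix.n_samples)
    if scope == "tumor_only":
        idx = np.flatnonzero(matrix.is_tumor)
        if idx.size == 0:
            raise EmptyClassError("tumor_only scope requested but no tumor samples")
        return idx
    raise ValueError(f"scope must be 'all' or 'tumor_only', got {scope!r}")


def build_graph(matrix: MutationMatrix, scope: str = "all") -> ig.Graph:
    """Bipartite mutation graph G (scope='all') or G^tum (scope='tumor_only').

    Vertices are genes first, then in-scope samples, with attributes
    ``name`` (identifier) and ``type`` (0 for genes, 1 for samples). An edge
    joins gene g and sample s iff ``D[g, s] = 1``.
    """
    cols = _scope_sample_indices(matrix, scope)
    sub = matrix.data[:, cols]
    gi, sj = np.nonzero(sub)
    n_g = matrix.n_genes
    graph = ig.Graph(
        n=n_g + cols.size,
        edges=np.column_stack([gi, n_g + sj]).tolist(),
    )
    graph.vs["type"] = [0] * n_g + [1] * cols.size
    graph.vs["name"] = list(matrix.gene_ids) + [matrix.sample_ids[j] for j in cols]
    return graph


def joint_mutation_samples(
    matrix: MutationMatrix, genes: Iterable[str], scope: str = "all"
) -> frozenset:
    """Samples jointly mutated in every gene of the combination.

    Returns M(C_G) = intersection over g of M(g); with ``scope='tumor_only'``
    the tumor-restricted M^tum(C_G).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("combination must be non-empty")
    rows = [matrix.gene_index(g) for g in genes]
    mask = matrix.data[rows].all(axis=0).astype(bool)
    if scope == "tumor_only":
        mask &= matrix.is_tumor
    elif scope != "all":
        raise ValueError(f"scope must be 'all' or 'tumor_only', got {scope!r}")
    return frozenset(np.asarray(matrix.sample_ids)[mask])


def chance_containment_probability(mutation_fraction: float, k: int) -> float:
    """Probability that an unrelated gene covers all k jointly-mutated samples.

    Under the independence model, a gene mutated in a fraction f of tumor
    samples is mutated in all k samples of a combination's joint-mutation set
    with probability f**k. At f = 0.5 and k = 10 this is ~0.001, which is why
    chance co-mutation rarely pulls unrelated genes into a dense community.
    """
    if not 0.0 <= mutation_fraction <= 1.0:
        raise ValueError("mutation_fraction must be in [0, 1]")
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(mutation_fraction) ** int(k)


def combination_space_size(n_genes: int, h: int) -> int:
    """Exact count C(n_genes, h) of gene combinations of size h."""
    if h < 0 or n_genes < 0:
        raise ValueError("n_genes and h must be non-negative")
    if h > n_genes:
        raise ValueError(f"h={h} exceeds n_genes={n_genes}")
    return math.comb(n_genes, h)
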