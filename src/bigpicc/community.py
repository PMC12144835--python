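"""Bipartite community detection and iterative size-constrained partitioning.

Community structure is defined by the Constant Potts Model (CPM) restricted
to the bipartite case: a partition P of the gene/sample vertices scores

    Q(P) = sum over communities C of  e(C) - gamma * |C_G| * |C_S|

where e(C) counts edges internal to C (all of them run between the gene
component C_G and the sample component C_S) and gamma in [0, 1] is the
resolution — the internal connection density a vertex set must exceed to
contribute positively. A community with an empty gene or sample component
contributes exactly zero, so the all-singleton partition scores 0 and any
optimiser that starts from singletons returns quality >= 0.

Quality optimisation delegates to the Leiden algorithm (leidenalg), which
guarantees locally optimal vertex assignments; :func:`cpm_quality` is an
independent implementation used for verification. The resolution is never a
free parameter: every (sub)graph is partitioned at gamma equal to its own
connectivity density, which is what makes the pipeline parameter-free.

Oversized communities — gene components larger than the maximum plausible
hit count u — are iteratively re-partitioned on the subgraph induced by
their genes together with every tumor sample any of those genes mutates,
again at the subgraph's own density. Each refinement strictly shrinks the
gene set, so the total number of optimiser calls is bounded by the number
of genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd

from .matrix import MutationMatrix, _scope_sample_indices

logger = logging.getLogger(__name__)

__all__ = [
    "Community",
    "Partition",
    "CandidatePool",
    "InvalidPartitionError",
    "cpm_quality",
    "subgraph_density",
    "optimize_partition",
    "iterative_partition",
    "IterativePartitionResult",
    "build_candidate_pool",
    "write_pool",
]


class InvalidPartitionError(ValueError):
    """The supplied communities do not partition the graph's vertices."""


@dataclass(frozen=True)
class Community:
    """A gene component C_G and sample component C_S found in one community."""

    genes: frozenset
    samples: frozenset

    @property
    def h(self) -> int:
        return len(self.genes)


@dataclass
class Partition:
    """Disjoint communities jointly covering a (sub)graph, with the gamma used."""

    communities: list[Community]
    gamma: float


def _community_vertex_sets(partition) -> list[tuple[set, set]]:
    if isinstance(partition, Partition):
        partition = partition.communities
    out = []
    for comm in partition:
        if isinstance(comm, Community):
            out.append((set(comm.genes), set(comm.samples)))
        else:  # raw vertex-name collection; caller's graph types disambiguate
            out.append((set(comm), set()))
    return out


def cpm_quality(graph: ig.Graph, partition, gamma: float) -> float:
    """Bipartite CPM quality of a partition, computed from first principles.

    ``partition`` is a :class:`Partition` or an iterable of
    :class:`Community`. The communities must be pairwise disjoint and
    jointly cover every vertex of ``graph`` (identified by the ``name``
    vertex attribute, with ``type`` 0 = gene, 1 = sample).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    names = graph.vs["name"]
    types = graph.vs["type"]
    if isinstance(partition, Partition):
        partition = partition.communities
    membership: dict = {}
    sizes: list[list[int]] = []
    for cid, comm in enumerate(partition):
        members = set(comm.genes) | set(comm.samples) if isinstance(comm, Community) else set(comm)
        for v in members:
            if v in membership:
                raise InvalidPartitionError(f"vertex {v!r} in more than one community")
            membership[v] = cid
        sizes.append([0, 0])
    if set(membership) != set(names):
        raise InvalidPartitionError("communities do not cover the graph's vertices")
    for name, typ in zip(names, types):
        sizes[membership[name]][int(typ)] += 1
    internal = [0] * len(sizes)
    for edge in graph.es:
        a, b = names[edge.source], names[edge.target]
        if membership[a] == membership[b]:
            internal[membership[a]] += 1
    return float(
        sum(e - gamma * n_g * n_s for e, (n_g, n_s) in zip(internal, sizes))
    )


def subgraph_density(graph: ig.Graph, genes: Iterable, samples: Iterable) -> float:
    """Connectivity density e(genes ⊔ samples) / (|genes| * |samples|)."""
    genes, samples = set(genes), set(samples)
    if not genes or not samples:
        raise ValueError("gene and sample sets must be non-empty")
    sub = graph.induced_subgraph(
        [v.index for v in graph.vs if v["name"] in genes | samples]
    )
    return sub.ecount() / (len(genes) * len(samples))


def _leiden_bipartite(graph: ig.Graph, types, gamma: float, seed: int) -> np.ndarray:
    """Leiden/CPM on a bipartite graph; returns the vertex membership array.

    Uses the three-layer multiplex formulation (combined with layer weights
    [1, -1, -1]) whose joint quality equals sum_C (e(C) - gamma*|C_G|*|C_S|)
    up to a partition-independent constant. Optimisation starts from the
    all-singleton partition, so the returned quality is never below zero.
    """
    n = graph.vcount()
    s0 = [1 if t == 0 else 0 for t in types]
    s1 = [1 - v for v in s0]
    p01 = la.CPMVertexPartition(graph, node_sizes=[1] * n, resolution_parameter=gamma)
    p0 = la.CPMVertexPartition(ig.Graph(n), node_sizes=s0, resolution_parameter=gamma)
    p1 = la.CPMVertexPartition(ig.Graph(n), node_sizes=s1, resolution_parameter=gamma)
    opt = la.Optimiser()
    opt.set_rng_seed(int(seed))
    opt.optimise_partition_multiplex(
        [p01, p0, p1], layer_weights=[1, -1, -1], n_iterations=-1
    )
    return np.asarray(p01.membership)


def optimize_partition(graph: ig.Graph, gamma: float, seed: int = 0) -> Partition:
    """Locally optimal CPM partition of a bipartite mutation graph.

    Deterministic for a fixed seed. The resulting quality is >= 0, the
    score of the all-singleton partition.
    """
    if graph.vcount() == 0:
        raise ValueError("cannot partition an empty graph")
    names = graph.vs["name"]
    types = graph.vs["type"]
    membership = _leiden_bipartite(graph, types, gamma, seed)
    comms = []
    for cid in np.unique(membership):
        members = np.flatnonzero(membership == cid)
        genes = frozenset(names[v] for v in members if not types[v])
        samples = frozenset(names[v] for v in members if types[v])
        comms.append(Community(genes, samples))
    return Partition(comms, gamma)


def _incidence_graph(sub: np.ndarray) -> ig.Graph:
    """Bipartite graph of a 0/1 incidence block (rows=genes, cols=samples)."""
    return ig.Graph.Biadjacency(sub.tolist())


@dataclass
class IterativePartitionResult:
    """Candidate gene combinations from one iterative-partitioning pass."""

    combinations: set
    optimizer_calls: int
    n_unsplit_discarded: int


def iterative_partition(
    matrix: MutationMatrix,
    l: int,
    u: int,
    seed: int = 0,
    scope: str = "tumor_only",
) -> IterativePartitionResult:
    """One pass of iterative size-constrained partitioning of G^tum.

    The whole graph is partitioned at gamma equal to its density; every
    community whose gene component exceeds ``u`` genes is re-partitioned on
    the subgraph over its genes and the union of their tumor mutation
    sample sets, at that subgraph's density, until all gene components fit.
    Components smaller than ``l`` are discarded. An oversized community
    that the optimiser fails to split is discarded with a warning rather
    than refined forever, which also keeps the number of optimiser calls
    at or below the number of genes.
    """
    if not 1 <= l <= u:
        raise ValueError(f"hit range requires 1 <= l <= u, got l={l}, u={u}")
    cols = _scope_sample_indices(matrix, scope)
    D = matrix.data[:, cols].astype(bool)
    gene_names = np.asarray(matrix.gene_ids)
    rng = np.random.default_rng(seed)

    results: set = set()
    calls = 0
    unsplit = 0
    # (gene row indices, sample column indices into the scoped view)
    stack: list[tuple[np.ndarray, np.ndarray]] = [
        (np.arange(D.shape[0]), np.arange(D.shape[1]))
    ]
    while stack:
        genes, samples = stack.pop()
        sub = D[np.ix_(genes, samples)]
        n_edges = int(sub.sum())
        if n_edges == 0 or samples.size == 0:
            continue
        gamma = n_edges / (genes.size * samples.size)
        graph = _incidence_graph(sub)
        calls += 1
        call_seed = int(rng.integers(2**31))
        types = [0] * genes.size + [1] * samples.size
        membership = _leiden_bipartite(graph, types, gamma, call_seed)
        mem_g = membership[: genes.size]
        for cid in np.unique(mem_g):
            cg = genes[mem_g == cid]
            if cg.size > u:
                if cg.size == genes.size:
                    unsplit += 1
                    logger.debug(
                        "discarding unsplittable community of %d genes (u=%d)",
                        cg.size,
                        u,
                    )
                    continue
                ext = np.flatnonzero(D[cg].any(axis=0))
                stack.append((cg, ext))
            elif cg.size >= l:
                results.add(frozenset(map(str, gene_names[cg])))
    return IterativePartitionResult(results, calls, unsplit)


@dataclass
class CandidatePool:
    """Deduplicated gene combinations pooled over independent passes.

    ``combinations`` maps each gene set (frozenset of gene ids) to the
    number of passes in which it was produced.
    """

    combinations: dict
    passes: int
    l: int
    u: int
    optimizer_calls: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.combinations)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (",".join(sorted(c)), len(c), n) for c, n in self.combinations.items()
        )
        return pd.DataFrame(rows, columns=["genes", "h", "n_passes_found"])


def build_candidate_pool(
    matrix: MutationMatrix,
    l: int,
    u: int,
    p: int,
    base_seed: int = 0,
    scope: str = "tumor_only",
) -> CandidatePool:
    """Union of ``p`` independent iterative-partitioning passes.

    Pass k uses seed ``base_seed + k``, so the pool is reproducible and
    independent of the order in which passes are run.
    """
    if p < 1:
        raise ValueError("number of passes p must be >= 1")
    combos: dict = {}
    calls = []
    for k in range(p):
        res = iterative_partition(matrix, l, u, seed=base_seed + k, scope=scope)
        calls.append(res.optimizer_calls)
        for c in res.combinations:
            combos[c] = combos.get(c, 0) + 1
    return CandidatePool(combos, p, l, u, calls)


def write_pool(pool: CandidatePool, path) -> None:
    """Serialize a pool (TSV, or JSON records if the path ends in .json).

    Both layouts carry the fields genes (comma-joined, sorted), h, and
    n_passes_found.
    """
    frame = pool.to_frame()
    if str(path).endswith(".json"):
        frame.to_json(path, orient="records", indent=2)
    else:
        frame.to_csv(path, sep="\t", index=False)
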