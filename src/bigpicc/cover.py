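"""Tumor-ratio filtering and greedy minimum set cover of tumor samples.

Each pooled candidate combination C_G is scored by its tumor ratio

    r(C_G) = |M^tum(C_G)| / |M(C_G)|,

the share of tumor samples among all samples in which the combination is
jointly mutated. Candidates below a threshold rho are filtered out; from
the survivors K_rho the final carcinogenic set is chosen as an (approximate)
minimum set cover of the tumor samples they jointly explain, using the
standard greedy heuristic: at each step pick the candidate covering the
most yet-unexplained tumor samples. The greedy solution size is within a
factor ln(m) of the optimum, where m is the largest tumor cover of any
single filtered candidate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .community import CandidatePool
from .matrix import MutationMatrix, joint_mutation_samples

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredCandidate",
    "CoverSolution",
    "score_candidates",
    "filter_candidates",
    "greedy_min_cover",
    "write_solution",
]


@dataclass(frozen=True)
class ScoredCandidate:
    """A candidate combination with its joint-mutation covers and tumor ratio."""

    genes: tuple
    all_cover: frozenset
    tumor_cover: frozenset
    tumor_ratio: float
    n_passes_found: int = 1

    @property
    def h(self) -> int:
        return len(self.genes)


@dataclass
class CoverSolution:
    """Greedy cover of the tumor samples explained by filtered candidates.

    ``selected`` is in greedy pick order; ``newly_covered[i]`` holds the
    tumor samples first explained by ``selected[i]``.
    """

    selected: list
    newly_covered: list
    covered_samples: frozenset
    target: frozenset
    rho: float
    m: int

    @property
    def combinations(self) -> list:
        return [frozenset(c.genes) for c in self.selected]


def score_candidates(pool: CandidatePool, matrix: MutationMatrix) -> list:
    """Compute covers and tumor ratios for every pooled combination.

    Covers are recomputed from the matrix (not taken from the communities
    that produced the candidates). Combinations with an empty joint cover
    are dropped, since their 0/0 tumor ratio is undefined and they can
    explain nothing.
    """
    out = []
    n_dropped = 0
    for genes, n_passes in pool.combinations.items():
        all_cover = joint_mutation_samples(matrix, genes, scope="all")
        if not all_cover:
            n_dropped += 1
            continue
        tumor_cover = frozenset(
            s for s in all_cover if matrix.is_tumor[matrix.sample_index(s)]
        )
        out.append(
            ScoredCandidate(
                tuple(sorted(genes)),
                all_cover,
                tumor_cover,
                len(tumor_cover) / len(all_cover),
                n_passes,
            )
        )
    if n_dropped:
        logger.info("dropped %d candidates with empty joint cover", n_dropped)
    out.sort(key=lambda c: c.genes)
    return out


def filter_candidates(candidates, rho: float) -> list:
    """Keep candidates with tumor ratio >= rho (K_rho; rho=0 keeps all)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    return [c for c in candidates if c.tumor_ratio >= rho]


def greedy_min_cover(filtered, rho: float = 0.0) -> CoverSolution:
    """Greedily cover the tumor samples explained by the filtered candidates.

    The target is the union of the candidates' tumor covers. Ties on new
    coverage break toward higher tumor ratio, then smaller combination
    size, then lexicographic gene order, so output is deterministic.
    """
    filtered = list(filtered)
    target = frozenset().union(*(c.tumor_cover for c in filtered)) if filtered else frozenset()
    m = max((len(c.tumor_cover) for c in filtered), default=0)
    selected: list = []
    newly: list = []
    covered: set = set()
    remaining = list(filtered)
    while covered != set(target):
        gain = max(len(c.tumor_cover - covered) for c in remaining)
        ties = [c for c in remaining if len(c.tumor_cover - covered) == gain]
        ties.sort(key=lambda c: (-c.tumor_ratio, c.h, c.genes))
        best = ties[0]
        new = frozenset(best.tumor_cover - covered)
        if not new:
            raise RuntimeError("greedy step covered no new samples")
        selected.append(best)
        newly.append(new)
        covered |= new
        remaining.remove(best)
    return CoverSolution(selected, newly, frozenset(covered), target, rho, m)


def write_solution(solution: CoverSolution, tsv_path, json_path=None, matrix=None) -> None:
    """Write the cover report as TSV (and optionally a JSON mirror).

    The JSON mirror includes the tumor samples left uncovered, computed
    against ``matrix`` when one is given (tumor samples no filtered
    candidate explains).
    """
    rows = [
        {
            "rank": i + 1,
            "genes": ",".join(c.genes),
            "h": c.h,
            "tumor_ratio": c.tumor_ratio,
            "n_tumor_covered": len(c.tumor_cover),
            "n_new_covered": len(new),
        }
        for i, (c, new) in enumerate(zip(solution.selected, solution.newly_covered))
    ]
    pd.DataFrame(
        rows,
        columns=["rank", "genes", "h", "tumor_ratio", "n_tumor_covered", "n_new_covered"],
    ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        uncovered = []
        if matrix is not None:
            uncovered = sorted(set(matrix.tumor_sample_ids) - solution.covered_samples)
        payload = {
            "rho": solution.rho,
            "m": solution.m,
            "combinations": [list(c.genes) for c in solution.selected],
            "n_covered": len(solution.covered_samples),
            "uncovered_tumor_samples": uncovered,
        }
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
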