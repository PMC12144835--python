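"""Synthetic mutation data with planted driver/passenger structure.

The generator emulates the validation model used to probe whether the
pipeline can tell drivers from near-perfectly co-occurring passengers:
every gene-sample entry mutates independently at a baseline rate of 4.1%
(a typical average per-gene mutation rate in tumor cohorts); a planted
combination of h driver genes is
mutated in 100% of tumor samples; a set of passenger genes is mutated with
99% probability per sample. With 1000 tumor samples a passenger is expected
to miss roughly ten samples, which is exactly the signal that separates it
from a true driver.

The standard validation grid crosses h in 3..8 with passenger counts 0, h,
10h and 100h (24 experiments), runs the pipeline on tumor-only data with
rho = 1 and hit range l = u = h, and asks whether the greedy cover is a
single combination equal to the planted driver set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .community import build_candidate_pool
from .cover import filter_candidates, greedy_min_cover, score_candidates
from .matrix import NORMAL, TUMOR, MutationMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_synthetic",
    "validation_grid",
    "make_toy_fixture",
    "run_validation_cell",
    "run_validation_grid",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic experiment."""

    n_genes: int = 20000
    n_tumor_samples: int = 1000
    n_normal_samples: int = 0
    baseline_rate: float = 0.041
    h: int = 0
    driver_rate: float = 1.0
    n_passengers: int = 0
    passenger_rate: float = 0.99
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_rate", "driver_rate", "passenger_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.h + self.n_passengers > self.n_genes:
            raise ValueError(
                f"h + n_passengers = {self.h + self.n_passengers} exceeds "
                f"n_genes = {self.n_genes}"
            )


@dataclass
class SyntheticDataset:
    """Generated matrix plus the planted ground truth."""

    matrix: MutationMatrix
    driver_genes: frozenset
    passenger_genes: frozenset
    config: SyntheticConfig

    def write_truth(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "driver_genes": sorted(self.driver_genes),
                    "passenger_genes": sorted(self.passenger_genes),
                    "config": asdict(self.config),
                },
                fh,
                indent=2,
            )


def generate_synthetic(config: SyntheticConfig) -> SyntheticDataset:
    """Sample a mutation matrix under the driver/passenger/background model.

    Background mutations are independent Bernoulli(baseline_rate) for every
    gene-sample pair. Driver genes additionally mutate in each tumor sample
    with probability driver_rate (1.0 plants them in every tumor sample);
    passenger genes additionally mutate in every sample with probability
    passenger_rate. Driver and passenger events are unioned with the
    background layer. Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_s = config.n_tumor_samples + config.n_normal_samples
    data = rng.random((config.n_genes, n_s)) < config.baseline_rate

    special = rng.choice(
        config.n_genes, size=config.h + config.n_passengers, replace=False
    )
    drivers, passengers = special[: config.h], special[config.h :]
    tumor_cols = np.arange(config.n_tumor_samples)
    if drivers.size:
        data[np.ix_(drivers, tumor_cols)] |= (
            rng.random((drivers.size, tumor_cols.size)) < config.driver_rate
        )
    if passengers.size:
        data[passengers] |= rng.random((passengers.size, n_s)) < config.passenger_rate

    width = len(str(max(config.n_genes - 1, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    sample_ids = [f"t{j:04d}" for j in range(config.n_tumor_samples)] + [
        f"n{j:04d}" for j in range(config.n_normal_samples)
    ]
    labels = [TUMOR] * config.n_tumor_samples + [NORMAL] * config.n_normal_samples
    matrix = MutationMatrix(gene_ids, sample_ids, labels, data.astype(np.uint8))
    return SyntheticDataset(
        matrix,
        frozenset(gene_ids[i] for i in drivers),
        frozenset(gene_ids[i] for i in passengers),
        config,
    )


def validation_grid(
    h_values: Sequence[int] = (3, 4, 5, 6, 7, 8),
    passenger_multipliers: Sequence[int] = (0, 1, 10, 100),
    n_genes: int = 20000,
    n_tumor_samples: int = 1000,
    base_seed: int = 0,
) -> list:
    """Configs for the driver-passenger validation grid (24 cells at defaults).

    Each cell plants h drivers (mutated in every tumor sample) and
    multiplier*h passengers (99% per sample) on a 4.1% background over
    tumor-only data.
    """
    if not h_values or not passenger_multipliers:
        raise ValueError("h_values and passenger_multipliers must be non-empty")
    configs = []
    for i, h in enumerate(h_values):
        for j, mult in enumerate(passenger_multipliers):
            configs.append(
                SyntheticConfig(
                    n_genes=n_genes,
                    n_tumor_samples=n_tumor_samples,
                    n_normal_samples=0,
                    baseline_rate=0.041,
                    h=h,
                    driver_rate=1.0,
                    n_passengers=mult * h,
                    passenger_rate=0.99,
                    seed=base_seed + i * len(passenger_multipliers) + j,
                )
            )
    return configs


def run_validation_cell(config: SyntheticConfig, passes: int = 100) -> dict:
    """Run the tumor-only pipeline at rho=1 on one grid cell.

    Uses hit range l = u = h (the planted size is the quantity under test)
    and reports whether the greedy cover is a sole combination equal to the
    planted driver set.
    """
    data = generate_synthetic(config)
    pool = build_candidate_pool(
        data.matrix,
        l=config.h,
        u=config.h,
        p=passes,
        base_seed=config.seed,
        scope="tumor_only",
    )
    scored = score_candidates(pool, data.matrix)
    solution = greedy_min_cover(filter_candidates(scored, 1.0), 1.0)
    recovered = solution.combinations
    success = len(recovered) == 1 and recovered[0] == data.driver_genes
    return {
        "h": config.h,
        "n_passengers": config.n_passengers,
        "n_genes": config.n_genes,
        "n_tumor_samples": config.n_tumor_samples,
        "seed": config.seed,
        "pool_size": len(pool),
        "cover_size": len(recovered),
        "driver_set_recovered": bool(success),
    }


def run_validation_grid(
    n_genes: int = 20000,
    passes: int = 100,
    seed: int = 0,
    h_values: Sequence[int] = (3, 4, 5, 6, 7, 8),
    passenger_multipliers: Sequence[int] = (0, 1, 10, 100),
    n_tumor_samples: int = 1000,
) -> dict:
    """Run every cell of the validation grid and aggregate successes."""
    cells = [
        run_validation_cell(cfg, passes=passes)
        for cfg in validation_grid(
            h_values,
            passenger_multipliers,
            n_genes=n_genes,
            n_tumor_samples=n_tumor_samples,
            base_seed=seed,
        )
    ]
    return {
        "cells": cells,
        "n_cells": len(cells),
        "n_success": sum(c["driver_set_recovered"] for c in cells),
    }


# -- deterministic toy fixtures used across the test-suite ----------------


def _planted_biclique_4x30() -> MutationMatrix:
    # 4 driver genes jointly mutated in the first 30 of 60 tumor samples,
    # on a sparse random background over 40 genes.
    rng = np.random.default_rng(1234)
    n_g, n_s = 40, 60
    data = (rng.random((n_g, n_s)) < 0.04).astype(np.uint8)
    data[:4, :30] = 1
    genes = [f"g{i:02d}" for i in range(n_g)]
    samples = [f"t{j:02d}" for j in range(n_s)]
    return MutationMatrix(genes, samples, [TUMOR] * n_s, data)


def _disjoint_covers() -> MutationMatrix:
    # Two 2-gene combinations with pairwise-disjoint joint-mutation covers:
    # {gA, gB} jointly mutated in t0, t1, t2 and n0 (ratio 3/4);
    # {gC, gD} jointly mutated in t3, t4, t5 (ratio 1).
    genes = ["gA", "gB", "gC", "gD"]
    samples = ["t0", "t1", "t2", "t3", "t4", "t5", "n0", "n1", "n2", "n3"]
    labels = [TUMOR] * 6 + [NORMAL] * 4
    data = np.zeros((4, 10), dtype=np.uint8)
    data[0, [0, 1, 2, 6]] = 1  # gA
    data[1, [0, 1, 2, 6]] = 1  # gB
    data[2, [3, 4, 5]] = 1  # gC
    data[3, [3, 4, 5]] = 1  # gD
    return MutationMatrix(genes, samples, labels, data)


def _greedy_vs_optimal() -> MutationMatrix:
    # Single-gene candidate covers over six tumor samples reproducing the
    # classic instance where greedy picks 3 sets but the optimum is 2:
    # {1,2,3,4}, {1,2,5}, {3,4,6}, {5}, {6}.
    covers = [(0, 1, 2, 3), (0, 1, 4), (2, 3, 5), (4,), (5,)]
    genes = [f"g{i}" for i in range(len(covers))]
    samples = [f"t{j}" for j in range(6)]
    data = np.zeros((len(covers), 6), dtype=np.uint8)
    for i, cov in enumerate(covers):
        data[i, list(cov)] = 1
    return MutationMatrix(genes, samples, [TUMOR] * 6, data)


def _empty() -> MutationMatrix:
    return MutationMatrix(
        ["g0", "g1", "g2"],
        ["t0", "t1", "n0", "n1"],
        [TUMOR, TUMOR, NORMAL, NORMAL],
        np.zeros((3, 4), dtype=np.uint8),
    )


_FIXTURES = {
    "planted_biclique_4x30": _planted_biclique_4x30,
    "disjoint_covers": _disjoint_covers,
    "greedy_vs_optimal": _greedy_vs_optimal,
    "empty": _empty,
}


def make_toy_fixture(name: str) -> MutationMatrix:
    """Small deterministic hand-built matrices used across unit tests."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
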