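# Methods

## Problem and model

The package identifies *multi-hit* carcinogenic gene combinations: sets of
2–9 genes whose joint mutation in a sample is hypothesised to initiate
carcinogenesis. The input is a binary incidence matrix `D` over genes
(rows) and samples (columns), `D[g, s] = 1` iff a protein-altering
mutation of gene `g` was observed in sample `s`, with each sample labelled
tumor or normal. Exhaustively scoring all C(|G|, h) gene combinations is
infeasible beyond h ≈ 4 (C(20000, 5) > 2.6·10^19), so the search is
reformulated as community detection on the bipartite mutation graph: gene
and sample vertices, one edge per observed mutation, adjacency
`[[0, D], [D^T, 0]]`. A carcinogenic combination C_G jointly mutated in
tumor samples M^tum(C_G) appears as a dense biclique-like community
C_G ⊔ M^tum(C_G) in the tumor-restricted graph G^tum, whereas an unrelated
gene mutated in a fraction f of tumor samples joins such a community only
with probability f^k (k = |M^tum(C_G)|; ≈ 0.001 at f = 0.5, k = 10).

## Pipeline

1. **Candidate pooling.** G^tum is partitioned under the bipartite
   Constant Potts Model quality Q(P) = Σ_C (e(C) − γ·|C_G|·|C_S|),
   optimised with the Leiden algorithm. The resolution γ is always set to
   the connectivity density of the (sub)graph being partitioned — the
   pipeline therefore has no free resolution parameter. Communities whose
   gene component exceeds the maximum hit count `u` are re-partitioned on
   the subgraph induced by their genes plus every tumor sample those genes
   mutate, again at that subgraph's own density; components below the
   minimum `l` are discarded. Each refinement strictly shrinks the gene
   set, so a pass makes at most |G| optimiser calls (tracked by an
   instrumented counter and asserted in tests). Because Leiden is
   randomised, `p` independent seeded passes are pooled and deduplicated
   by gene set.
2. **Tumor-ratio filtering.** Each pooled combination is scored by
   r(C_G) = |M^tum(C_G)| / |M(C_G)|, recomputed from the matrix rather
   than taken from the community that produced it; candidates with
   r < ρ are removed. Candidates with an empty joint cover are dropped at
   scoring (their ratio is 0/0 and they can explain nothing).
3. **Greedy minimum set cover.** From the filtered pool K_ρ the final set
   𝒞_ρ is chosen to cover the union of the candidates' tumor covers: at
   each step the candidate explaining the most yet-uncovered tumor
   samples is selected (ties: higher tumor ratio, then fewer genes, then
   lexicographic gene order, making output deterministic). The greedy
   solution is within a factor ln(m) of the optimal cover size, where m
   is the largest single-candidate tumor cover; tests audit this bound
   against a brute-force exact cover oracle on small instances.
4. **Classification.** A sample is predicted tumor iff it jointly mutates
   at least one selected combination. With ρ = "auto", 25% of samples are
   held out, and ρ is learned on the rest by stratified 4-fold
   cross-validation over the grid 0.00–1.00 (step 0.01, 101 points),
   selecting the ρ with the highest mean held-out Matthews correlation
   coefficient. One candidate pool is built per fold and reused across
   the whole grid, since filtering and covering are cheap relative to
   pooling.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `min_hits`, `max_hits` (l, u) | bounds on combination size | 2, 7 | literature-derived per cancer type; supplied by the user |
| `passes` (p) | pooled partitioning passes | 100 | matches the synthetic-validation protocol; production runs may use 10,000 |
| `rho` (ρ) | tumor-ratio threshold | `"auto"` | learned by CV; ρ=1 keeps only combinations never jointly mutated in normals |
| `folds` | CV folds | 4 | standard protocol for the threshold search |
| `random_state` | seed | 0 | pass k of a pool uses seed `base+k`, so pooling is order-independent |

## Statistical properties

ρ implicitly controls precision: when selected combinations have pairwise
disjoint joint-mutation covers, precision ≥ ρ and specificity is bounded
below by 1 − (1−ρ)r/((1−r)ρ), where r is the tumor fraction of the data.
Both bounds are exercised on a constructed disjoint-cover fixture. MCC is
computed in the standard phi-coefficient form with a zero-denominator → 0
convention (flagged as degenerate), keeping it within [−1, 1]; tests check
its swap-symmetry and negation identities and cross-check values against
scikit-learn.

## Numerical and design choices

* **Optimiser backend.** CPM optimisation delegates to leidenalg's
  three-layer bipartite multiplex (layer weights [1, −1, −1]), whose
  combined quality equals the bipartite CPM up to a partition-independent
  constant; an independent `cpm_quality` implementation verifies this
  against brute-force enumeration in the tests. The refinement loop is
  implemented here, treating Leiden as a black box with a local-optimality
  contract (optimisation runs to convergence, `n_iterations=-1`).
* **Degenerate resolutions.** A subgraph of density 0 is discarded without
  an optimiser call. A complete biclique has density 1, so γ = 1 makes
  every community contribute exactly 0; the optimiser is still run and the
  resulting all-singleton partition simply yields no candidates. Dense but
  incomplete communities split off their weakest members instead.
* **Non-splitting refinement.** If re-partitioning an oversized community
  returns its entire gene set as one community, that community is
  discarded with a warning rather than refined again: refinement then
  always strictly shrinks the gene set, guaranteeing termination and the
  ≤ |G| call bound unconditionally.
* **Tie-breaks.** Cover selection ties and equal-MCC ρ grid points are
  broken deterministically (largest ρ wins, favouring the stronger
  precision bound and matching the observation that learned thresholds
  sit near 1).
* **Combination representation.** Gene combinations are plain
  frozensets/sorted tuples of gene identifiers; deduplication across
  passes is by gene set only, with covers recomputed from the matrix.

## Synthetic data generator

The generator emulates the driver/passenger validation model: independent
Bernoulli(0.041) background mutations for every gene-sample pair (a
typical average per-gene mutation rate in tumor cohorts), h planted
driver genes mutated in every tumor sample
(driver_rate = 1.0), and passenger genes mutated with probability 0.99 in
every sample. Driver and passenger events are unioned with the background
layer; driver mutations are restricted to tumor columns, passengers apply
to all samples. The validation grid crosses h ∈ {3..8} with passenger
counts {0, h, 10h, 100h} — 24 experiments on tumor-only data — and runs
the pipeline with ρ = 1 and hit range l = u = h, the planted size being
the quantity under test. Success means the greedy cover is a single
combination equal to the planted driver set.

What the generator does *not* emulate: mutational signatures, per-gene
rate heterogeneity, hypermutated samples, sub-gene mutation resolution,
and correlated mutation processes. Passing the synthetic grid therefore
demonstrates the driver/passenger distinction under idealised
independence assumptions, not performance on real cohorts.

A known, intentional failure mode: when tumor samples are few, some
passengers are mutated in *every* tumor sample (probability 0.99^n per
passenger) and become information-theoretically indistinguishable from
drivers; the reduced-sample test logs this outcome rather than asserting
it away.

## Problem sizes

The test-suite and the acceptance script run the validation grid at a
2,000-gene scale with 10 passes per cell and the full sample count
(1000 tumor samples), which preserves the driver/passenger signal (the
separation depends on the sample count, not the gene count) while keeping
a full 24-cell run in the minutes range on one CPU. The full 20,000-gene,
100-pass configuration is available through the library and the
`bigpicc validate-grid` command.

## Limitations

* Gene-level binarisation ignores which mutation within a gene occurred.
* Candidates are only as good as the community structure: combinations
  whose joint cover is tiny may never form a community that survives
  refinement.
* The ln(m) guarantee applies to the cover size, not to the biological
  relevance of the chosen combinations; near-duplicate candidates with
  equal coverage are resolved by tie-break, not by evidence.
* Cross-validation of ρ requires both classes in every fold; tumor-only
  data supports only fixed-ρ runs.
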