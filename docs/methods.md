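# Methods

## Biological distance on a confidence-weighted interactome

The package models functional relatedness between genes as shortest-path
distance on an undirected network whose edges carry an interaction
confidence `c ∈ (0, 1]`. The default edge weight is the reciprocal
`w = 1/c`, so a maximally confident interaction (`c = 0.999`) costs 1.001
distance units and rank-1 direct neighbors in a genome-scale network sit at
distance ≈ 1 — the calibration that matches published candidate tables. A
`-log c` transform is selectable; it rejects `c = 1.0` exactly, because a
zero-weight edge would break the strict positivity that shortest-path
ranking requires. Duplicate edge rows are reduced to the maximum
confidence, self-loops are dropped, and symbols are normalized by
trim + upper-case only (no alias resolution: if two data sources disagree
about a symbol, that disagreement is surfaced, not papered over).

Two shortest-path backends serve different needs. Route-reporting queries
use a hand-written Dijkstra whose heap priority is the triple
`(distance, edge count, route)`: the first label settled at a node is the
minimum-distance path with the fewest edges and, among those, the
lexicographically smallest gene sequence. This makes every reported route
reproducible across runs and platforms, which a generic library routine
does not guarantee. Statistical layers that need only large batches of
distances use `scipy.sparse.csgraph.dijkstra` over the whole network,
cached per network object. Because floating-point summation order differs
per direction, the cached matrix is symmetrized with an elementwise
minimum; a test asserts the two backends agree to 1e-9. Unreachable pairs
are represented explicitly (`inf` / empty route), never substituted with a
large finite number; each downstream stage decides its own policy
(exclusion with a logged count).

## Connectomes and percentile p-values

The connectome of a core gene ranks all reachable genes by ascending
distance (ties broken by symbol) and assigns `p = rank / N_ref`. `N_ref`
is a policy choice: the default counts all *other* genes in the network,
which reproduces hand-enumerable small cases exactly and is
indistinguishable from including the core gene at the 5-decimal precision
used in genome-scale reporting (1/14131 and 1/14130 both round to
0.00007). The alternatives ("network", "reachable", or an explicit
denominator) are recorded in output metadata.

## Clustering permutation test

A gene set's compactness is summarized by the median of its pairwise
distances (unreachable pairs excluded, logged). The null distribution is
built by drawing `n_sims` same-size gene sets uniformly without replacement
from all network genes — including core genes, matching the usual "all
human genes" sampling frame; excluding the observed set is a flag. The
empirical p is the fraction of null medians *strictly* smaller than the
observed one; with zero hits the result carries the resolution bound
`p < 1/n_sims`. A `(hits+1)/(sims+1)` pseudo-count correction is available
but off by default, since the strict fraction is what published analyses
report. Sampling is vectorized over the cached distance matrix (random
keys + argpartition give uniform subsets), so 10,000 simulations on a
500-gene network take ~2 s. Distance-bin profiles use half-open bins
[0,10), [10,20), [20,30), [30,40), [40,∞) — 20 being the typical median
distance between random gene pairs on real interactomes — with boundary
values going to the upper bin; the edge convention is declared here because
bin descriptions in the literature rarely state it.

## Candidate funnel

Top-percentile selection is strict `p < α` per connectome, pooled across
core genes. The pre-deduplication occurrence count is reported because the
funnel totals (occurrences → deduplicated → function-filtered) are the
headline numbers of this kind of analysis. Deduplication keeps, per
candidate, the occurrence with smallest p, breaking ties by smaller
distance then lexicographic core symbol, so the "closest core gene"
annotation is deterministic.

GO enrichment of the core set uses the plain one-tailed hypergeometric
tail `P(X ≥ k)` (population: all annotated network genes by default,
configurable). Two deliberate deviations from popular enrichment servers:
no EASE-style `k−1` penalty (available behind a flag) and no
multiple-testing correction by default (Benjamini–Hochberg behind a flag),
because the procedure's published form selects on raw `p < 0.05`. The
threshold is configurable — analyses of this type have used both 0.05 and
0.01. The function filter then keeps candidates carrying ≥ 1 enriched
term; unannotated candidates are removed like any other non-match, with a
logged count.

## Held-out validation

With `N` background genes (network minus core, configurable), `K`
candidates, `n` held-out genes and `k` hits, the package reports both the
exact tail `P(X ≥ k)` and an empirical estimate. The default Monte-Carlo
path samples the hit count directly from its exact null law with
`numpy.random.Generator.hypergeometric` — distributionally identical to
materializing each random `n`-subset and counting the intersection, but
fast enough for 10⁷ draws in seconds; an explicit subset-materializing
path (`method="subsets"`) exists and a test checks the two agree within
Monte-Carlo error. Zero-hit simulations are reported as the bound
`p < 1/n_sims`.

## Neighbor-joining FGA tree

The functional-genomic-alignment tree applies canonical neighbor joining
(Saitou–Nei with the Studier–Keppler criterion
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`) to the biological-distance matrix of
core + candidate genes. NJ is implemented in-package because two behaviors
had to be pinned down: exact Q ties are broken by the lexicographically
smallest cluster-label pair (a cluster is labeled by its smallest leaf),
and negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch — at the final trifurcation, where there is no
single sibling, the deficit is split equally between the other two
branches. The Q matrix is symmetrized (elementwise minimum) before the
argmin because subtraction order can break symmetry by one ulp. Genes
causing infinite matrix entries are dropped greedily (most infinite
partners first, ties lexicographic) rather than imputed. Trees are held as
dendropy objects and serialized to Newick with 6 significant digits;
labels with reserved characters are quoted. scikit-bio's `nj` serves as an
independent oracle in the test suite, never as the implementation. NJ is
O(n³); the tested surface is ≤ 500 leaves, which a desk machine handles in
seconds.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes, not
any particular organismal dataset: a planted-partition (stochastic block)
graph — the simplest model producing the tight disease-gene sub-clusters
the method exploits — with equal-size modules (remainder to the last),
uniform confidences, and flat module-homed annotation terms plus a
catch-all term guaranteeing annotation coverage. Default parameters are
the package's documented study conditions: 500 genes, 5 modules,
`p_within = 0.5`, `p_between = 0.005`, confidences in (0.5, 0.999], one
disease module contributing 50 core and 10 held-out genes, 50 terms with
affinity 0.9 and background rate 0.05. The core set is deliberately a
large fraction of its pathway, mirroring phenotypes whose known genes
densely cover a few pathways; with the default top-1 % cutoff on a
500-gene network (rank ≤ 4 per core gene), 50 cores are what gives the
funnel a realistic chance of tiling the module. One world seed is split
via `numpy.random.SeedSequence.spawn` into child seeds consumed in a fixed
order (edges → gene sets → annotations), so identical parameters and seed
reproduce the world edge-for-edge and stages can be regenerated
independently.

What the generator does *not* emulate: scale-free degree distributions,
GO's DAG topology (terms are flat labels), annotation biases, or symbol
aliasing. Passing tests on synthetic worlds therefore demonstrate the
correctness and calibration of the machinery under the planted-module
model, not predictive performance on real interactomes.

## Numerical and degenerate-input choices

- Percentile ranks are validated against `1 ≤ rank ≤ N_ref`; an isolated
  core gene yields an empty connectome with a warning.
- Empty distance lists produce an explicit empty bin profile; negative or
  non-finite distances raise.
- A gene set covering the entire network makes the permutation test
  degenerate (every null median equals the observed median); the test
  warns and reports zero hits.
- Discrete hypergeometric p-values are conservative (super-uniform under
  the null); the calibration tests allow for that shift.
- The pipeline derives per-stage seeds from the single config seed by
  fixed offsets (clustering +1, holdout +2) and echoes every threshold and
  seed into each artifact's metadata header; stripped of headers, reruns
  are byte-identical. A `RUN.partial` marker in the output directory
  flags aborted runs.

## Test problem sizes

Unit tests run on toy graphs and 120–300-gene worlds. The acceptance
tests use: exhaustive 4-node weighted and 5-node unit-weight graphs plus
random ≤ 8-node graphs against an all-simple-paths oracle; 500 calibration
replicates at 200 simulations each; 20 replicate 500-gene planted worlds
at 10,000 simulations each; NJ recovery for 4–12 taxa; full hypergeometric
enumeration for populations ≤ 25; and 10⁷ Monte-Carlo draws for the
held-out enrichment bound. These sizes were chosen so the whole suite
completes in a few minutes on a single core while leaving each statistical
check enough resolution to fail loudly if the implementation drifts.
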