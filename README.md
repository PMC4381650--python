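# geneconnectome

Disease-gene prioritization on a weighted gene-interaction network.

Clinical sequencing of a patient with a suspected Mendelian disorder yields
thousands of candidate variants, and checking them only against the short
list of genes already proven to cause the phenotype misses every
yet-undiscovered disease gene. `geneconnectome` implements the
guilt-by-association alternative: starting from a *core set* of established
disease genes, it ranks every other gene in a genome-scale interaction
network by shortest-path **biological distance** to each core gene, keeps
the top percentile of neighbors, filters them by shared biological function
(GO-term enrichment of the core set), and validates the resulting candidate
list against an independently discovered held-out gene set. It is written
for computational geneticists who want the whole procedure as a tested,
reproducible library plus CLI rather than a chain of web services.

## Model and statistics

* **Network.** An undirected graph over gene symbols; each edge carries an
  interaction confidence `c ∈ (0, 1]` and weight `w = 1/c` (a `-log c`
  transform is also available). The biological distance `d(a, b)` is the
  minimum total weight over paths from `a` to `b`; the *route* is the gene
  sequence realizing it and the *degrees of separation* its edge count.
  Dijkstra ties are broken deterministically: fewer edges first, then the
  lexicographically smallest route.
* **Connectome.** For a core gene `g`, all reachable genes sorted by
  `d(g, ·)` with 1-based rank `r` and percentile p-value `p = r / N_ref`,
  where `N_ref` defaults to the number of other genes in the network.
* **Clustering test.** Whether a gene set is biologically compact: its
  median pairwise distance is compared against medians of `n_sims` random
  same-size gene sets; the empirical p-value is the fraction of null
  medians strictly smaller than the observed one.
* **Candidate funnel.** Pool all connectome entries with `p < α`
  (default `α = 0.01`, the top 1 %), drop core genes, keep one best
  occurrence per gene, then retain only candidates annotated with at least
  one GO term over-represented in the core set (one-tailed hypergeometric
  tail `P(X ≥ k)`, raw `p < 0.05` by default).
* **Validation.** For a held-out gene set, the exact hypergeometric tail for
  the number of held-out genes inside the candidate list, plus an empirical
  estimate from random draws.
* **FGA tree.** A "functional genomic alignment": neighbor joining
  (Saitou–Nei, Studier–Keppler Q) applied to the biological-distance matrix
  of core + candidate genes, emitted as Newick.

Because the real genome-scale inputs live behind external services, the
package ships a first-class synthetic generator: a planted-partition
interactome with module-correlated GO annotations whose planted disease
module reproduces the statistical structure the method relies on.

## Worked example

Generate a synthetic study (500 genes, 5 modules, one planted disease
module with 50 known core genes and 10 held-out genes) and run the full
pipeline:

```bash
geneconnectome simulate --seed 7 --out-dir inputs
geneconnectome run \
    --edges inputs/edges.tsv --core inputs/core_genes.txt \
    --annotations inputs/annotations.tsv --holdout inputs/holdout_genes.txt \
    --out-dir out --n-sims 10000 --seed 7
```

prints

```
{"deduplicated": 50, "filtered": 49, "occurrences": 200}
artifacts in out
```

— the funnel counts: 200 top-1 % connectome entries across the 50 core
genes collapse to 50 distinct non-core candidates, of which 49 carry a
core-enriched GO term. The clustering test on the core set:

```
$ geneconnectome cluster-stats --edges inputs/edges.tsv \
      --genes inputs/core_genes.txt --n-sims 10000 --seed 8
observed median 1.925 over set of 50; 0/10000 null sets smaller (p < 0.0001)
```

i.e. no random 50-gene set was as biologically compact as the planted core
set. Held-out validation (`out/holdout.json`) reports 9 of the 10 held-out
disease genes inside the 49-gene candidate list drawn from a 450-gene
background, with exact tail `p_exact = 9.8e-09` and no random draw reaching
9 hits in 10,000 simulations (`p_empirical < 1e-4`). The candidate table
(`out/candidates_filtered.tsv`) mirrors the published layout:

```
candidate  closest_core  distance  rank  p        route              degrees
G0006      G0041         1.002     1     0.00200  G0041 <-> G0006    1
G0007      G0081         1.004     1     0.00200  G0081 <-> G0007    1
```

and `out/fga_tree.nwk` holds the 99-leaf neighbor-joining tree of core and
candidate genes. Every subcommand (`simulate`, `build-network`,
`connectome`, `cluster-stats`, `predict`, `go-filter`, `validate`,
`fga-tree`, `run`) is a thin wrapper over the library functions in
`geneconnectome`.

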