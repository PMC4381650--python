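"""Candidate extraction and functional (GO-enrichment) filtering.

The candidate stage pools, across the connectomes of all core (known
disease) genes, every gene in the top fraction ``alpha`` by percentile
p-value, removes core genes, and keeps a single best occurrence per
candidate.  The functional filter retains only candidates annotated with at
least one GO term over-represented in the core set, scored by a one-tailed
hypergeometric tail probability (the statistic behind Fisher's exact test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom

from .connectome import Connectome
from .network import ParameterError, coerce_members, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateRecord:
    """One predicted candidate and its closest core gene's connectome entry."""

    candidate: str
    closest_core: str
    distance: float
    rank: int
    p: float
    route: tuple[str, ...]
    degrees: int


@dataclass(frozen=True)
class CandidateExtraction:
    """Deduplicated candidate list plus the pre-dedup occurrence count.

    ``n_occurrences`` counts every top-``alpha`` connectome entry before core
    removal and deduplication — the first number of the reporting funnel
    (occurrences >= deduplicated >= filtered).
    """

    records: tuple[CandidateRecord, ...]
    n_occurrences: int

    @property
    def n_deduplicated(self) -> int:
        return len(self.records)

    def genes(self) -> tuple[str, ...]:
        return tuple(r.candidate for r in self.records)


def extract_candidates(
    connectomes: Mapping[str, Connectome],
    alpha: float,
    core_set: Iterable[str],
) -> CandidateExtraction:
    """Pool top-``alpha`` connectome entries into a non-redundant candidate list.

    Selection is strict (``p < alpha``).  Core genes are dropped; for a
    candidate reached from several cores the occurrence with smallest p wins
    (ties: smaller distance, then lexicographically smaller core symbol).
    Output is sorted by ``(p, candidate)``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    core = coerce_members(core_set)
    stray = sorted(set(connectomes) - core)
    if stray:
        raise ParameterError(
            f"connectome core genes not in the core set: {stray[:10]}"
        )

    n_occurrences = 0
    best: dict[str, tuple[tuple[float, float, str], CandidateRecord]] = {}
    for core_gene in sorted(connectomes):
        for entry in connectomes[core_gene].entries:
            if not entry.p < alpha:  # also skips NaN p
                continue
            n_occurrences += 1
            if entry.gene in core:
                continue
            key = (entry.p, entry.distance, core_gene)
            if entry.gene not in best or key < best[entry.gene][0]:
                best[entry.gene] = (
                    key,
                    CandidateRecord(
                        candidate=entry.gene,
                        closest_core=core_gene,
                        distance=entry.distance,
                        rank=entry.rank,
                        p=entry.p,
                        route=entry.route,
                        degrees=entry.degrees,
                    ),
                )
    records = tuple(
        sorted((rec for _, rec in best.values()), key=lambda r: (r.p, r.candidate))
    )
    return CandidateExtraction(records=records, n_occurrences=n_occurrences)


# ---------------------------------------------------------------------------
# GO annotations and enrichment
# ---------------------------------------------------------------------------

class GOAnnotationSet:
    """Gene -> GO-term annotations with the inverse term -> genes view.

    Terms are flat labels (no DAG propagation); the two mappings are kept
    mutually consistent by construction.
    """

    def __init__(
        self,
        gene_to_terms: Mapping[str, Iterable[str]],
        term_names: Mapping[str, str] | None = None,
    ):
        self._gene_to_terms: dict[str, frozenset[str]] = {}
        term_to_genes: dict[str, set[str]] = {}
        for gene, terms in gene_to_terms.items():
            g = normalize_symbol(gene)
            tset = frozenset(str(t).strip() for t in terms)
            self._gene_to_terms[g] = self._gene_to_terms.get(g, frozenset()) | tset
            for t in tset:
                term_to_genes.setdefault(t, set()).add(g)
        self._term_to_genes: dict[str, frozenset[str]] = {
            t: frozenset(gs) for t, gs in term_to_genes.items()
        }
        self.term_names: dict[str, str] = dict(term_names or {})

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        term_names: Mapping[str, str] | None = None,
    ) -> "GOAnnotationSet":
        gene_to_terms: dict[str, set[str]] = {}
        for gene, term in pairs:
            gene_to_terms.setdefault(gene, set()).add(term)
        return cls(gene_to_terms, term_names)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._gene_to_terms)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._term_to_genes)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self._gene_to_terms.get(normalize_symbol(gene), frozenset())

    def genes_of(self, term: str) -> frozenset[str]:
        return self._term_to_genes.get(term, frozenset())

    def name_of(self, term: str) -> str:
        return self.term_names.get(term, "")

    @property
    def n_annotations(self) -> int:
        return sum(len(t) for t in self._gene_to_terms.values())

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (g, t) for g, ts in self._gene_to_terms.items() for t in ts
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one GO term in the core set.

    ``k`` of ``n`` core genes carry the term; ``K`` of ``N`` background genes
    do.  ``fold = (k/n) / (K/N)``; ``p`` is the one-tailed hypergeometric
    upper tail P(X >= k); ``q`` is the Benjamini-Hochberg adjusted p when
    requested, else None.
    """

    term: str
    name: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    q: float | None = None


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-tailed over-representation probability P(X >= k).

    X ~ Hypergeometric(population ``N``, successes ``K``, draws ``n``).
    ``k <= 0`` gives 1 (the tail at zero is vacuous).
    """
    if min(N, K, n) < 0 or K > N or n > N:
        raise ParameterError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}"
        )
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def go_enrichment(
    core_set: Iterable[str],
    annotations: GOAnnotationSet,
    background: Iterable[str],
    p_threshold: float = 0.05,
    ease: bool = False,
    bh: bool = False,
    return_all: bool = False,
) -> list[EnrichmentResult]:
    """GO terms over-represented in the core set versus a background.

    For every term, the one-tailed hypergeometric tail P(X >= k) is computed
    with population ``N = |background|``, successes ``K`` (background genes
    carrying the term) and draws ``n = |core|``.  Terms with raw ``p <
    p_threshold`` (or adjusted ``q`` when ``bh=True``) are returned sorted by
    ``(p, term)``.

    ``ease=True`` applies the conservative EASE-style k-1 substitution
    (the tail evaluated at k-1 observed successes) used by some
    enrichment servers; off by default.  No multiple-testing correction is
    applied unless ``bh=True``.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ParameterError(f"p_threshold must be in (0, 1], got {p_threshold}")
    core = coerce_members(core_set)
    bg = coerce_members(background)
    missing = sorted(core - bg)
    if missing:
        raise ParameterError(
            f"core genes absent from the background: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    stray_terms = sorted(
        t for t in annotations.terms if not annotations.genes_of(t) <= bg
    )
    if stray_terms:
        raise ParameterError(
            f"terms annotate genes outside the background: {stray_terms[:10]}"
            + ("..." if len(stray_terms) > 10 else "")
        )

    N = len(bg)
    n = len(core)
    results = []
    for term in sorted(annotations.terms):
        term_genes = annotations.genes_of(term)
        K = len(term_genes)
        k = len(term_genes & core)
        if ease:
            p = hypergeom_tail(k - 1, N, K, n)
        else:
            p = hypergeom_tail(k, N, K, n)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        results.append(
            EnrichmentResult(
                term=term, name=annotations.name_of(term),
                k=k, n=n, K=K, N=N, fold=fold, p=p,
            )
        )
    if bh:
        qvals = _benjamini_hochberg(np.asarray([r.p for r in results]))
        results = [
            EnrichmentResult(
                term=r.term, name=r.name, k=r.k, n=r.n, K=r.K, N=r.N,
                fold=r.fold, p=r.p, q=float(q),
            )
            for r, q in zip(results, qvals)
        ]
    results.sort(key=lambda r: (r.p, r.term))
    if return_all:
        return results
    if bh:
        return [r for r in results if r.q is not None and r.q < p_threshold]
    return [r for r in results if r.p < p_threshold]


def filter_candidates_by_function(
    candidates: Iterable[CandidateRecord],
    enriched_terms: Iterable[str],
    annotations: GOAnnotationSet,
) -> list[CandidateRecord]:
    """Keep candidates annotated with at least one enriched term.

    Order is preserved; unannotated candidates are removed like any other
    non-matching gene, with the removed count logged.
    """
    terms = set(enriched_terms)
    cands = list(candidates)
    kept = [c for c in cands if annotations.terms_of(c.candidate) & terms]
    removed = len(cands) - len(kept)
    if removed:
        logger.info(
            "function filter removed %d of %d candidate(s)", removed, len(cands)
        )
    return kept
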