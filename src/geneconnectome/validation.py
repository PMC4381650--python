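"""Held-out validation and functional-genomic-alignment (FGA) phylogenies.

Validation asks whether an independently discovered (held-out) disease gene
set is over-represented among the predicted candidates: an exact
hypergeometric upper tail plus an empirical estimate from random draws.

The FGA tree is a hierarchical clustering of genes obtained by running
neighbor joining on a biological-distance matrix instead of sequence
divergences: genes that are functionally close end up as neighboring leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .candidates import hypergeom_tail
from .network import GeneNetwork, ParameterError, coerce_members, normalize_symbol

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

def distance_matrix(
    net: GeneNetwork, genes: Sequence[str]
) -> tuple[list[str], np.ndarray]:
    """Square symmetric biological-distance matrix over a gene list.

    Genes absent from the network are dropped (logged).  Genes causing
    infinite entries (disconnected from part of the set) are dropped greedily,
    most-infinite-entries first with lexicographic tie-breaking, until the
    matrix is finite.  Input order is preserved for the survivors; fewer than
    3 usable genes is an error.
    """
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(normalize_symbol(g), None)
    labels = [g for g in seen if g in net]
    n_absent = len(seen) - len(labels)
    if n_absent:
        logger.info("distance_matrix: dropped %d gene(s) absent from network", n_absent)
    if len(labels) < 3:
        raise ParameterError(
            f"need >= 3 usable genes for a distance matrix, got {len(labels)}"
        )
    sub = np.array(net.distances_between(labels), dtype=float)
    while True:
        inf_counts = np.isinf(sub).sum(axis=1)
        worst = int(inf_counts.max(initial=0))
        if worst == 0:
            break
        drop_i = min(
            (i for i in range(len(labels)) if inf_counts[i] == worst),
            key=lambda i: labels[i],
        )
        logger.info(
            "distance_matrix: dropped %s (%d unreachable partner(s))",
            labels[drop_i], worst,
        )
        keep = [i for i in range(len(labels)) if i != drop_i]
        labels = [labels[i] for i in keep]
        sub = sub[np.ix_(keep, keep)]
    if len(labels) < 3:
        raise ParameterError(
            f"fewer than 3 mutually reachable genes remain ({len(labels)})"
        )
    return labels, sub


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FGATree:
    """Unrooted NJ tree over gene labels (wraps a dendropy tree)."""

    tree: dendropy.Tree
    labels: tuple[str, ...]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )


def _validate_matrix(matrix: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError(f"distance matrix must be square, got shape {m.shape}")
    if len(labels) != m.shape[0]:
        raise ParameterError(
            f"{len(labels)} labels for a {m.shape[0]}x{m.shape[0]} matrix"
        )
    if len(set(labels)) != len(labels):
        raise ParameterError("labels must be unique")
    if not np.isfinite(m).all():
        raise ParameterError("distance matrix must be finite")
    if not np.array_equal(m, m.T):
        raise ParameterError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise ParameterError("distance matrix diagonal must be zero")
    return m


def nj_tree(matrix: np.ndarray, labels: Sequence[str]) -> FGATree:
    """Canonical neighbor joining (Saitou-Nei, Studier-Keppler Q-criterion).

    At each step the pair minimizing ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` is
    joined; exact Q ties are broken by the lexicographically smallest cluster
    label pair (a cluster is labeled by its smallest leaf), making the tree
    reproducible across platforms.  Negative branch lengths are clamped to 0
    with the deficit moved to the sibling branch (at the final trifurcation:
    split equally between the other two branches).  The result is unrooted
    with a degree-3 seed node.
    """
    dist = _validate_matrix(matrix, labels)
    n = dist.shape[0]
    if n < 3:
        raise ParameterError(f"neighbor joining needs >= 3 taxa, got {n}")

    taxa = dendropy.TaxonNamespace(list(labels))
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels
    ]
    keys: list[str] = list(labels)  # cluster key = smallest leaf label
    work = dist.copy()

    while len(keys) > 3:
        m = len(keys)
        r = work.sum(axis=1)
        q = (m - 2) * work - r[:, None] - r[None, :]
        q = np.minimum(q, q.T)  # subtraction order can break symmetry by 1 ulp
        np.fill_diagonal(q, np.inf)
        q_min = q.min()
        tied = [(i, j) for i, j in np.argwhere(q == q_min) if i < j]
        _, i, j = min(
            (tuple(sorted((keys[i], keys[j]))), i, j) for i, j in tied
        )
        d_ij = work[i, j]
        v_i = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        v_j = d_ij - v_i
        if v_i < 0:
            v_i, v_j = 0.0, d_ij
        elif v_j < 0:
            v_j, v_i = 0.0, d_ij
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(v_i)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(v_j)

        new_row = 0.5 * (work[i, :] + work[j, :] - d_ij)
        keep = [x for x in range(m) if x not in (i, j)]
        reduced = np.zeros((len(keep) + 1, len(keep) + 1))
        reduced[:-1, :-1] = work[np.ix_(keep, keep)]
        reduced[-1, :-1] = new_row[keep]
        reduced[:-1, -1] = new_row[keep]
        new_key = min(keys[i], keys[j])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]
        work = reduced

    # final trifurcation: three-point formulas
    d01, d02, d12 = work[0, 1], work[0, 2], work[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for idx in range(3):
        if lengths[idx] < 0:
            deficit = -lengths[idx]
            lengths[idx] = 0.0
            for other in range(3):
                if other != idx:
                    lengths[other] += deficit / 2.0
    root = dendropy.Node()
    for node, length in zip(nodes, lengths):
        root.add_child(node)
        node.edge.length = float(length)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return FGATree(tree=tree, labels=tuple(labels))


def to_newick(fga: FGATree, digits: int = 6) -> str:
    """Newick text with branch lengths at ``digits`` significant figures.

    Labels containing spaces or other Newick-reserved characters are quoted;
    parseable by common tree readers.
    """
    text = fga.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,
        real_value_format_specifier=f".{digits}g",
    )
    return text.strip() + "\n"


def parse_newick(text: str) -> dendropy.Tree:
    """Read a Newick string back into a dendropy tree (round-trip helper)."""
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# Held-out enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoldoutEnrichment:
    """Enrichment of a held-out gene set among predicted candidates.

    ``k`` of the ``n`` held-out genes fall in the ``K``-gene candidate list
    drawn from an ``N``-gene background.  ``p_exact`` is the hypergeometric
    upper tail P(X >= k); ``p_empirical`` the fraction of random draws with
    >= k hits (``p_bound = 1/n_sims`` carried when no simulation reached k).
    """

    N: int
    K: int
    n: int
    k: int
    p_exact: float
    p_empirical: float
    n_sims: int
    seed: int
    p_bound: float | None = None

    def to_dict(self) -> dict:
        return {
            "N": self.N, "K": self.K, "n": self.n, "k": self.k,
            "p_exact": self.p_exact, "p_empirical": self.p_empirical,
            "n_sims": self.n_sims, "seed": self.seed, "p_bound": self.p_bound,
        }


def holdout_enrichment_test(
    candidate_set: Iterable[str],
    holdout_set: Iterable[str],
    background: Iterable[str],
    n_sims: int = 100_000,
    seed: int = 0,
    method: str = "marginal",
) -> HoldoutEnrichment:
    """Test whether held-out genes are over-represented among candidates.

    The null draws random ``n``-gene subsets of the background and counts how
    often >= ``k`` land in the candidate list.  ``method="marginal"``
    (default) samples the hit count directly from its exact null law — the
    hypergeometric distribution — which is distributionally identical to
    materializing each subset but fast enough for 10^7 draws;
    ``method="subsets"`` materializes the subsets explicitly.
    """
    if n_sims < 1:
        raise ParameterError(f"n_sims must be >= 1, got {n_sims}")
    bg = coerce_members(background)
    cand = coerce_members(candidate_set)
    hold = coerce_members(holdout_set)
    outside = sorted(hold - bg)
    if outside:
        raise ParameterError(
            f"held-out genes outside the background: {outside[:10]}"
        )
    stray = sorted(cand - bg)
    if stray:
        raise ParameterError(
            f"candidate genes outside the background: {stray[:10]}"
        )

    N, K, n = len(bg), len(cand), len(hold)
    k = len(hold & cand)
    p_exact = hypergeom_tail(k, N, K, n)

    rng = np.random.default_rng(seed)
    if method == "marginal":
        n_hits = 0
        done = 0
        while done < n_sims:
            c = min(5_000_000, n_sims - done)
            draws = rng.hypergeometric(K, N - K, n, size=c)
            n_hits += int((draws >= k).sum())
            done += c
    elif method == "subsets":
        bg_sorted = sorted(bg)
        mask = np.fromiter((g in cand for g in bg_sorted), dtype=bool, count=N)
        n_hits = 0
        done = 0
        chunk = max(1, int(4_000_000 // max(N, 1)))
        while done < n_sims:
            c = min(chunk, n_sims - done)
            keys = rng.random((c, N))
            subset = np.argpartition(keys, max(n - 1, 0), axis=1)[:, :n]
            hits = mask[subset].sum(axis=1)
            n_hits += int((hits >= k).sum())
            done += c
    else:
        raise ParameterError(f"unknown method {method!r}; use 'marginal' or 'subsets'")

    p_empirical = n_hits / n_sims
    return HoldoutEnrichment(
        N=N, K=K, n=n, k=k,
        p_exact=p_exact, p_empirical=p_empirical,
        n_sims=n_sims, seed=seed,
        p_bound=(1.0 / n_sims) if n_hits == 0 else None,
    )
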