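"""Weighted gene-interaction network and biological-distance machinery.

The network is an undirected graph over normalized gene symbols.  Each edge
carries an interaction *confidence* in (0, 1] and a derived strictly positive
*weight* (by default ``1/confidence``, so that a maximally confident
interaction costs just over 1 distance unit).  The **biological distance**
between two genes is the minimum total weight along any path, the **route** is
the ordered gene sequence realizing that minimum, and the **degrees of
separation** is the number of edges on the route.

Two shortest-path backends coexist:

* a hand-written Dijkstra with fully deterministic tie-breaking (smallest
  distance, then fewest edges, then lexicographically smallest route) that
  also reports routes — used wherever routes or reproducible per-pair results
  are needed;
* :func:`scipy.sparse.csgraph.dijkstra` over the whole network, cached on the
  :class:`GeneNetwork`, used by the statistical layers that only need large
  batches of distances.

A property test asserts the two backends agree on distances.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

logger = logging.getLogger(__name__)

#: Separator used when routes are serialized to text.
ROUTE_SEPARATOR = " <-> "


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class InputFormatError(ValueError):
    """An input record or file is malformed; the message names the offender."""


class UnknownGeneError(KeyError):
    """A gene symbol is not present in the network."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: trim surrounding whitespace, upper-case.

    Idempotent by construction.  No alias or identifier mapping is attempted.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise InputFormatError("empty gene symbol")
    return s


def coerce_members(gene_set: Iterable[str]) -> set[str]:
    """Accept a GeneSet-like object (``.members``) or any iterable of symbols."""
    members = getattr(gene_set, "members", gene_set)
    return {normalize_symbol(g) for g in members}


# ---------------------------------------------------------------------------
# Edge-weight transforms
# ---------------------------------------------------------------------------

def _reciprocal(confidence: float) -> float:
    return 1.0 / confidence


def _neglog(confidence: float) -> float:
    if confidence >= 1.0:
        raise ParameterError(
            "neglog transform requires confidence < 1 (weight must stay positive); "
            f"got {confidence}"
        )
    return -math.log(confidence)


WEIGHT_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "reciprocal": _reciprocal,
    "neglog": _neglog,
}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RouteResult:
    """Shortest route between two genes.

    For a reachable pair: ``distance`` is the summed edge weight, ``route``
    includes both endpoints and ``degrees == len(route) - 1``.  An unreachable
    pair is represented explicitly with ``distance = inf`` and an empty route
    (never an arbitrary large finite number).
    """

    source: str
    target: str
    distance: float
    route: tuple[str, ...]
    degrees: int

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.distance)

    @classmethod
    def unreachable(cls, source: str, target: str) -> "RouteResult":
        return cls(source, target, math.inf, (), 0)

    def route_text(self) -> str:
        return ROUTE_SEPARATOR.join(self.route)


class GeneNetwork:
    """Undirected weighted gene network.

    Wraps a :class:`networkx.Graph` whose edges carry ``confidence`` and
    ``weight`` attributes, plus a lazily computed, cached all-pairs distance
    matrix over the lexicographically sorted gene list.
    """

    def __init__(self, graph: nx.Graph, weight_transform: str = "reciprocal"):
        self._graph = graph
        self.weight_transform = weight_transform
        self._nodes: tuple[str, ...] = tuple(sorted(graph.nodes))
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._nodes)}
        self._dmat: np.ndarray | None = None

    # -- basic queries ------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def nodes_sorted(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def n_genes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    def index_of(self, gene: str) -> int:
        self.require(gene)
        return self._index[gene]

    def require(self, gene: str) -> None:
        if gene not in self._index:
            raise UnknownGeneError(f"gene {gene!r} is not in the network")

    def confidence(self, a: str, b: str) -> float:
        return float(self._graph.edges[a, b]["confidence"])

    def weight(self, a: str, b: str) -> float:
        return float(self._graph.edges[a, b]["weight"])

    # -- cached all-pairs distances ----------------------------------------

    def distance_matrix_full(self) -> np.ndarray:
        """All-pairs biological distances, ``inf`` for unreachable pairs.

        Row/column order follows :attr:`nodes_sorted`.  Computed once per
        network and cached; fine up to a few thousand genes.
        """
        if self._dmat is None:
            if self.n_genes == 0:
                self._dmat = np.zeros((0, 0))
            else:
                adj = nx.to_scipy_sparse_array(
                    self._graph, nodelist=list(self._nodes),
                    weight="weight", format="csr",
                )
                dmat = _csgraph_dijkstra(adj, directed=False)
                # float accumulation order can differ per direction at the
                # last ulp; enforce exact symmetry
                self._dmat = np.minimum(dmat, dmat.T)
        return self._dmat

    def distances_between(self, genes: Sequence[str]) -> np.ndarray:
        """Submatrix of the cached all-pairs matrix for ``genes`` (in order)."""
        idx = [self.index_of(g) for g in genes]
        full = self.distance_matrix_full()
        return full[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_network(
    edge_records: Iterable[tuple[str, str, float]],
    weight_transform: str = "reciprocal",
    genes: Iterable[str] = (),
) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from ``(symbol, symbol, confidence)`` rows.

    Symbols are normalized; self-loop rows are dropped with a logged warning;
    duplicate gene pairs are reduced to the maximum confidence (logged count);
    a confidence outside (0, 1] raises :class:`InputFormatError` naming the
    offending row.  ``genes`` adds isolated genes that carry no interactions.
    """
    try:
        transform = WEIGHT_TRANSFORMS[weight_transform]
    except KeyError:
        raise ParameterError(
            f"unknown weight transform {weight_transform!r}; "
            f"choose from {sorted(WEIGHT_TRANSFORMS)}"
        ) from None

    graph = nx.Graph()
    for extra in genes:
        graph.add_node(normalize_symbol(extra))

    n_self = 0
    n_dup = 0
    for row_no, record in enumerate(edge_records, start=1):
        try:
            a_raw, b_raw, conf_raw = record
        except (TypeError, ValueError):
            raise InputFormatError(
                f"edge row {row_no}: expected (gene_a, gene_b, confidence), got {record!r}"
            ) from None
        a = normalize_symbol(a_raw)
        b = normalize_symbol(b_raw)
        try:
            conf = float(conf_raw)
        except (TypeError, ValueError):
            raise InputFormatError(
                f"edge row {row_no} ({a}, {b}): confidence {conf_raw!r} is not a number"
            ) from None
        if not 0.0 < conf <= 1.0:
            raise InputFormatError(
                f"edge row {row_no} ({a}, {b}): confidence {conf} outside (0, 1]"
            )
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            if conf <= graph.edges[a, b]["confidence"]:
                continue
        graph.add_edge(a, b, confidence=conf)

    for _, _, data in graph.edges(data=True):
        data["weight"] = transform(data["confidence"])

    if n_self:
        logger.warning("dropped %d self-loop edge row(s)", n_self)
    if n_dup:
        logger.info("reduced %d duplicate edge row(s), keeping max confidence", n_dup)
    return GeneNetwork(graph, weight_transform)


# ---------------------------------------------------------------------------
# Shortest routes (deterministic Dijkstra with route reporting)
# ---------------------------------------------------------------------------

def _dijkstra_routes(
    net: GeneNetwork, source: str, target: str | None = None
) -> dict[str, tuple[float, int, tuple[str, ...]]]:
    """Dijkstra sweep returning ``{gene: (distance, degrees, route)}``.

    The heap priority is the triple ``(distance, degrees, route)``: with
    strictly positive weights every prefix of a path is popped before the
    path itself, so the first label settled at a node is simultaneously the
    minimum-distance, then fewest-edge, then lexicographically smallest
    route — reproducible across runs and platforms.
    """
    adj = net.graph.adj
    settled: dict[str, tuple[float, int, tuple[str, ...]]] = {}
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, (source,))]
    while heap:
        dist, degrees, route = heapq.heappop(heap)
        node = route[-1]
        if node in settled:
            continue
        settled[node] = (dist, degrees, route)
        if node == target:
            break
        for neighbor, attrs in adj[node].items():
            if neighbor not in settled:
                heapq.heappush(
                    heap, (dist + attrs["weight"], degrees + 1, route + (neighbor,))
                )
    return settled


def shortest_route(net: GeneNetwork, source: str, target: str) -> RouteResult:
    """Minimum-total-weight route between two genes (Dijkstra semantics).

    ``source == target`` gives distance 0 and a single-gene route.  An
    unreachable target yields :meth:`RouteResult.unreachable`.
    """
    s = normalize_symbol(source)
    t = normalize_symbol(target)
    net.require(s)
    net.require(t)
    if s == t:
        return RouteResult(s, t, 0.0, (s,), 0)
    settled = _dijkstra_routes(net, s, target=t)
    if t not in settled:
        return RouteResult.unreachable(s, t)
    dist, degrees, route = settled[t]
    return RouteResult(s, t, dist, route, degrees)


def single_source_distances(net: GeneNetwork, core: str) -> dict[str, RouteResult]:
    """One :class:`RouteResult` per gene reachable from ``core`` (core excluded)."""
    c = normalize_symbol(core)
    net.require(c)
    settled = _dijkstra_routes(net, c)
    return {
        gene: RouteResult(c, gene, dist, route, degrees)
        for gene, (dist, degrees, route) in settled.items()
        if gene != c
    }


def direct_edges(net: GeneNetwork) -> list[tuple[str, str, float]]:
    """The raw edge set (degrees-of-separation = 1 pairs) with weights.

    Pairs are returned alphabetically ordered within and across tuples,
    suitable as input to external layout or plotting tools.
    """
    out = []
    for a, b, data in net.graph.edges(data=True):
        lo, hi = sorted((a, b))
        out.append((lo, hi, float(data["weight"])))
    return sorted(out)
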