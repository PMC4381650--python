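"""Planted-module synthetic worlds for end-to-end testing.

Real disease-gene inputs (a genome-scale interactome with interaction
confidences, a curated core gene list, GO annotations) come from external
services.  This module generates a fully synthetic stand-in with the
statistical structure the analysis assumes: a planted-partition (stochastic
block model) interactome whose designated "disease" modules are densely
intra-connected, core and held-out disease gene sets sampled from those
modules, and flat GO-like annotations correlated with module membership.

A single integer seed governs all draws: the world seed is split into three
child seeds consumed in a fixed order (edges, then gene sets, then
annotations), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .candidates import GOAnnotationSet
from .io import GeneSet, write_annotations, write_edge_list, write_gene_set
from .network import GeneNetwork, ParameterError, build_network

logger = logging.getLogger(__name__)


def gene_symbols(n_genes: int) -> list[str]:
    """Synthetic symbols G0001, G0002, ... zero-padded for stable sorting."""
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _term_symbols(n_terms: int) -> list[str]:
    width = max(4, len(str(n_terms)))
    return [f"T{i:0{width}d}" for i in range(0, n_terms + 1)]


def derive_stage_seeds(seed: int, n: int = 3) -> list[int]:
    """Split a world seed into ``n`` independent child seeds (< 2^31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def generate_network(
    n_genes: int,
    n_modules: int,
    p_within: float,
    p_between: float,
    conf_range: tuple[float, float] = (0.5, 0.999),
    seed: int = 0,
) -> tuple[GeneNetwork, dict[str, int]]:
    """Planted-partition interactome plus the gene -> module map.

    Modules are equal-size blocks of the symbol list, remainder genes going
    to the last module.  Each unordered gene pair gains an edge with
    probability ``p_within`` (same module) or ``p_between`` (different
    modules); edge confidences are uniform over ``conf_range``.
    """
    if n_modules < 1 or n_genes < n_modules:
        raise ParameterError(
            f"need n_genes >= n_modules >= 1, got n_genes={n_genes}, n_modules={n_modules}"
        )
    if not (0.0 <= p_between <= p_within <= 1.0):
        raise ParameterError(
            f"need 0 <= p_between <= p_within <= 1, got {p_between}, {p_within}"
        )
    low, high = conf_range
    if not (0.0 < low <= high <= 1.0):
        raise ParameterError(f"confidence range must satisfy 0 < low <= high <= 1, got {conf_range}")

    rng = np.random.default_rng(seed)
    symbols = gene_symbols(n_genes)
    block = n_genes // n_modules
    module = np.minimum(np.arange(n_genes) // block, n_modules - 1)

    ia, ib = np.triu_indices(n_genes, k=1)
    p_edge = np.where(module[ia] == module[ib], p_within, p_between)
    picked = rng.random(p_edge.size) < p_edge
    ia, ib = ia[picked], ib[picked]
    confs = rng.uniform(low, high, size=ia.size)
    records = [
        (symbols[a], symbols[b], float(c)) for a, b, c in zip(ia, ib, confs)
    ]
    net = build_network(records, genes=symbols)
    module_of = {symbols[i]: int(module[i]) for i in range(n_genes)}
    return net, module_of


# ---------------------------------------------------------------------------
# Core / held-out sets
# ---------------------------------------------------------------------------

def plant_core_and_holdout(
    module_of: Mapping[str, int],
    disease_modules: Iterable[int],
    n_core: int,
    n_holdout: int,
    seed: int = 0,
) -> tuple[GeneSet, GeneSet]:
    """Disjoint core and held-out gene sets sampled from the disease modules.

    Emulates a curated list of known disease genes plus the more recently
    discovered genes reserved for validation.
    """
    if n_core < 1 or n_holdout < 0:
        raise ParameterError(
            f"need n_core >= 1 and n_holdout >= 0, got {n_core}, {n_holdout}"
        )
    disease = set(disease_modules)
    pool = sorted(g for g, m in module_of.items() if m in disease)
    need = n_core + n_holdout
    if need > len(pool):
        raise ParameterError(
            f"disease modules hold {len(pool)} genes; cannot sample {need}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=need, replace=False)
    core = GeneSet("core", frozenset(pool[i] for i in picked[:n_core]))
    holdout = GeneSet("holdout", frozenset(pool[i] for i in picked[n_core:]))
    return core, holdout


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    module_of: Mapping[str, int],
    n_terms: int,
    affinity: float,
    background_rate: float,
    seed: int = 0,
) -> tuple[GOAnnotationSet, dict[str, int | None]]:
    """Module-correlated flat GO-like annotations.

    Each term gets a random home module; a gene receives the term with
    probability ``affinity`` inside the home module and ``background_rate``
    outside.  A catch-all term (home ``None``) annotates every gene so that
    coverage is guaranteed.  Returns the annotation set and the term -> home
    module map.
    """
    if n_terms < 1:
        raise ParameterError(f"n_terms must be >= 1, got {n_terms}")
    for name, p in (("affinity", affinity), ("background_rate", background_rate)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {p}")

    genes = sorted(module_of)
    module = np.asarray([module_of[g] for g in genes])
    n_modules = int(module.max()) + 1 if len(genes) else 1
    rng = np.random.default_rng(seed)
    homes = rng.integers(0, n_modules, size=n_terms)

    term_ids = _term_symbols(n_terms)
    catch_all = term_ids[0]
    gene_to_terms: dict[str, set[str]] = {g: {catch_all} for g in genes}
    term_home: dict[str, int | None] = {catch_all: None}
    term_names: dict[str, str] = {catch_all: "catch-all (annotates all genes)"}
    for t in range(n_terms):
        term = term_ids[t + 1]
        home = int(homes[t])
        term_home[term] = home
        term_names[term] = f"synthetic function of module {home}"
        probs = np.where(module == home, affinity, background_rate)
        hit = rng.random(len(genes)) < probs
        for i in np.nonzero(hit)[0]:
            gene_to_terms[genes[i]].add(term)
    annotations = GOAnnotationSet(gene_to_terms, term_names)
    return annotations, term_home


# ---------------------------------------------------------------------------
# Whole worlds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorldParams:
    """Generator defaults: the documented study conditions of the test world.

    500 genes in 5 equal modules; dense planted modules (p_within=0.5)
    against a sparse background (p_between=0.005); confidences uniform in
    (0.5, 0.999]; one disease module providing 50 core and 10 held-out
    genes; 50 module-homed annotation terms with affinity 0.9 inside the
    home module and a 0.05 background rate.
    """

    n_genes: int = 500
    n_modules: int = 5
    p_within: float = 0.5
    p_between: float = 0.005
    conf_range: tuple[float, float] = (0.5, 0.999)
    disease_modules: tuple[int, ...] = (0,)
    n_core: int = 50
    n_holdout: int = 10
    n_terms: int = 50
    affinity: float = 0.9
    background_rate: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conf_range"] = list(self.conf_range)
        d["disease_modules"] = list(self.disease_modules)
        return d


@dataclass(frozen=True)
class SyntheticWorld:
    """A complete synthetic study: network, truth labels, inputs, seed."""

    network: GeneNetwork
    module_of: dict[str, int]
    core: GeneSet
    holdout: GeneSet
    annotations: GOAnnotationSet
    term_home: dict[str, int | None]
    seed: int
    params: WorldParams

    @property
    def disease_genes(self) -> frozenset[str]:
        disease = set(self.params.disease_modules)
        return frozenset(g for g, m in self.module_of.items() if m in disease)


def generate_world(params: WorldParams = WorldParams(), seed: int = 0) -> SyntheticWorld:
    """Generate a full world from one seed (edges -> sets -> annotations)."""
    s_edges, s_sets, s_ann = derive_stage_seeds(seed, 3)
    net, module_of = generate_network(
        params.n_genes, params.n_modules, params.p_within, params.p_between,
        params.conf_range, seed=s_edges,
    )
    core, holdout = plant_core_and_holdout(
        module_of, params.disease_modules, params.n_core, params.n_holdout,
        seed=s_sets,
    )
    annotations, term_home = generate_annotations(
        module_of, params.n_terms, params.affinity, params.background_rate,
        seed=s_ann,
    )
    return SyntheticWorld(
        network=net, module_of=module_of, core=core, holdout=holdout,
        annotations=annotations, term_home=term_home, seed=seed, params=params,
    )


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard pipeline inputs plus a JSON parameter sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": world.seed}
    paths = {
        "edge_list": out / "edges.tsv",
        "core_set": out / "core_genes.txt",
        "holdout_set": out / "holdout_genes.txt",
        "annotations": out / "annotations.tsv",
        "params": out / "world_params.json",
    }
    write_edge_list(paths["edge_list"], world.network, metadata=meta)
    write_gene_set(paths["core_set"], world.core, metadata=meta)
    write_gene_set(paths["holdout_set"], world.holdout, metadata=meta)
    write_annotations(paths["annotations"], world.annotations, metadata=meta)
    sidecar = {"seed": world.seed, "params": world.params.to_dict()}
    paths["params"].write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return paths
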