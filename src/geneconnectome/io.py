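"""File formats, configuration, and the end-to-end pipeline.

All tabular artifacts are TSV with an explicit header row, preceded by
``# key: value`` metadata lines echoing the tool version, seed and the
configuration that produced them.  Percentile p-values are written with 5
decimals; routes are serialized with a ``" <-> "`` separator.  Stripped of
metadata headers, reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .candidates import (
    CandidateExtraction,
    CandidateRecord,
    EnrichmentResult,
    GOAnnotationSet,
    extract_candidates,
    filter_candidates_by_function,
    go_enrichment,
)
from .connectome import (
    Connectome,
    PermutationTestResult,
    build_connectome,
    median_clustering_test,
)
from .network import (
    ROUTE_SEPARATOR,
    GeneNetwork,
    InputFormatError,
    ParameterError,
    build_network,
    normalize_symbol,
)
from .validation import (
    HoldoutEnrichment,
    distance_matrix,
    holdout_enrichment_test,
    nj_tree,
    to_newick,
)

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"

#: Per-stage seed offsets derived from the single pipeline seed, so each
#: stochastic stage is independently reproducible.
STAGE_SEED_OFFSETS = {"clustering": 1, "holdout": 2}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene symbols."""

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_HEADER_WORDS = {"gene_a", "genea", "gene", "source", "a"}


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Parse a 3-column edge-list TSV: gene_a, gene_b, confidence in (0, 1].

    A header row is optional; ``#`` comment lines and blank lines are
    ignored; CRLF and LF files parse identically; a whitespace-delimited
    dialect is accepted when no tabs are present.  Malformed rows raise
    :class:`InputFormatError` with the line number.
    """
    path = Path(path)
    records: list[tuple[str, str, float]] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            a, b, conf_text = (f.strip() for f in fields)
            try:
                conf = float(conf_text)
            except ValueError:
                if not records and a.lower() in _HEADER_WORDS:
                    continue  # optional header row
                raise InputFormatError(
                    f"{path}:{lineno}: confidence {conf_text!r} is not a number"
                ) from None
            if not 0.0 < conf <= 1.0:
                raise InputFormatError(
                    f"{path}:{lineno}: confidence {conf} outside (0, 1]"
                )
            records.append((a, b, conf))
    if not records:
        raise InputFormatError(f"{path}: no edge records found")
    return records


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a gene set: one symbol per line, ``#`` starts a comment."""
    path = Path(path)
    members: list[str] = []
    with open(path, newline="") as fh:
        for raw in fh:
            token = raw.split("#", 1)[0].strip()
            if not token:
                continue
            members.append(normalize_symbol(token))
    unique = frozenset(members)
    n_dup = len(members) - len(unique)
    if n_dup:
        logger.info("%s: collapsed %d duplicate symbol(s)", path, n_dup)
    if not unique:
        raise InputFormatError(f"{path}: no gene symbols found")
    return GeneSet(name, unique)


def read_annotations(path: str | Path) -> GOAnnotationSet:
    """Read gene -> GO-term annotations.

    Accepts a 2- or 3-column TSV (``gene  term_id  [term_name]``) or a GAF
    2.2 subset (``!`` comment lines; gene symbol in column 3, GO id in
    column 5).
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith(("!", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) >= 15:  # GAF 2.2 row
                gene, term = fields[2], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
                if len(fields) >= 3 and fields[2].strip():
                    names[term.strip()] = fields[2].strip()
            else:
                raise InputFormatError(
                    f"{path}:{lineno}: expected at least 2 columns"
                )
            gene, term = gene.strip(), term.strip()
            if not pairs and gene.lower() == "gene":
                continue  # optional header row
            if not gene or not term:
                raise InputFormatError(f"{path}:{lineno}: empty gene or term field")
            pairs.append((gene, term))
    if not pairs:
        raise InputFormatError(f"{path}: no annotations found")
    return GOAnnotationSet.from_pairs(pairs, names)


def read_candidates(path: str | Path) -> list[CandidateRecord]:
    """Read a candidate table written by :func:`write_candidates`."""
    path = Path(path)
    records: list[CandidateRecord] = []
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "candidate":
                continue
            if len(fields) != 7:
                raise InputFormatError(f"{path}: malformed candidate row {line!r}")
            cand, core, dist, rank, p, route, degrees = fields
            records.append(
                CandidateRecord(
                    candidate=cand,
                    closest_core=core,
                    distance=float(dist),
                    rank=int(rank),
                    p=float(p),
                    route=tuple(route.split(ROUTE_SEPARATOR)) if route else (),
                    degrees=int(degrees),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _metadata_lines(metadata: Mapping[str, object] | None) -> list[str]:
    lines = [f"# tool: geneconnectome {_VERSION}"]
    for key in sorted(metadata or {}):
        lines.append(f"# {key}: {metadata[key]}")
    return lines


def _write_table(
    path: Path,
    header: Sequence[str],
    rows: Iterable[Sequence[str]],
    metadata: Mapping[str, object] | None,
) -> None:
    with open(path, "w", newline="\n") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_edge_list(
    path: str | Path,
    net_or_records: GeneNetwork | Iterable[tuple[str, str, float]],
    metadata: Mapping[str, object] | None = None,
) -> None:
    if isinstance(net_or_records, GeneNetwork):
        rows = sorted(
            (a, b) if a < b else (b, a)
            for a, b in net_or_records.graph.edges
        )
        records = [
            (a, b, net_or_records.confidence(a, b)) for a, b in rows
        ]
    else:
        records = sorted(
            (min(a, b), max(a, b), float(c)) for a, b, c in net_or_records
        )
    _write_table(
        Path(path),
        ("gene_a", "gene_b", "confidence"),
        ((a, b, repr(c)) for a, b, c in records),
        metadata,
    )


def write_gene_set(
    path: str | Path, gene_set: GeneSet, metadata: Mapping[str, object] | None = None
) -> None:
    with open(path, "w", newline="\n") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        fh.write(f"# gene set: {gene_set.name} ({len(gene_set)} genes)\n")
        for gene in gene_set:
            fh.write(gene + "\n")


def write_annotations(
    path: str | Path,
    annotations: GOAnnotationSet,
    metadata: Mapping[str, object] | None = None,
) -> None:
    rows = (
        (gene, term, annotations.name_of(term))
        for gene, term in annotations.pairs()
    )
    _write_table(Path(path), ("gene", "term_id", "term_name"), rows, metadata)


def write_connectome(
    path: str | Path, conn: Connectome, metadata: Mapping[str, object] | None = None
) -> None:
    meta = dict(metadata or {})
    meta.update({"core": conn.core, "N_ref": conn.n_ref, "N_ref_policy": conn.n_ref_policy})
    rows = (
        (
            e.gene, f"{e.distance:.3f}", str(e.rank), f"{e.p:.5f}",
            ROUTE_SEPARATOR.join(e.route), str(e.degrees),
        )
        for e in conn.entries
    )
    _write_table(
        Path(path), ("gene", "distance", "rank", "p", "route", "degrees"), rows, meta
    )


def write_candidates(
    path: str | Path,
    records: Iterable[CandidateRecord],
    metadata: Mapping[str, object] | None = None,
) -> None:
    rows = (
        (
            r.candidate, r.closest_core, f"{r.distance:.3f}", str(r.rank),
            f"{r.p:.5f}", ROUTE_SEPARATOR.join(r.route), str(r.degrees),
        )
        for r in records
    )
    _write_table(
        Path(path),
        ("candidate", "closest_core", "distance", "rank", "p", "route", "degrees"),
        rows,
        metadata,
    )


def write_enrichment(
    path: str | Path,
    results: Iterable[EnrichmentResult],
    metadata: Mapping[str, object] | None = None,
) -> None:
    rows = (
        (
            r.term, r.name, str(r.k), str(r.K), str(r.n), str(r.N),
            f"{r.fold:.4f}", f"{r.p:.5g}",
            "" if r.q is None else f"{r.q:.5g}",
        )
        for r in results
    )
    _write_table(
        Path(path),
        ("term_id", "term_name", "k", "K", "n", "N", "fold", "p", "q"),
        rows,
        metadata,
    )


def write_json(path: str | Path, payload: Mapping[str, object]) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_matrix(
    path: str | Path,
    labels: Sequence[str],
    matrix: np.ndarray,
    metadata: Mapping[str, object] | None = None,
) -> None:
    rows = (
        [labels[i]] + [f"{x:.6g}" for x in matrix[i]] for i in range(len(labels))
    )
    _write_table(Path(path), ["gene"] + list(labels), rows, metadata)


def write_newick(path: str | Path, newick_text: str) -> None:
    Path(path).write_text(newick_text)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, echoed into every output."""

    edge_list: Path
    core_set: Path
    annotations: Path
    out_dir: Path
    holdout_set: Path | None = None
    alpha: float = 0.01
    go_p_threshold: float = 0.05
    n_sims: int = 10_000
    seed: int = 1
    weight_transform: str = "reciprocal"
    n_ref_policy: str = "others"
    write_matrix_tsv: bool = True

    def __post_init__(self):
        self.edge_list = Path(self.edge_list)
        self.core_set = Path(self.core_set)
        self.annotations = Path(self.annotations)
        self.out_dir = Path(self.out_dir)
        if self.holdout_set is not None:
            self.holdout_set = Path(self.holdout_set)

    def validate(self) -> None:
        for name in ("alpha", "go_p_threshold"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ParameterError(f"{name} must be in (0, 1], got {value}")
        if self.n_sims < 1:
            raise ParameterError(f"n_sims must be >= 1, got {self.n_sims}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, Path):
                d[key] = str(value)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full prediction pipeline and write every intermediate table.

    Stages: build network -> per-core connectomes -> median clustering test
    -> top-``alpha`` candidate extraction -> GO enrichment of the core set ->
    function filter -> held-out enrichment (if a held-out set is given) ->
    FGA neighbor-joining tree over core + filtered candidates.  Returns the
    run manifest (also written as ``manifest.json``), whose ``funnel`` block
    records the occurrence / deduplicated / filtered counts.

    While the run is in progress a ``RUN.partial`` marker exists in the
    output directory; it is removed only on success, so any outputs present
    alongside the marker are partial.
    """
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "RUN.partial"
    marker.write_text("pipeline in progress or aborted\n")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    meta = {
        "seed": config.seed,
        "alpha": config.alpha,
        "go_p_threshold": config.go_p_threshold,
        "n_sims": config.n_sims,
        "weight_transform": config.weight_transform,
        "N_ref_policy": config.n_ref_policy,
    }

    records = stage("read-edges", lambda: read_edge_list(config.edge_list))
    core = stage("read-core", lambda: read_gene_set(config.core_set, "core"))
    annotations = stage("read-annotations", lambda: read_annotations(config.annotations))
    holdout = None
    if config.holdout_set is not None:
        holdout = stage(
            "read-holdout", lambda: read_gene_set(config.holdout_set, "holdout")
        )

    net = stage(
        "build-network", lambda: build_network(records, config.weight_transform)
    )

    core_in_net = sorted(g for g in core.members if g in net)
    n_core_missing = len(core) - len(core_in_net)
    if n_core_missing:
        logger.info(
            "%d core gene(s) have no distance information and are skipped",
            n_core_missing,
        )

    def _connectomes():
        conn_dir = out / "connectomes"
        conn_dir.mkdir(exist_ok=True)
        result = {}
        for gene in core_in_net:
            conn = build_connectome(net, gene, n_ref_policy=config.n_ref_policy)
            write_connectome(conn_dir / f"{gene}.tsv", conn, metadata=meta)
            result[gene] = conn
        return result

    connectomes = stage("connectomes", _connectomes)

    clustering = stage(
        "cluster-stats",
        lambda: median_clustering_test(
            net, core, config.n_sims, config.stage_seed("clustering")
        ),
    )
    write_json(
        out / "clustering.json",
        {
            "observed_median": clustering.observed_median,
            "n_sims": clustering.n_sims,
            "n_hits": clustering.n_hits,
            "p_empirical": clustering.p_empirical,
            "p_bound": clustering.p_bound,
            "seed": clustering.seed,
            "set_size": clustering.set_size,
        },
    )

    extraction = stage(
        "predict", lambda: extract_candidates(connectomes, config.alpha, core)
    )
    write_candidates(out / "candidates_initial.tsv", extraction.records, metadata=meta)

    def _enrichment():
        background = annotations.genes & net.genes
        annotated_core = core.members & background
        n_dropped = len(core) - len(annotated_core)
        if n_dropped:
            logger.info(
                "%d core gene(s) outside the annotated background dropped "
                "from enrichment", n_dropped,
            )
        restricted = GOAnnotationSet(
            {g: annotations.terms_of(g) for g in background},
            annotations.term_names,
        )
        return go_enrichment(
            annotated_core, restricted, background, config.go_p_threshold
        )

    enriched = stage("go-enrichment", _enrichment)
    write_enrichment(out / "enrichment.tsv", enriched, metadata=meta)

    filtered = stage(
        "go-filter",
        lambda: filter_candidates_by_function(
            extraction.records, {r.term for r in enriched}, annotations
        ),
    )
    write_candidates(out / "candidates_filtered.tsv", filtered, metadata=meta)

    holdout_result: HoldoutEnrichment | None = None
    if holdout is not None:
        def _validate():
            background = net.genes - core.members
            usable = holdout.members & background
            n_dropped = len(holdout) - len(usable)
            if n_dropped:
                logger.info(
                    "%d held-out gene(s) outside the validation background "
                    "dropped", n_dropped,
                )
            return holdout_enrichment_test(
                {r.candidate for r in filtered},
                usable,
                background,
                n_sims=config.n_sims,
                seed=config.stage_seed("holdout"),
            )

        holdout_result = stage("validate", _validate)
        write_json(out / "holdout.json", holdout_result.to_dict())

    def _tree():
        genes = sorted(set(core_in_net) | {r.candidate for r in filtered})
        if len(genes) < 3:
            logger.warning("fewer than 3 tree genes; skipping FGA tree")
            return None
        labels, mat = distance_matrix(net, genes)
        if config.write_matrix_tsv:
            write_matrix(out / "fga_distance_matrix.tsv", labels, mat, metadata=meta)
        tree = nj_tree(mat, labels)
        write_newick(out / "fga_tree.nwk", to_newick(tree))
        return len(labels)

    n_tree_leaves = stage("fga-tree", _tree)

    manifest = {
        "tool_version": _VERSION,
        "config": config.to_dict(),
        "network": {"n_genes": net.n_genes, "n_edges": net.n_edges},
        "n_core_in_network": len(core_in_net),
        "funnel": {
            "occurrences": extraction.n_occurrences,
            "deduplicated": extraction.n_deduplicated,
            "filtered": len(filtered),
        },
        "n_enriched_terms": len(enriched),
        "clustering": {
            "observed_median": clustering.observed_median,
            "n_hits": clustering.n_hits,
            "p_empirical": clustering.p_empirical,
            "p_bound": clustering.p_bound,
        },
        "holdout": holdout_result.to_dict() if holdout_result else None,
        "fga_tree_leaves": n_tree_leaves,
    }
    write_json(out / "manifest.json", manifest)
    marker.unlink()
    return manifest
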