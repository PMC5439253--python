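"""End-to-end orchestration: preprocess -> screen -> clinical -> network -> enrichment.

``run_pipeline`` executes the stages in order with the canonical default
parameters (pseudocount 0.001, pair cutoff -0.5, edge threshold 0.7, hub
degree 20, enrichment alpha 0.05 with >= 3 genes) and writes every table
plus a manifest recording parameters, input checksums and row counts.
Reruns on unchanged inputs are byte-identical apart from the manifest
timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .expression import (
    DEFAULT_PSEUDOCOUNT,
    align_samples,
    preprocess,
    read_expression_tsv,
)
from .correlation import (
    DEFAULT_PAIR_CUTOFF,
    cross_correlation_matrix,
    screen_negative_pairs,
    write_pair_table,
)
from .network import (
    DEFAULT_EDGE_THRESHOLD,
    DEFAULT_HUB_DEGREE,
    AdjacencySpec,
    build_network,
    export_edge_list,
    hub_genes,
)
from .clinical import (
    association_table,
    build_contingency,
    dichotomize_expression,
    read_clinical_tsv,
    survival_median_split,
)
from .enrichment import (
    fisher_enrichment,
    filter_enriched,
    read_gmt,
    write_enrichment_table,
)

logger = logging.getLogger("comira")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for a full run.

    Threshold defaults are the canonical analysis parameters; any deviation
    must be set explicitly so the default run is the reference behavior.
    """

    mrna_path: str
    mirna_path: str
    out_dir: str
    clinical_path: str | None = None
    gmt_path: str | None = None
    marker_mirna: str | None = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    hub_degree: int = DEFAULT_HUB_DEGREE
    alpha: float = 0.05
    min_genes: int = 3
    network_genes: list[str] | None = None
    max_network_genes: int = 4000

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.pair_cutoff >= 0:
            raise ValueError("pair cutoff must be negative")
        if not (0 < self.edge_threshold <= 1):
            raise ValueError("edge threshold must be in (0, 1]")
        if self.hub_degree < 0 or self.min_genes < 0:
            raise ValueError("hub_degree and min_genes must be non-negative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Stages: preprocess, screen, clinical (if clinical inputs given), network,
    hubs, enrichment (if a GMT is given). A failure aborts with the failing
    stage named; the manifest flags partial output.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "comira",
        "version": __version__,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("mrna_path", "mirna_path", "clinical_path", "gmt_path", "out_dir")
        },
        "inputs": {},
        "stages": [],
        "outputs": {},
        "counts": {},
    }
    for key in ("mrna_path", "mirna_path", "clinical_path", "gmt_path"):
        p = getattr(cfg, key)
        if p is not None:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    stage = "preprocess"
    t0 = time.monotonic()
    try:
        mrna_raw = read_expression_tsv(cfg.mrna_path, scale="fpkm")
        mirna_raw = read_expression_tsv(cfg.mirna_path, scale="fpkm")
        mrna = preprocess(mrna_raw, pseudocount=cfg.pseudocount)
        mirna = preprocess(mirna_raw, pseudocount=cfg.pseudocount)
        mrna, mirna = align_samples(mrna, mirna)
        manifest["counts"]["mrna_genes"] = mrna.n_genes
        manifest["counts"]["mirna_genes"] = mirna.n_genes
        manifest["counts"]["samples"] = mrna.n_samples
        _log_stage(manifest, stage, t0)

        stage = "screen"
        t0 = time.monotonic()
        corr = cross_correlation_matrix(mrna, mirna)
        pairs = screen_negative_pairs(corr, cutoff=cfg.pair_cutoff)
        pair_path = out / "pairs.tsv"
        write_pair_table(pairs, pair_path)
        manifest["outputs"]["pairs"] = str(pair_path)
        manifest["counts"]["pairs"] = len(pairs)
        _log_stage(manifest, stage, t0)

        stage = "clinical"
        t0 = time.monotonic()
        if cfg.clinical_path is not None and cfg.marker_mirna is not None:
            records = read_clinical_tsv(cfg.clinical_path)
            marker = dict(zip(mirna.sample_ids, mirna.data.loc[cfg.marker_mirna]))
            groups = dichotomize_expression(marker)
            tables = {}
            feature_names = sorted({k for r in records for k in r.features})
            for feat in feature_names:
                fmap = {r.patient_id: r.features.get(feat) for r in records}
                tables[feat] = build_contingency(fmap, groups)
            if any(r.survival_days is not None for r in records):
                surv_groups = survival_median_split(records)
                tables["overall_survival"] = build_contingency(
                    {p: g for p, g in surv_groups.items()}, groups
                )
            assoc = association_table(tables)
            clin_path = out / "clinical_association.tsv"
            assoc.to_csv(clin_path, sep="\t", index=False)
            manifest["outputs"]["clinical_association"] = str(clin_path)
            manifest["counts"]["clinical_features"] = len(tables)
        _log_stage(manifest, stage, t0)

        stage = "network"
        t0 = time.monotonic()
        genes = cfg.network_genes
        if genes is None and mrna.n_genes > cfg.max_network_genes:
            raise PipelineError(
                f"stage network: {mrna.n_genes} genes exceed max_network_genes="
                f"{cfg.max_network_genes}; pass network_genes to select candidates"
            )
        graph = build_network(
            mrna, AdjacencySpec(edge_threshold=cfg.edge_threshold), genes=genes
        )
        comps = graph.components
        manifest["counts"]["network_nodes"] = len(graph.nodes)
        manifest["counts"]["network_edges"] = len(graph.edges)
        manifest["counts"]["components"] = len(comps)
        manifest["counts"]["component_sizes"] = [len(c) for c in comps]
        edges_tsv = out / "edges.tsv"
        edges_sif = out / "edges.sif"
        export_edge_list(graph, edges_tsv, format="tsv")
        export_edge_list(graph, edges_sif, format="sif")
        manifest["outputs"]["edges_tsv"] = str(edges_tsv)
        manifest["outputs"]["edges_sif"] = str(edges_sif)
        _log_stage(manifest, stage, t0)

        stage = "hubs"
        t0 = time.monotonic()
        hubs = hub_genes(graph, min_degree_exclusive=cfg.hub_degree)
        hub_path = out / "hubs.tsv"
        with open(hub_path, "w") as fh:
            fh.write("gene\tdegree\n")
            for g, d in hubs:
                fh.write(f"{g}\t{d}\n")
        manifest["outputs"]["hubs"] = str(hub_path)
        manifest["counts"]["hubs"] = len(hubs)
        _log_stage(manifest, stage, t0)

        stage = "enrichment"
        t0 = time.monotonic()
        if cfg.gmt_path is not None:
            gs = read_gmt(cfg.gmt_path)
            universe = set(mrna.gene_ids)  # zero-filter survivors
            for i, comp in enumerate(comps, start=1):
                results = filter_enriched(
                    fisher_enrichment(set(comp), gs, universe=universe),
                    alpha=cfg.alpha,
                    min_genes=cfg.min_genes,
                )
                epath = out / f"enrichment_network{i}.tsv"
                write_enrichment_table(results, epath)
                manifest["outputs"][f"enrichment_network{i}"] = str(epath)
                manifest["counts"][f"enriched_terms_network{i}"] = len(results)
        _log_stage(manifest, stage, t0)
    except PipelineError:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, out)
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, out)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out)
    return manifest


def _log_stage(manifest: dict, stage: str, t0: float) -> None:
    elapsed = time.monotonic() - t0
    logger.info("stage %s done in %.2fs", stage, elapsed)
    manifest["stages"].append({"name": stage, "seconds": round(elapsed, 3)})


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
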