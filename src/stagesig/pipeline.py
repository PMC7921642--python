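"""End-to-end pipeline: simulate/load -> DGE -> network -> signature -> null -> enrichment.

A :class:`PipelineConfig` (loadable from YAML) drives :func:`run_pipeline`,
which writes every intermediate artifact to the output directory plus a JSON
manifest recording parameters, the root seed, and a SHA-256 hash of each
output file.  All randomness flows from the root seed, split per stage with
``numpy.random.SeedSequence``, so a rerun with the same config reproduces
byte-identical artifacts and manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dge, enrichment, io, network, signature, synthetic
from .errors import ConfigError, PipelineError

logger = logging.getLogger("stagesig")

_STAGE_NAMES = ("simulate", "dge", "network", "gatekeepers", "signature", "null", "enrichment")


@dataclass
class PipelineConfig:
    """Every threshold and input of the pipeline, overridable from YAML/CLI."""

    out_dir: str = "stagesig_run"
    seed: int = 0

    # inputs; None -> synthesize with the simulation settings below
    expression_path: str | None = None
    design_path: str | None = None
    edge_list_path: str | None = None
    gmt_path: str | None = None
    annotation_path: str | None = None

    stage_labels: tuple[str, ...] = synthetic.DEFAULT_STAGES
    control_stages: tuple[str, ...] = synthetic.DEFAULT_STAGES[:2]

    # simulation settings (used only when the corresponding input is None)
    sim_n_genes: int = 2000
    sim_n_signature: int = 15
    sim_samples_per_stage: tuple[int, ...] = synthetic.DEFAULT_SAMPLES_PER_STAGE
    sim_effect_size: float = 2.0
    sim_noise_sd: float = 1.0
    sim_n_hubs: int = 4
    sim_hub_degree: int = 20
    sim_n_gatekeepers: int = 3

    # analysis thresholds
    p_thresh: float = 0.05
    fc_thresh: float = 1.5
    use_adjusted_p: bool = True
    moderated: bool = True
    min_degree: int = 2
    expand_neighbors: bool = False
    z_threshold: float = 0.78
    l2_strength: float = 0.7
    signature_k: int = 15
    n_null_sets: int = 500
    fdr_thresh: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.p_thresh <= 1 or not 0 < self.fdr_thresh <= 1:
            raise ConfigError("p_thresh/fdr_thresh: must lie in (0, 1]")
        if self.fc_thresh < 1:
            raise ConfigError("fc_thresh: must be >= 1 (linear fold-change scale)")
        if self.min_degree < 2:
            raise ConfigError("min_degree: must be >= 2")
        if self.l2_strength <= 0:
            raise ConfigError("l2_strength: must be > 0")
        if self.n_null_sets < 1 or self.signature_k < 1:
            raise ConfigError("n_null_sets/signature_k: must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict[str, Any] | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides or {})
        for key in ("stage_labels", "control_stages", "sim_samples_per_stage"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_inputs(self) -> None:
        for name in ("expression_path", "design_path", "edge_list_path",
                     "gmt_path", "annotation_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                raise ConfigError(f"{name}: file not found: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGE_NAMES, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Raises (and writes nothing further) as soon as a stage fails; input
    validation happens before any output is produced.
    """
    config.validate_inputs()
    seeds = _stage_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save(name: str, path: Path) -> None:
        outputs[name] = str(path)

    # ------------------------------------------------------------- stage 1
    truth = synthetic.GroundTruth()
    if config.expression_path is None:
        sim = synthetic.SimulationConfig(
            n_genes=config.sim_n_genes,
            n_signature=config.sim_n_signature,
            stage_labels=config.stage_labels,
            samples_per_stage=config.sim_samples_per_stage,
            effect_size=config.sim_effect_size,
            noise_sd=config.sim_noise_sd,
            n_control_stages=len(config.control_stages),
            seed=seeds["simulate"],
        )
        expr, design, truth = synthetic.simulate_expression(sim)
        io.write_expression(expr, out / "expression.tsv")
        io.write_design(design, out / "design.tsv")
        save("expression", out / "expression.tsv")
        save("design", out / "design.tsv")
    else:
        expr = io.read_expression(config.expression_path)
        design = io.read_design(config.design_path, config.stage_labels, config.control_stages)

    if config.edge_list_path is None:
        planted = sorted(truth.signature_genes)
        n_gk, n_hub = config.sim_n_gatekeepers, config.sim_n_hubs
        if len(planted) < n_gk + n_hub:
            raise PipelineError("sim_n_signature too small to host planted hubs+gatekeepers")
        net_cfg = synthetic.NetworkSimConfig(
            n_nodes=len(expr.index),
            n_hubs=n_hub,
            hub_degree=config.sim_hub_degree,
            n_gatekeepers=n_gk,
            seed=seeds["simulate"],
        )
        graph, net_truth = synthetic.simulate_network(
            net_cfg,
            node_ids=list(expr.index),
            gatekeeper_ids=planted[:n_gk],
            hub_ids=planted[n_gk : n_gk + n_hub],
        )
        truth = synthetic.GroundTruth(
            signature_genes=truth.signature_genes,
            gatekeeper_nodes=net_truth.gatekeeper_nodes,
            hub_nodes=net_truth.hub_nodes,
        )
        io.write_edge_list(graph, out / "edges.tsv")
        save("edges", out / "edges.tsv")
        raw_edges = [tuple(sorted(e)) for e in graph.edges()]
    else:
        raw_edges = io.read_edge_list(config.edge_list_path)

    if truth.signature_genes or truth.gatekeeper_nodes:
        io.write_ground_truth(truth, out / "ground_truth.json")
        save("ground_truth", out / "ground_truth.json")

    # ------------------------------------------------------------- stage 2
    logger.info("DGE: %d genes, contrasts %s", len(expr), design.non_control_stages)
    tables = dge.fit_all_contrasts(expr, design, moderated=config.moderated)
    for stage_label, table in tables.items():
        path = out / f"dge_{stage_label}.tsv"
        io.write_table(table.reset_index().rename(columns={"index": "gene"}), path)
        save(f"dge_{stage_label}", path)
    merged = dge.filter_and_merge(
        tables, config.p_thresh, config.fc_thresh, use_adjusted=config.use_adjusted_p
    )
    io.write_table(merged, out / "dge_merged.tsv")
    save("dge_merged", out / "dge_merged.tsv")

    # ------------------------------------------------------------- stage 3
    graph, report = network.clean_network(raw_edges)
    if config.annotation_path is not None:
        probe_map = io.read_annotation(config.annotation_path)
        merged_genes = sorted({probe_map.get(g, g) for g in merged["gene"]})
    else:
        merged_genes = list(merged["gene"])
    if config.expand_neighbors:
        seeds_in = [g for g in merged_genes if g in graph]
        expanded = set(seeds_in)
        for g in seeds_in:
            expanded.update(graph[g])
        merged_genes = sorted(expanded)
    sub, unmapped = network.induce_subnetwork(graph, merged_genes)
    records = network.clustering_centrality(sub)
    io.write_table(records, out / "centrality.tsv")
    save("centrality", out / "centrality.tsv")

    gatekeepers = network.find_gatekeepers(records, min_degree=config.min_degree)
    io.write_table(pd.DataFrame({"gatekeeper": gatekeepers}),
                   out / "gatekeepers.tsv")
    save("gatekeepers", out / "gatekeepers.tsv")

    big = network.largest_component(sub)
    comp_df = pd.DataFrame({"node": sorted(big.nodes())})
    io.write_table(comp_df, out / "big_component.tsv")
    save("big_component", out / "big_component.tsv")
    if gatekeepers:
        edges_set, coverage = network.neighbor_edge_closure(sub, gatekeepers, order=2)
    else:
        edges_set, coverage = set(), 0.0
    closure_df = pd.DataFrame(sorted(edges_set), columns=["node_a", "node_b"])
    io.write_table(closure_df, out / "gatekeeper_closure.tsv")
    if len(closure_df):
        save("gatekeeper_closure", out / "gatekeeper_closure.tsv")

    # ------------------------------------------------------------- stage 4
    X = expr.T  # samples x genes
    y = design.labels(list(expr.columns))
    reduction = signature.two_round_reduction(
        X, y, threshold=config.z_threshold, l2_strength=config.l2_strength,
        seed=seeds["signature"],
    )
    io.write_table(
        pd.DataFrame({"gene": reduction.round2}), out / "signature.tsv"
    )
    save("signature", out / "signature.tsv")
    sig_cols = reduction.round2
    model = signature.train_classifier(
        X[sig_cols], y, l2_strength=config.l2_strength, seed=seeds["signature"]
    )
    pred = model.predict(X[sig_cols].to_numpy(float))
    report_cls = signature.evaluate(y, pred, class_labels=list(design.stage_order))
    io.write_table(report_cls.confusion, out / "confusion.tsv", index=True)
    save("confusion", out / "confusion.tsv")

    # ------------------------------------------------------------- stage 5
    null = signature.random_signature_null(
        X, y, observed=report_cls.macro_jaccard, k=min(config.signature_k, X.shape[1]),
        n_sets=config.n_null_sets, l2_strength=config.l2_strength, seed=seeds["null"],
    )
    io.write_table(
        pd.DataFrame({"jaccard": null.jaccard_values}),
        out / "null_distribution.tsv",
    )
    save("null_distribution", out / "null_distribution.tsv")

    # ------------------------------------------------------------- stage 6
    enrich_rows = 0
    if config.gmt_path is not None or config.expression_path is None:
        universe = list(expr.index)
        if config.gmt_path is not None:
            sets, names = enrichment.read_gmt(config.gmt_path)
        else:
            sets = synthetic.make_gene_sets(
                universe, sorted(truth.signature_genes), seed=seeds["enrichment"]
            )
            names = {k: k for k in sets}
            io.write_gmt(sets, out / "gene_sets.gmt", names)
            save("gene_sets", out / "gene_sets.gmt")
        collection = enrichment.GeneSetCollection.from_sets(sets, universe, names)
        input_genes = gatekeepers if gatekeepers else list(merged["gene"])
        table = enrichment.fisher_enrichment(input_genes, collection,
                                             fdr_thresh=config.fdr_thresh)
        io.write_table(table, out / "enrichment.tsv")
        save("enrichment", out / "enrichment.tsv")
        enrich_rows = len(table)

    # ------------------------------------------------------------- manifest
    manifest = {
        "parameters": _jsonable(asdict(config)),
        "seed": config.seed,
        "stage_seeds": seeds,
        "cleaning": asdict(report),
        "n_merged_genes": int(len(merged)),
        "n_unmapped_genes": int(len(unmapped)),
        "n_gatekeepers": int(len(gatekeepers)),
        "gatekeeper_closure_coverage": coverage,
        "signature_round1_size": len(reduction.round1),
        "signature_round2_size": len(reduction.round2),
        "accuracy": report_cls.accuracy,
        "macro_jaccard": report_cls.macro_jaccard,
        "null_max_jaccard": float(null.jaccard_values.max()),
        "null_empirical_p": null.empirical_p,
        "n_enrichment_sets": enrich_rows,
        "outputs": {},
    }
    for name, path in sorted(outputs.items()):
        p = Path(path)
        if not p.is_file() or p.stat().st_size == 0:
            raise PipelineError(f"declared output missing or empty: {path}")
        manifest["outputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
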