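"""Plain-text readers and writers for the pipeline's file formats.

All formats are TSV or JSON so runs are reproducible and diffable:

* expression — genes x samples TSV, first column ``gene_id``, header row of
  sample ids, log2-scale values;
* design — two-column TSV ``sample_id<TAB>stage``;
* edge list — two-column TSV (optional third ``taxon`` column, filtered when
  a taxon is requested);
* annotation — two-column TSV ``probe<TAB>symbol``;
* ground truth / manifest — JSON with sorted keys.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AnnotationError, ParseError, ValidationError
from .synthetic import GroundTruth, StageDesign

FLOAT_FORMAT = "%.10g"  # fixed text representation keeps reruns byte-identical


# ---------------------------------------------------------------- expression

def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a genes x samples TSV; rejects duplicates and missing values."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        dupes = sorted(matrix.index[matrix.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene ids: {dupes[:10]}")
    if matrix.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in header")
    if matrix.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    return matrix


# -------------------------------------------------------------------- design

def write_design(design: StageDesign, path: str | Path) -> None:
    rows = sorted(design.assignment.items())
    df = pd.DataFrame(rows, columns=["sample_id", "stage"])
    df.to_csv(path, sep="\t", index=False)


def read_design(
    path: str | Path,
    stage_order: Sequence[str],
    control_stages: Sequence[str],
) -> StageDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "stage"]:
        raise ParseError(f"{path}: expected columns sample_id, stage")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return StageDesign(
        assignment=dict(zip(df["sample_id"], df["stage"])),
        stage_order=tuple(stage_order),
        control_stages=tuple(control_stages),
    )


# ----------------------------------------------------------------- edge list

def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path: str | Path, taxon: str | None = None) -> list[tuple[str, str]]:
    """Read raw interaction pairs; rows are NOT cleaned here.

    With a third column present and ``taxon`` given, rows of other taxa are
    dropped (cross-species interaction filtering).
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("node_a", "source", "protein_a"):
                continue
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(f"{path}: line {lineno}: expected two node columns")
            if taxon is not None and len(parts) >= 3 and parts[2] != taxon:
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


# ---------------------------------------------------------------- annotation

def read_annotation(path: str | Path) -> dict[str, str]:
    """Probe -> symbol map from a two-column TSV.

    Many probes may share one symbol.  A probe listed twice with the same
    symbol is deduplicated silently; conflicting symbols raise, listing the
    offenders.  Probes with an empty symbol are dropped (count stored on the
    returned dict as no attribute is possible — reported via AnnotationError
    docs; the loader logs through the pipeline).
    """
    mapping: dict[str, str] = {}
    conflicts: list[str] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("probe", "probe_id"):
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected probe and symbol columns")
            probe, symbol = parts[0], parts[1]
            n_rows += 1
            if not symbol:
                continue
            if probe in mapping and mapping[probe] != symbol:
                conflicts.append(f"{probe}: {mapping[probe]} vs {symbol}")
                continue
            mapping[probe] = symbol
    if conflicts:
        raise AnnotationError(f"{path}: conflicting probe annotations: {conflicts}")
    if n_rows == 0:
        raise ParseError(f"{path}: annotation file is empty")
    return mapping


# ---------------------------------------------------------------------- JSON

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {k: sorted(v) for k, v in asdict(truth).items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        signature_genes=frozenset(payload.get("signature_genes", [])),
        gatekeeper_nodes=frozenset(payload.get("gatekeeper_nodes", [])),
        hub_nodes=frozenset(payload.get("hub_nodes", [])),
    )


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path,
              names: dict[str, str] | None = None) -> None:
    names = names or {}
    with open(path, "w") as fh:
        for sid in sorted(sets):
            members = "\t".join(sets[sid])
            fh.write(f"{sid}\t{names.get(sid, sid)}\t{members}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
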