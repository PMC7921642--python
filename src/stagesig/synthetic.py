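"""Seeded synthetic data for the stage-signature pipeline.

Two generators make every downstream stage exercisable offline:

* :func:`simulate_expression` — a genes x samples log2-scale expression matrix
  over an ordered series of 8 histological stages (the first two pooled as the
  control group), with a planted set of stage-discriminative genes carrying an
  additive, monotone stage effect plus Gaussian noise.  The non-planted
  background defaults to a latent-module co-expression structure (see
  ``SimulationConfig.n_modules``; 0 gives an i.i.d. background), mimicking
  the strong gene-gene correlation of real microarray data on which the
  coefficient-thresholding reduction downstream depends.  Because values
  live on an additive log2-like scale, a fold-change filter downstream is a
  difference of group means.
* :func:`simulate_network` — a scale-free-ish undirected interactome with
  planted hubs (high-degree, pairwise connected) and planted gatekeepers:
  low-degree nodes attached only to mutually connected hubs, so each planted
  gatekeeper has clustering centrality exactly 1 by construction.  A repair
  pass guarantees that *no other* node ends up with centrality 1, so the
  planted set round-trips exactly through gatekeeper detection.

Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_STAGES: tuple[str, ...] = (
    "normal-NF",
    "normal-HF",
    "metaplasia",
    "mild-dysplasia",
    "moderate-dysplasia",
    "severe-dysplasia",
    "carcinoma-in-situ",
    "scc",
)

#: Per-stage sample counts of the motivating microarray series (sum = 107).
DEFAULT_SAMPLES_PER_STAGE: tuple[int, ...] = (13, 14, 15, 13, 13, 12, 13, 14)


@dataclass(frozen=True)
class StageDesign:
    """Assignment of samples to ordered stages, with a pooled control group."""

    assignment: dict[str, str]
    stage_order: tuple[str, ...]
    control_stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.control_stages:
            raise ConfigError("control_stages: must be non-empty")
        unknown = set(self.control_stages) - set(self.stage_order)
        if unknown:
            raise ConfigError(f"control_stages: {sorted(unknown)} not in stage_order")
        bad = {s for s, st in self.assignment.items() if st not in self.stage_order}
        if bad:
            raise ConfigError(f"assignment: samples {sorted(bad)} have unknown stages")

    @property
    def non_control_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stage_order if s not in self.control_stages)

    def samples_for(self, stage: str) -> list[str]:
        return [s for s, st in self.assignment.items() if st == stage]

    def control_samples(self) -> list[str]:
        return [s for s, st in self.assignment.items() if st in self.control_stages]

    def labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[s] for s in sample_ids])


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulation, for recovery checks."""

    signature_genes: frozenset[str] = frozenset()
    gatekeeper_nodes: frozenset[str] = frozenset()
    hub_nodes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the expression simulator.

    effect_size is the per-stage additive shift (log2 expression units) of the
    planted genes: under the default ``"ramp"`` profile a planted gene's mean
    at stage index j (0-based along ``stage_labels``) is
    ``baseline_mean + j * effect_size``; under ``"step"`` it is
    ``baseline_mean + effect_size`` from ``step_stage`` onward.
    """

    n_genes: int = 2000
    n_signature: int = 15
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    samples_per_stage: tuple[int, ...] = DEFAULT_SAMPLES_PER_STAGE
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    n_control_stages: int = 2
    effect_profile: str = "ramp"
    step_stage: int = 4
    n_modules: int = 10
    module_idio_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be >= 1")
        if not 0 <= self.n_signature <= self.n_genes:
            raise ConfigError("n_signature: must satisfy 0 <= n_signature <= n_genes")
        if len(self.stage_labels) != len(set(self.stage_labels)):
            raise ConfigError("stage_labels: duplicate labels")
        if len(self.samples_per_stage) != len(self.stage_labels):
            raise ConfigError("samples_per_stage: length must match stage_labels")
        if any(n < 1 for n in self.samples_per_stage):
            raise ConfigError("samples_per_stage: all counts must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd: must be > 0")
        if not 1 <= self.n_control_stages < len(self.stage_labels):
            raise ConfigError("n_control_stages: must leave at least one test stage")
        if self.effect_profile not in ("ramp", "step"):
            raise ConfigError("effect_profile: must be 'ramp' or 'step'")
        if not 0 <= self.step_stage < len(self.stage_labels):
            raise ConfigError("step_stage: must index a stage")
        if self.n_modules < 0:
            raise ConfigError("n_modules: must be >= 0")
        if self.n_modules > 0 and self.module_idio_sd <= 0:
            raise ConfigError("module_idio_sd: must be > 0 when n_modules > 0")


def _stage_effects(config: SimulationConfig) -> np.ndarray:
    idx = np.arange(len(config.stage_labels), dtype=float)
    if config.effect_profile == "ramp":
        return idx * config.effect_size
    return np.where(idx >= config.step_stage, config.effect_size, 0.0)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, StageDesign, GroundTruth]:
    """Draw a seeded expression matrix with a planted stage signature.

    Returns the genes x samples matrix (rows indexed by gene id, columns by
    sample id), the stage design (first ``n_control_stages`` labels pooled as
    control), and the ground-truth planted gene set.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes - 1)) if config.n_genes > 1 else 1
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]

    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    stage_of_sample: list[int] = []
    k = 0
    for j, (stage, n) in enumerate(zip(config.stage_labels, config.samples_per_stage)):
        for _ in range(n):
            sid = f"s{k:03d}"
            sample_ids.append(sid)
            assignment[sid] = stage
            stage_of_sample.append(j)
            k += 1

    planted_idx = rng.choice(config.n_genes, size=config.n_signature, replace=False)
    planted_idx.sort()
    planted = frozenset(gene_ids[i] for i in planted_idx)

    means = np.full((config.n_genes, len(sample_ids)), config.baseline_mean)
    effects = _stage_effects(config)
    means[planted_idx, :] += effects[np.array(stage_of_sample)]

    n_samples = len(sample_ids)
    if config.n_modules > 0:
        # Co-expression background: each non-planted gene tracks one latent
        # module activity (stage-independent, block-correlation structure)
        # with a near-unit signed loading plus small idiosyncratic noise —
        # the dominant correlation pattern of real microarray data.  Planted
        # genes keep independent Gaussian noise of sd noise_sd.
        scores = rng.normal(0.0, 1.0, size=(config.n_modules, n_samples))
        module_of = rng.integers(0, config.n_modules, size=config.n_genes)
        loading = rng.uniform(0.9, 1.1, size=config.n_genes)
        loading *= rng.choice([-1.0, 1.0], size=config.n_genes)
        noise = loading[:, None] * scores[module_of, :]
        noise += rng.normal(0.0, config.module_idio_sd, size=noise.shape)
        noise[planted_idx, :] = rng.normal(
            0.0, config.noise_sd, size=(config.n_signature, n_samples)
        )
    else:
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    values = means + noise
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    design = StageDesign(
        assignment=assignment,
        stage_order=tuple(config.stage_labels),
        control_stages=tuple(config.stage_labels[: config.n_control_stages]),
    )
    return matrix, design, GroundTruth(signature_genes=planted)


@dataclass(frozen=True)
class NetworkSimConfig:
    """Parameters of the interactome simulator.

    Hubs form a clique and each additionally attaches to ``hub_degree``
    background nodes; each gatekeeper attaches to exactly ``gatekeeper_hubs``
    hubs and nothing else.  The background is preferential-attachment
    (Barabasi-Albert with ``attachment_m`` edges per new node).
    """

    n_nodes: int = 500
    n_hubs: int = 4
    hub_degree: int = 20
    n_gatekeepers: int = 3
    gatekeeper_hubs: int = 2
    attachment: str = "barabasi-albert"
    attachment_m: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ConfigError("n_nodes: must be >= 1")
        if self.n_hubs < 0 or self.n_gatekeepers < 0:
            raise ConfigError("n_hubs/n_gatekeepers: must be >= 0")
        if self.n_gatekeepers >= 1 and self.n_hubs < 2:
            raise ConfigError("n_hubs: must be >= 2 when n_gatekeepers >= 1")
        if self.n_gatekeepers >= 1 and not 2 <= self.gatekeeper_hubs <= self.n_hubs:
            raise ConfigError("gatekeeper_hubs: must satisfy 2 <= gatekeeper_hubs <= n_hubs")
        if self.n_gatekeepers + self.n_hubs > self.n_nodes:
            raise ConfigError("n_nodes: must be >= n_hubs + n_gatekeepers")
        if self.attachment != "barabasi-albert":
            raise ConfigError("attachment: only 'barabasi-albert' is implemented")
        if self.attachment_m < 1:
            raise ConfigError("attachment_m: must be >= 1")
        n_background = self.n_nodes - self.n_hubs - self.n_gatekeepers
        if self.n_gatekeepers + self.n_hubs > 0 and n_background < max(
            self.hub_degree, self.attachment_m + 1, 3
        ):
            raise ConfigError("n_nodes: too few background nodes for hub_degree/attachment_m")


def _centrality_one_nodes(graph: nx.Graph, exclude: set[str]) -> list[str]:
    """Nodes outside `exclude` whose neighborhood is a clique (k >= 2)."""
    tri = nx.triangles(graph)
    out = []
    for node in graph:
        if node in exclude:
            continue
        k = graph.degree(node)
        if k >= 2 and 2 * tri[node] == k * (k - 1):
            out.append(node)
    return out


def simulate_network(
    config: NetworkSimConfig,
    node_ids: Sequence[str] | None = None,
    gatekeeper_ids: Sequence[str] | None = None,
    hub_ids: Sequence[str] | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Draw a seeded interactome with planted hubs and gatekeepers.

    ``node_ids`` (optional, length ``n_nodes``) substitutes caller-supplied
    identifiers — e.g. gene symbols shared with an expression matrix — for the
    default ``n####`` labels; ``gatekeeper_ids``/``hub_ids`` pin the planted
    roles to specific identifiers (they must be among ``node_ids``).

    The returned graph is simple and undirected.  Planted gatekeepers have
    clustering centrality exactly 1, and after the repair pass no non-planted
    node does, so downstream gatekeeper detection recovers exactly the
    planted set.
    """
    rng = np.random.default_rng(config.seed)
    if node_ids is None:
        width = len(str(max(config.n_nodes - 1, 1)))
        node_ids = [f"n{i:0{width}d}" for i in range(config.n_nodes)]
    else:
        node_ids = list(node_ids)
        if len(node_ids) != config.n_nodes:
            raise ConfigError("node_ids: length must equal n_nodes")
        if len(set(node_ids)) != len(node_ids):
            raise ConfigError("node_ids: duplicates present")

    if gatekeeper_ids is None and hub_ids is None:
        gatekeepers = list(node_ids[: config.n_gatekeepers])
        hubs = list(node_ids[config.n_gatekeepers : config.n_gatekeepers + config.n_hubs])
    else:
        gatekeepers = list(gatekeeper_ids or [])
        hubs = list(hub_ids or [])
        if len(gatekeepers) != config.n_gatekeepers or len(hubs) != config.n_hubs:
            raise ConfigError("gatekeeper_ids/hub_ids: lengths must match config counts")
        if set(gatekeepers) & set(hubs):
            raise ConfigError("gatekeeper_ids: overlap with hub_ids")
        if not (set(gatekeepers) | set(hubs)) <= set(node_ids):
            raise ConfigError("gatekeeper_ids/hub_ids: must be members of node_ids")
    planted = set(gatekeepers) | set(hubs)
    background = [n for n in node_ids if n not in planted]

    graph = nx.Graph()
    graph.add_nodes_from(node_ids)

    # Scale-free-ish background; BA needs n > m.
    if len(background) > config.attachment_m:
        ba_seed = int(rng.integers(0, 2**31 - 1))
        ba = nx.barabasi_albert_graph(len(background), config.attachment_m, seed=ba_seed)
        graph.add_edges_from((background[u], background[v]) for u, v in ba.edges())

    # Hubs: pairwise connected, plus hub_degree background attachments each.
    for i, a in enumerate(hubs):
        for b in hubs[i + 1 :]:
            graph.add_edge(a, b)
    for hub in hubs:
        if background:
            picks = rng.choice(len(background), size=min(config.hub_degree, len(background)),
                               replace=False)
            for p in sorted(picks):
                graph.add_edge(hub, background[p])

    # Gatekeepers: attach to a clique of hubs and nothing else.
    for gk in gatekeepers:
        picks = rng.choice(config.n_hubs, size=config.gatekeeper_hubs, replace=False)
        for p in sorted(picks):
            graph.add_edge(gk, hubs[p])

    _repair_accidental_gatekeepers(graph, set(gatekeepers))

    truth = GroundTruth(
        gatekeeper_nodes=frozenset(gatekeepers), hub_nodes=frozenset(hubs)
    )
    return graph, truth


def _repair_accidental_gatekeepers(graph: nx.Graph, protected: set[str]) -> None:
    """Break centrality-1 neighborhoods of non-planted nodes.

    For each offending node v an edge v-u is added where u shares no neighbor
    with v and u is not adjacent to all of v's neighbors: this lowers C(v)
    below 1, cannot raise C(u) (no common neighbors means E_u is unchanged
    while its degree grows), and changes no third node's neighbor-edge count.
    Iterates to a fixed point.
    """
    ordered = sorted(graph.nodes())
    for _ in range(100):
        offenders = _centrality_one_nodes(graph, exclude=protected)
        if not offenders:
            return
        for v in offenders:
            nbrs = set(graph[v])
            repaired = False
            for u in ordered:
                if u == v or u in protected or u in nbrs:
                    continue
                if set(graph[u]) & nbrs:
                    continue
                graph.add_edge(v, u)
                repaired = True
                break
            if not repaired:  # pragma: no cover - essentially impossible off tiny graphs
                raise ConfigError("n_nodes: graph too dense to repair planted structure")
    raise ConfigError("repair did not converge")  # pragma: no cover


def make_gene_sets(
    universe: Sequence[str],
    planted: Sequence[str],
    n_sets: int = 10,
    set_size: int = 25,
    planted_overlap: int = 10,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Small seeded gene-set collection over `universe` for enrichment demos.

    The first set is enriched for the planted genes (``planted_overlap``
    members plus random fill); the rest are uniform draws.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    planted = [g for g in planted if g in set(universe)]
    sets: dict[str, list[str]] = {}
    if n_sets >= 1 and planted:
        take = min(planted_overlap, len(planted), set_size)
        picks = sorted(rng.choice(len(planted), size=take, replace=False))
        members = [planted[i] for i in picks]
        pool = [g for g in universe if g not in set(members)]
        fill = sorted(rng.choice(len(pool), size=max(set_size - take, 0), replace=False))
        sets["SET_PLANTED"] = sorted(members + [pool[i] for i in fill])
    while len(sets) < n_sets:
        picks = sorted(rng.choice(len(universe), size=min(set_size, len(universe)),
                                  replace=False))
        sets[f"SET_{len(sets):03d}"] = [universe[i] for i in picks]
    return sets
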