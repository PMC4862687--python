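"""Similarity-network classification of receptor repertoires.

An all-against-all similarity matrix (p-valued edges) is thresholded into
a graph, embedded by a force-directed layout, and partitioned into convex
clusters; cross-species co-clustering transfers family labels from
reference receptors to unknowns.

The attraction on an edge with p-value p under threshold t is
``-log10(p) + log10(t)`` (positive for every stored edge); cluster
extraction keeps edges whose attraction exceeds the mean by a configured
number of standard deviations and reports connected components of at
least ``min_size`` members.  Convexity of each cluster in the layout is
reported, not enforced: manual merge/split curation directives are
accepted and logged rather than automated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np


@dataclass
class SimilarityGraph:
    """Undirected p-valued similarity graph with attraction weights."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (i, j, p), p < threshold
    p_threshold: float
    labels: dict[str, str] = field(default_factory=dict)  # optional species/family tags

    def attraction(self, p: float) -> float:
        return -math.log10(p) + math.log10(self.p_threshold)

    def attractions(self) -> np.ndarray:
        return np.array([self.attraction(p) for _, _, p in self.edges])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, p in self.edges:
            g.add_edge(a, b, p_value=p, attraction=self.attraction(p))
        return g


@dataclass
class Layout:
    node_order: list[str]
    coordinates: np.ndarray  # (n_nodes, dims)
    rng_seed: int
    iterations_run: int
    energy_trace: np.ndarray | None = None


@dataclass
class ClusterSet:
    clusters: list[set[str]]
    unclustered: set[str]
    labels: list[str] = field(default_factory=list)
    convexity: list[float] = field(default_factory=list)

    def membership(self) -> dict[str, str]:
        out = {n: f"C{i}" for i, cl in enumerate(self.clusters) for n in cl}
        out.update({n: "unclustered" for n in self.unclustered})
        return out


def build_graph(
    edges: Iterable[tuple[str, str, float]],
    p_threshold: float,
    nodes: Sequence[str] | None = None,
    labels: Mapping[str, str] | None = None,
) -> SimilarityGraph:
    """Threshold a p-valued edge list into a :class:`SimilarityGraph`.

    Only edges with p < ``p_threshold`` are stored; symmetric duplicates
    collapse to the smaller p, self-edges are dropped.  If no edge
    survives, a warning is issued and an edge-free graph returned.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    best: dict[tuple[str, str], float] = {}
    seen_nodes: list[str] = list(nodes) if nodes is not None else []
    seen_set = set(seen_nodes)
    for a, b, p in edges:
        for x in (a, b):
            if x not in seen_set:
                seen_set.add(x)
                seen_nodes.append(x)
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if p < p_threshold:
            best[key] = min(best.get(key, 1.0), p)
    kept = [(a, b, p) for (a, b), p in sorted(best.items())]
    if not kept:
        warnings.warn("no edge survives the p-value threshold", stacklevel=2)
    return SimilarityGraph(
        nodes=seen_nodes,
        edges=kept,
        p_threshold=p_threshold,
        labels=dict(labels) if labels else {},
    )


def graph_from_alignments(
    proteins: Sequence, p_threshold: float, labels: Mapping[str, str] | None = None
) -> SimilarityGraph:
    """All-against-all graph from pairwise local alignment of proteins.

    Pairwise E-values come from the mining module's search machinery;
    E-values are clipped into (0, 1] so they can serve as edge p-values.
    """
    from .mining import Seed, search_seeds

    seeds = [Seed(p, "gpcr_seed") for p in proteins]
    edges = []
    for i, q in enumerate(proteins):
        hits = search_seeds([q], seeds[i + 1 :])
        for h in hits:
            edges.append((h.query_id, h.target_id, min(h.e_value, 1.0)))
    return build_graph(edges, p_threshold, nodes=[p.id for p in proteins], labels=labels)


def force_layout(
    graph: SimilarityGraph,
    dims: int = 3,
    iterations: int = 20000,
    seed: int = 0,
    attraction_scale: float = 0.05,
    repulsion_scale: float = 0.05,
) -> Layout:
    """Force-directed embedding of the similarity graph.

    Edges attract proportionally to their attraction weight times the
    current distance; every node pair repels proportionally to inverse
    distance.  Per-step displacement is capped by a linearly cooling
    schedule, which settles the embedding; the run is deterministic given
    the seed (initial coordinates uniform in the unit cube).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = len(graph.nodes)
    rng = np.random.RandomState(seed)
    coords = rng.uniform(size=(n, dims))
    if n <= 1:
        return Layout(list(graph.nodes), coords, seed, iterations)

    idx = {name: i for i, name in enumerate(graph.nodes)}
    if graph.edges:
        ei = np.array([idx[a] for a, _, _ in graph.edges])
        ej = np.array([idx[b] for _, b, _ in graph.edges])
        w = graph.attractions()
    else:
        ei = ej = np.zeros(0, dtype=int)
        w = np.zeros(0)
    w_norm = w / (w.mean() if len(w) else 1.0)

    trace = np.empty(iterations)
    eps = 1e-9
    for t in range(iterations):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2)) + eps
        # pairwise repulsion ~ 1/distance
        rep = repulsion_scale * diff / (dist ** 2)[:, :, None]
        np.einsum("iik->ik", rep)[:] = 0.0
        force = rep.sum(axis=1)
        # attraction along edges ~ weight * distance
        if len(ei):
            pull = attraction_scale * w_norm[:, None] * (coords[ej] - coords[ei])
            np.add.at(force, ei, pull)
            np.add.at(force, ej, -pull)
        cap = max(0.002, 0.1 * (1.0 - t / iterations))
        norm = np.sqrt((force ** 2).sum(axis=1, keepdims=True))
        step = force * np.minimum(1.0, cap / (norm + eps))
        coords = coords + step
        trace[t] = _energy(coords, ei, ej, w_norm, repulsion_scale, attraction_scale)
    return Layout(list(graph.nodes), coords, seed, iterations, energy_trace=trace)


def _energy(coords, ei, ej, w, repulsion_scale, attraction_scale) -> float:
    """Attraction-weighted squared edge lengths minus log-repulsion potential."""
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    iu = np.triu_indices(len(coords), k=1)
    e_rep = -repulsion_scale * np.log(dist[iu] + 1e-9).sum()
    e_att = 0.0
    if len(ei):
        d = np.sqrt(((coords[ei] - coords[ej]) ** 2).sum(axis=1))
        e_att = 0.5 * attraction_scale * float((w * d ** 2).sum())
    return e_att + e_rep


def extract_clusters(
    graph: SimilarityGraph,
    layout: Layout | None = None,
    min_size: int = 4,
    sd_limit: float = 0.5,
) -> ClusterSet:
    """Convex-cluster extraction from the thresholded attraction subgraph.

    Edges whose attraction is at least ``mean + sd_limit * SD`` are kept;
    the statistics run over the full attraction matrix — node pairs
    without a stored edge contribute attraction 0 — so the limit measures
    how far an edge stands out from the typical (mostly absent) pairwise
    attraction, in the style of a global attraction-limit cutoff.
    Connected components with ``min_size`` or more members become
    clusters, everything else is unclustered.  When a layout is given,
    each cluster is annotated with a convexity score: the fraction of
    laid-out points falling inside the cluster's convex hull that belong
    to the cluster.
    """
    if not graph.edges:
        return ClusterSet([], set(graph.nodes))
    att = graph.attractions()
    n = len(graph.nodes)
    n_pairs = n * (n - 1) // 2
    mean = att.sum() / n_pairs
    sd = math.sqrt(max((att**2).sum() / n_pairs - mean**2, 0.0))
    cut = mean + sd_limit * sd
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for (a, b, _), w in zip(graph.edges, att):
        if w >= cut:
            g.add_edge(a, b)
    clusters: list[set[str]] = []
    unclustered: set[str] = set()
    for comp in nx.connected_components(g):
        if len(comp) >= min_size:
            clusters.append(set(comp))
        else:
            unclustered |= comp
    clusters.sort(key=lambda c: (-len(c), min(c)))
    convexity = [
        _convexity_score(cl, layout) if layout is not None else float("nan")
        for cl in clusters
    ]
    return ClusterSet(
        clusters=clusters,
        unclustered=unclustered,
        labels=[f"C{i}" for i in range(len(clusters))],
        convexity=convexity,
    )


def _convexity_score(cluster: set[str], layout: Layout) -> float:
    from scipy.spatial import Delaunay, QhullError

    idx = {n: i for i, n in enumerate(layout.node_order)}
    members = np.array(sorted(idx[n] for n in cluster))
    pts = layout.coordinates[members]
    if len(pts) <= layout.coordinates.shape[1]:
        return 1.0
    try:
        hull = Delaunay(pts)
    except QhullError:
        return 1.0
    inside = hull.find_simplex(layout.coordinates) >= 0
    n_inside = int(inside.sum())
    n_members_inside = int(inside[members].sum())
    return n_members_inside / n_inside if n_inside else 1.0


def co_cluster_label(
    clusters: ClusterSet, reference_labels: Mapping[str, str]
) -> dict[str, str]:
    """Transfer family labels by co-clustering with reference receptors.

    Every non-reference node inherits the majority family label among the
    reference nodes sharing its cluster; a tie yields ``"ambiguous"``
    (tied families recorded in the value, sorted), and clusters without
    any reference member are ``"phylum-specific"``.  Unclustered nodes are
    labeled ``"unclustered"``.
    """
    out: dict[str, str] = {}
    for cl in clusters.clusters:
        fams: dict[str, int] = {}
        for n in cl:
            if n in reference_labels:
                fams[reference_labels[n]] = fams.get(reference_labels[n], 0) + 1
        if not fams:
            label = "phylum-specific"
        else:
            top = max(fams.values())
            winners = sorted(f for f, c in fams.items() if c == top)
            label = winners[0] if len(winners) == 1 else "ambiguous:" + "|".join(winners)
        for n in cl:
            if n not in reference_labels:
                out[n] = label
    for n in clusters.unclustered:
        if n not in reference_labels:
            out[n] = "unclustered"
    return out


@dataclass
class CurationDirective:
    """A logged manual merge/split adjustment to a cluster set."""

    action: str  # "merge" | "split"
    targets: tuple[str, ...]


def apply_curation(
    clusters: ClusterSet, directives: Sequence[CurationDirective]
) -> tuple[ClusterSet, list[str]]:
    """Apply manual merge/split directives, returning the log of actions.

    ``merge A B`` unions cluster labels A and B; ``split C`` dissolves C
    into unclustered.  Mirrors the curation step of hand-adjusted cluster
    maps; every action is logged for provenance.
    """
    labels = list(clusters.labels)
    sets = [set(c) for c in clusters.clusters]
    unclustered = set(clusters.unclustered)
    log: list[str] = []
    for d in directives:
        if d.action == "merge":
            ids = [labels.index(t) for t in d.targets]
            keep = min(ids)
            merged = set()
            for i in ids:
                merged |= sets[i]
            for i in sorted(ids, reverse=True):
                if i != keep:
                    del sets[i], labels[i]
            sets[labels.index(d.targets[0]) if d.targets[0] in labels else keep] = merged
            log.append(f"merge {'+'.join(d.targets)} -> {labels[keep]} ({len(merged)} nodes)")
        elif d.action == "split":
            i = labels.index(d.targets[0])
            unclustered |= sets[i]
            log.append(f"split {d.targets[0]} ({len(sets[i])} nodes -> unclustered)")
            del sets[i], labels[i]
        else:
            raise ValueError(f"unknown curation action {d.action!r}")
    return ClusterSet(sets, unclustered, labels, [float("nan")] * len(sets)), log
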