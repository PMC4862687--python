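"""Receptor-family phylogenetics: progressive alignment, Jukes-Cantor
distances, neighbor-joining trees, bootstrap supports, outgroup rooting.

The aligner is a minimal deterministic progressive aligner (pairwise
global alignments -> distance-based guide tree -> profile-profile
merging).  Distances use the generalized k-state Jukes-Cantor correction
(k = 20 for proteins) with pairwise deletion of gapped columns.  The NJ
builder follows the classic Q-matrix algorithm with lexicographic
tie-breaking and clamping of negative branch lengths (the deficit moves
to the sister edge, preserving path lengths).  Bayesian tree inference is
out of scope; :func:`write_bayesian_run_parameters` records the run
settings for external use alongside the exported alignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord, write_fasta


@dataclass
class MultipleAlignment:
    rows: list[tuple[str, str]]  # (id, gapped sequence)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(i, s, "protein") for i, s in self.rows]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    saturated: np.ndarray | None = None  # pairs where the JC correction overflowed

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        self.d = d


# ---------------------------------------------------------------------------
# progressive alignment

_GAP_COL_SCORE = -4.0


def _pairwise_global(a: str, b: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner.align(a, b)[0]


def _profile_columns(rows: list[str]) -> list[tuple[str, ...]]:
    return [tuple(r[k] for r in rows) for k in range(len(rows[0]))]


def _col_score(ca: tuple[str, ...], cb: tuple[str, ...], matrix) -> float:
    total = 0.0
    n = 0
    for x in ca:
        for y in cb:
            n += 1
            if x == "-" or y == "-":
                total += 0.0
            else:
                total += matrix[x, y]
    return total / n


def _align_profiles(rows_a: list[str], rows_b: list[str], matrix) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch over profile columns with linear gap costs."""
    ca = _profile_columns(rows_a)
    cb = _profile_columns(rows_b)
    la, lb = len(ca), len(cb)
    score = np.zeros((la + 1, lb + 1))
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = _GAP_COL_SCORE * np.arange(1, la + 1)
    score[0, 1:] = _GAP_COL_SCORE * np.arange(1, lb + 1)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1, j - 1] + _col_score(ca[i - 1], cb[j - 1], matrix)
            up = score[i - 1, j] + _GAP_COL_SCORE
            left = score[i, j - 1] + _GAP_COL_SCORE
            best = max(diag, up, left)
            score[i, j] = best
            move[i, j] = 0 if best == diag else (1 if best == up else 2)
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = la, lb
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            i, j = i - 1, j - 1
        elif m == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r in out_b:
                r.append("-")
            i -= 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            j -= 1
    return ["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b]


def progressive_align(proteins: Sequence[SequenceRecord]) -> MultipleAlignment:
    """Deterministic progressive multiple alignment.

    Pairwise global alignments give identity-based distances; an
    average-linkage guide tree fixes the merge order; profiles are merged
    by column-wise Needleman-Wunsch.
    """
    if len(proteins) < 2:
        raise ValueError("progressive_align needs at least 2 sequences")
    matrix = substitution_matrices.load("BLOSUM62")
    n = len(proteins)
    seqs = [p.seq for p in proteins]
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = _pairwise_global(seqs[i], seqs[j])
        a, b = str(aln[0]), str(aln[1])
        ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        dist[i, j] = dist[j, i] = 1.0 - ident / len(a)

    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    link = average(squareform(dist, checks=False)) if n > 2 else None

    # merge in guide-tree order; cluster id -> (member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    if link is None:
        merges = [(0, 1)]
    else:
        merges = [(int(a), int(b)) for a, b, _, _ in link]
    next_id = n
    for a, b in merges:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b = _align_profiles(rows_a, rows_b, matrix)
        clusters[next_id] = (ids_a + ids_b, new_a + new_b)
        next_id += 1
    member_ids, rows = clusters.popitem()[1]
    order = np.argsort(member_ids)
    return MultipleAlignment(
        [(proteins[member_ids[k]].id, rows[k]) for k in order]
    )


# ---------------------------------------------------------------------------
# distances


def jc_distance(
    alignment: MultipleAlignment, alphabet_size: int = 20, cap: float = 10.0
) -> DistanceMatrix:
    """Generalized k-state Jukes-Cantor distances with pairwise deletion.

    d = -((k-1)/k) * ln(1 - (k/(k-1)) * p) where p is the mismatch
    fraction over columns where both rows are ungapped.  Saturated pairs
    (p >= (k-1)/k, or no shared ungapped column) receive the configured
    cap and are flagged.
    """
    k = alphabet_size
    if k < 2:
        raise ValueError("alphabet_size must be >= 2")
    ids = alignment.ids
    n = len(ids)
    arr = np.array([list(s) for _, s in alignment.rows])
    gaps = arr == "-"
    d = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    limit = (k - 1) / k
    for i, j in itertools.combinations(range(n), 2):
        both = ~gaps[i] & ~gaps[j]
        m = int(both.sum())
        if m == 0:
            dij, sat = cap, True
        else:
            p = float((arr[i][both] != arr[j][both]).sum()) / m
            if p >= limit:
                dij, sat = cap, True
            else:
                dij = -limit * math.log(1.0 - p / limit)
                sat = False
        d[i, j] = d[j, i] = dij
        saturated[i, j] = saturated[j, i] = sat
    return DistanceMatrix(ids, d, saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor-joining tree from a distance matrix.

    Q-matrix minimization with ties broken by the lexicographic pair of
    cluster labels (a cluster is labeled by its lexicographically smallest
    leaf).  Negative branch lengths are clamped to zero with the deficit
    moved to the sister edge, preserving the joined pair's path length.
    The returned tree is unrooted.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dist.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: dict[str, dendropy.Node] = {}
    for name in dist.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes[name] = node
    # active cluster labels -> (node, min-leaf label)
    active = {name: name for name in dist.ids}  # label -> min leaf
    d = {
        frozenset((a, b)): dist.d[i, j]
        for (i, a), (j, b) in itertools.combinations(enumerate(dist.ids), 2)
    }

    def dget(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    while len(active) > 3:
        labels = sorted(active, key=lambda x: active[x])
        r = len(labels)
        row_sum = {a: sum(dget(a, b) for b in labels if b != a) for a in labels}
        best = None
        for a, b in itertools.combinations(labels, 2):
            q = (r - 2) * dget(a, b) - row_sum[a] - row_sum[b]
            key = tuple(sorted((active[a], active[b])))
            if best is None or (q, key) < (best[0], best[1]):
                best = (q, key, a, b)
        _, _, a, b = best
        la = 0.5 * dget(a, b) + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = dget(a, b) - la
        la, lb = _clamp_pair(la, lb)
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length, nb.edge.length = la, lb
        parent.add_child(na)
        parent.add_child(nb)
        new_label = f"__join_{len(d)}"
        nodes[new_label] = parent
        for c in labels:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (
                dget(a, c) + dget(b, c) - dget(a, b)
            )
        min_leaf = min(active[a], active[b])
        del active[a], active[b]
        active[new_label] = min_leaf

    a, b, c = sorted(active, key=lambda x: active[x])
    la = 0.5 * (dget(a, b) + dget(a, c) - dget(b, c))
    lb = 0.5 * (dget(a, b) + dget(b, c) - dget(a, c))
    lc = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
    center = dendropy.Node()
    for label, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(label)
        node.edge.length = max(ln, 0.0)
        center.add_child(node)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return la, max(lb, 0.0)


def tree_path_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(t1, t2)
    return out


# ---------------------------------------------------------------------------
# bootstrap


def _internal_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, keyed by one side."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    bips: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        bips.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return bips


def bootstrap_support(
    alignment: MultipleAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    alphabet_size: int = 20,
) -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap supports (percent).

    Supports of the full-data tree's internal bipartitions are the
    percentage of replicate trees containing them, written to internal
    node labels.  Deterministic given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = neighbor_joining(jc_distance(alignment, alphabet_size))
    rng = np.random.RandomState(seed)
    counts: dict[frozenset, int] = {b: 0 for b in _internal_bipartitions(tree)}
    length = alignment.length
    for _ in range(n_replicates):
        cols = rng.randint(0, length, size=length)
        rep_rows = [(i, "".join(s[c] for c in cols)) for i, s in alignment.rows]
        rep_tree = neighbor_joining(
            jc_distance(MultipleAlignment(rep_rows), alphabet_size)
        )
        for b in _internal_bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1

    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.label = f"{100.0 * counts[key] / n_replicates:g}"
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_ids: Sequence[str]) -> dendropy.Tree:
    """Root on the edge separating a monophyletic outgroup from the ingroup.

    The root lands at the midpoint of that edge.  A paraphyletic outgroup
    is an error naming the conflicting split.
    """
    out = set(outgroup_ids)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if not out <= leaves:
        raise ValueError(f"outgroup ids not in tree: {sorted(out - leaves)}")
    tree = tree.clone(depth=1)
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if side == out or side == leaves - out:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(out)} is not monophyletic: no edge induces the "
            f"bipartition {sorted(out)} | {sorted(leaves - out)}"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half)
    tree.is_rooted = True
    return tree


def write_bayesian_run_parameters(path: str | Path, **overrides) -> None:
    """Record the Bayesian-inference settings used externally (not re-run here)."""
    params = {
        "model": "WAG",
        "generations": 200000,
        "burnin_fraction": 0.25,
        "chains": 4,
    }
    params.update(overrides)
    with Path(path).open("w") as fh:
        fh.write("parameter\tvalue\n")
        for k, v in params.items():
            fh.write(f"{k}\t{v}\n")


def export_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    write_fasta(alignment.to_records(), path)
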