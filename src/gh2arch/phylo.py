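"""Distance-based phylogenetics for the catalytic-domain alignment.

The tree stage is deliberately self-contained: p-distances (with
pairwise or complete gap deletion), Poisson or Kimura protein distance
corrections, Saitou–Nei neighbor-joining with deterministic
tie-breaking, nonparametric bootstrap over alignment columns, and
condensation of weakly supported edges into polytomies. Alignments can
be exported (aligned FASTA / PHYLIP) for cross-checking with external
maximum-likelihood software; the analyses here rest on topology-level
statements (which architecture types cluster together), which are
robust to the choice of tree criterion.

Trees are :class:`skbio.TreeNode` objects; bootstrap supports live on
internal nodes as ``node.support`` in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .msa import GAP, MSA

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; saturated pairs are ``inf``."""

    ids: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        finite = np.isfinite(m)
        if not np.allclose(m[finite & finite.T], m.T[finite & finite.T]):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m[finite] < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    @property
    def saturated_pairs(self) -> list:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if not math.isfinite(self.matrix[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.matrix[i])
                fh.write(f"{sid}  {row}\n")


def p_distance(msa: MSA, pair: tuple, deletion: str = "pairwise") -> float:
    """Fraction of differing residues among comparable columns of two
    alignment rows.

    Under ``pairwise`` deletion a column counts if neither row has a gap
    there; under ``complete`` deletion, only columns gap-free across the
    whole alignment count for every pair.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    a = np.frombuffer(msa.row(pair[0]).encode(), dtype="S1")
    b = np.frombuffer(msa.row(pair[1]).encode(), dtype="S1")
    gap = GAP.encode()
    if deletion == "complete":
        arr = msa.to_array()
        keep = ~(arr == GAP).any(axis=0)
    else:
        keep = (a != gap) & (b != gap)
    comparable = int(keep.sum())
    if comparable == 0:
        raise ValueError(f"no comparable columns for pair {pair}")
    diffs = int(((a != b) & keep).sum())
    return diffs / comparable


def correct_distance(p: float, method: str = "kimura") -> float:
    """Transform a p-distance into an evolutionary distance.

    ``none`` returns p; ``poisson`` is −ln(1−p); ``kimura`` is the
    protein-distance approximation −ln(1 − p − 0.2 p²). A p at or above
    the method's domain bound saturates and is returned as ``inf``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1]")
    if method == "none":
        return p
    if method == "poisson":
        arg = 1.0 - p
    elif method == "kimura":
        arg = 1.0 - p - 0.2 * p * p
    else:
        raise ValueError(f"unknown correction method {method!r}")
    if arg <= 0.0:
        return math.inf
    return -math.log(arg)


def distance_matrix(
    msa: MSA, method: str = "kimura", deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs corrected distances from an alignment (vectorised)."""
    arr = msa.to_array()
    n = len(msa.ids)
    gaps = arr == GAP
    eq = arr[:, None, :] == arr[None, :, :]
    if deletion == "complete":
        keep = ~gaps.any(axis=0)
        comparable = np.full((n, n), int(keep.sum()))
        diffs = (~eq & keep[None, None, :]).sum(axis=2)
    else:
        ok = ~gaps[:, None, :] & ~gaps[None, :, :]
        comparable = ok.sum(axis=2)
        diffs = (~eq & ok).sum(axis=2)
    if np.any(comparable == 0):
        raise ValueError("some pair has zero comparable columns")
    p = diffs / comparable
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = correct_distance(float(p[i, j]), method)
    return DistanceMatrix(list(msa.ids), out)


# ---------------------------------------------------------------------------
# neighbor joining


def nj(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining.

    Pair choice uses the standard Q criterion, with ties broken by the
    lowest (row-major) index pair. Negative branch-length estimates are
    clamped to zero and the clamped deficit logged. The returned tree is
    unrooted, represented with a trifurcating root.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.saturated_pairs:
        raise ValueError(
            f"saturated distances for pairs {dm.saturated_pairs[:3]}..."
        )
    D = dm.matrix.copy()
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum in row-major order
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp(li), _clamp(lj)
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent.extend([a, b])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        newD = np.zeros((n - 1, n - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]
    # three-point resolution of the final star
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        _clamp(0.5 * (d01 + d02 - d12)),
        _clamp(0.5 * (d01 + d12 - d02)),
        _clamp(0.5 * (d02 + d12 - d01)),
    )
    root = TreeNode()
    for node, length in zip(nodes, lengths):
        node.length = length
        root.append(node)
    root.support = None
    return root


def _clamp(length: float) -> float:
    if length < 0:
        logger.debug("clamping negative branch length %.6g to 0", length)
        return 0.0
    return float(length)


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (the additive matrix it
    induces)."""
    tips = sorted(t.name for t in tree.tips())
    td = tree.tip_tip_distances()
    order = [list(td.ids).index(t) for t in tips]
    mat = np.asarray(td.data)[np.ix_(order, order)]
    return DistanceMatrix(tips, mat)


def bipartitions(tree: TreeNode) -> dict:
    """Canonical internal bipartitions of an unrooted tree.

    Maps each non-trivial split (canonicalised as the lexicographically
    smaller of the two sides, shortest first) to the tree node under the
    defining edge.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(all_tips - side) <= 1:
            continue
        out[canonical_split(side, all_tips)] = node
    return out


def canonical_split(side: frozenset, all_tips: frozenset) -> frozenset:
    other = all_tips - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def bootstrap_support(
    msa: MSA,
    n_replicates: int = 100,
    seed: int = 0,
    method: str = "kimura",
    deletion: str = "pairwise",
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate is re-aligned-free (same columns, resampled) and passed
    through the same distance + NJ stage. The support of each internal
    edge of the full-data tree is the fraction of successful replicates
    whose tree contains the same bipartition. Replicates whose distance
    matrix saturates are dropped and logged. Identical seeds give
    identical supports.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    full = nj(distance_matrix(msa, method, deletion))
    all_tips = frozenset(t.name for t in full.tips())
    edges = bipartitions(full)
    counts = {split: 0 for split in edges}
    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    completed = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row[c] for c in cols) for row in msa.rows]
        rep = MSA(list(msa.ids), rep_rows)
        try:
            rep_tree = nj(distance_matrix(rep, method, deletion))
        except ValueError as exc:
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        completed += 1
        rep_splits = set(bipartitions(rep_tree))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if completed == 0:
        raise ValueError("all bootstrap replicates failed")
    for split, node in edges.items():
        node.support = counts[split] / completed
    for tip in full.tips():
        tip.support = None
    full.support = None
    return full


def condense(tree: TreeNode, threshold: float = 0.5) -> TreeNode:
    """Collapse internal edges with support strictly below ``threshold``
    into polytomies; edges at exactly the threshold are retained.

    The collapsed edge (and its length) disappears — its children attach
    directly to the grandparent, the usual condensed-tree convention.
    Idempotent, and never increases the internal-edge count.
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.non_tips(include_self=False)):
            support = getattr(node, "support", None)
            if support is not None and support < threshold:
                parent = node.parent
                for child in list(node.children):
                    parent.append(child)
                parent.remove(node)
                changed = True
    return out


# ---------------------------------------------------------------------------
# DA-type / tree concordance


@dataclass(frozen=True)
class LabelConcordance:
    label: str
    monophyletic: bool
    clade_size: int
    purity: float


@dataclass
class ConcordanceReport:
    per_label: dict = field(default_factory=dict)
    nesting: dict = field(default_factory=dict)

    def is_nested(self, inner, outer) -> bool:
        return self.nesting.get((str(inner), str(outer)), False)


def concordance(tree: TreeNode, labels: Mapping) -> ConcordanceReport:
    """How well leaf labels agree with the tree's clades.

    For each label: is its leaf set monophyletic in the unrooted sense
    (some split separates exactly that set), what is the smallest clade
    (split side) containing it, and the label's purity inside that
    clade. The nesting matrix marks label A strictly inside label B's
    smallest containing clade. Singleton labels are monophyletic by
    convention.
    """
    tips = [t.name for t in tree.tips()]
    unlabeled = [t for t in tips if t not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled[:5]}")
    all_tips = frozenset(tips)
    sides = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        sides.add(side)
        sides.add(all_tips - side)
    for t in tips:
        sides.add(frozenset([t]))
        sides.add(all_tips - frozenset([t]))
    sides.add(all_tips)

    by_label: dict = {}
    for tip, label in labels.items():
        if tip in all_tips:
            by_label.setdefault(str(label), set()).add(tip)

    report = ConcordanceReport()
    smallest: dict = {}
    for label, members in sorted(by_label.items()):
        members = frozenset(members)
        mono = len(members) == 1 or members == all_tips or members in sides
        containing = min(
            (s for s in sides if members <= s),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        smallest[label] = containing
        report.per_label[label] = LabelConcordance(
            label=label,
            monophyletic=mono,
            clade_size=len(containing),
            purity=len(members) / len(containing),
        )
    for a in by_label:
        for b in by_label:
            if a == b:
                continue
            report.nesting[(a, b)] = smallest[a] < smallest[b]
    return report


def union_monophyletic(tree: TreeNode, labels: Mapping, group: Iterable) -> bool:
    """Is the union of the given labels' leaves a clade of the tree?"""
    wanted = {str(g) for g in group}
    members = frozenset(
        t.name for t in tree.tips() if str(labels[t.name]) in wanted
    )
    all_tips = frozenset(t.name for t in tree.tips())
    if len(members) <= 1 or members == all_tips:
        return True
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == members or all_tips - side == members:
            return True
    return False


def separating_edge_support(tree: TreeNode, labels: Mapping, group: Iterable):
    """Bootstrap support of the edge splitting the given labels' leaves
    from the rest, or ``None`` if no such edge exists."""
    wanted = {str(g) for g in group}
    members = frozenset(
        t.name for t in tree.tips() if str(labels[t.name]) in wanted
    )
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == members or all_tips - side == members:
            return getattr(node, "support", None)
    return None


# ---------------------------------------------------------------------------
# subclustering and representative selection


def subcluster_and_select(
    dm: DistanceMatrix,
    cut: float,
    quota: int,
    seed: int = 0,
) -> tuple[list, dict]:
    """Single-linkage subclusters at a distance cut, plus a seeded
    representative selection.

    Every subcluster contributes at least one representative (its
    lexicographically smallest member); the remaining quota is filled by
    seeded uniform sampling without replacement. A quota exceeding the
    pool returns the whole pool (logged). Deterministic given the seed.
    """
    ids = list(dm.ids)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if dm.matrix[i, j] <= cut:
                parent[find(a)] = find(ids[j])
    clusters: dict = {}
    for sid in ids:
        clusters.setdefault(find(sid), []).append(sid)
    ordered = sorted(clusters.values(), key=lambda c: min(c))
    subcluster_of = {
        sid: f"SC{k + 1}" for k, comp in enumerate(ordered) for sid in comp
    }
    if quota >= len(ids):
        if quota > len(ids):
            logger.info("quota %d exceeds pool %d; taking all", quota, len(ids))
        return sorted(ids), subcluster_of
    if quota < len(ordered):
        raise ValueError(
            f"quota {quota} below subcluster count {len(ordered)}; "
            "cannot represent every subcluster"
        )
    chosen = [min(comp) for comp in ordered]
    pool = sorted(set(ids) - set(chosen))
    rng = np.random.default_rng(seed)
    extra = rng.choice(len(pool), size=quota - len(chosen), replace=False)
    chosen.extend(pool[k] for k in sorted(extra))
    return sorted(chosen), subcluster_of
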