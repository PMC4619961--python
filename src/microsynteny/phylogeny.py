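"""Family phylogenetics: Poisson distances, neighbor-joining, bootstrap.

Distances are Poisson-corrected amino-acid distances with pairwise
deletion (columns gapped or unknown in either of the two rows being
compared are dropped): ``d = -ln(1 - p)`` with p the mismatch proportion
over the retained columns. Trees are built with Saitou-Nei
neighbor-joining; support comes from column-resampling bootstrap over the
same distance + NJ procedure. Negative NJ branch-length estimates are
clamped to zero and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .homology import align_global

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "poisson_distance",
    "poisson_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "align_family",
]

_GAP_CHARS = {"-", ".", "X", "?"}


# ---------------------------------------------------------------------------
# Distances


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance between two equal-length gapped rows.

    Pairwise deletion: columns where either row holds a gap or an unknown
    residue are excluded from both numerator and denominator. Returns inf
    when all retained columns mismatch; raises if no column is retained.
    """
    if len(a) != len(b):
        raise ValueError("rows differ in length")
    retained = mism = 0
    for x, y in zip(a, b):
        if x in _GAP_CHARS or y in _GAP_CHARS:
            continue
        retained += 1
        if x != y:
            mism += 1
    if retained == 0:
        raise ValueError("no columns retained under pairwise deletion")
    p = mism / retained
    if p >= 1.0:
        return math.inf
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal over ordered taxa."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distance")


def _encode(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    mat = np.zeros((len(taxa), lengths.pop()), dtype=np.int16)
    for i, t in enumerate(taxa):
        row = alignment[t]
        mat[i] = [-1 if ch in _GAP_CHARS else ord(ch) for ch in row]
    return taxa, mat


def _matrix_from_encoded(mat: np.ndarray) -> np.ndarray:
    valid = (mat[:, None, :] >= 0) & (mat[None, :, :] >= 0)
    mism = valid & (mat[:, None, :] != mat[None, :, :])
    retained = valid.sum(axis=2)
    if np.any(retained == 0):
        raise ValueError("a pair retains no columns under pairwise deletion")
    p = mism.sum(axis=2) / retained
    with np.errstate(divide="ignore"):
        d = -np.log(1.0 - p)
    np.fill_diagonal(d, 0.0)
    return d


def poisson_distance_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Poisson pairwise-deletion distance matrix over an aligned protein set."""
    taxa, mat = _encode(alignment)
    return DistanceMatrix(taxa=taxa, d=_matrix_from_encoded(mat))


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    """A node of an unrooted tree (represented with a trifurcating root)."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None
    clamped: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-or-canonical leaf set."""
        all_leaves = self.leaf_names()
        splits: set[frozenset[str]] = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = node.leaf_names()
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def is_monophyletic(self, group: Iterable[str]) -> bool:
        """True if some edge of the unrooted tree separates exactly this group."""
        group = frozenset(group)
        all_leaves = self.leaf_names()
        if group == all_leaves or len(group) == 1:
            return True
        comp = all_leaves - group
        canon = min(group, comp, key=lambda s: (len(s), sorted(s)))
        if len(group) == len(all_leaves) - 1:
            return True  # complement is a single leaf: always an edge
        return canon in self.bipartitions()

    def support_of(self, group: Iterable[str]) -> float | None:
        """Bootstrap support of the edge separating ``group``, if present."""
        group = frozenset(group)
        all_leaves = self.leaf_names()
        canon = min(group, all_leaves - group, key=lambda s: (len(s), sorted(s)))
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = node.leaf_names()
            if min(side, all_leaves - side, key=lambda s: (len(s), sorted(s))) == canon:
                return node.support
        return None

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if include_support and node.support is not None and not top:
                label = f"{node.support:g}"
            length = "" if top else f":{node.length:.6f}"
            return f"({inner}){label}{length}"

        return fmt(self, True) + ";"


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining on a distance matrix.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest (taxon, taxon) pair, internal nodes being
    keyed by their smallest descendant leaf. Negative branch-length
    estimates are clamped to 0 and flagged on the node.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    keys: list[str] = list(dm.taxa)  # smallest leaf name per active node
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(node: TreeNode, length: float) -> None:
        if length < 0:
            node.length = 0.0
            node.clamped = True
        else:
            node.length = length

    while len(active) > 3:
        idx = np.array(active)
        m = len(idx)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = np.argwhere(q <= qmin + 1e-12)
        ai, aj = min(
            ((a, b) for a, b in cands if a < b),
            key=lambda ab: tuple(sorted((keys[idx[ab[0]]], keys[idx[ab[1]]]))),
        )
        i, j = int(idx[ai]), int(idx[aj])
        li = d[i, j] / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new = TreeNode(children=[nodes[i], nodes[j]])
        clamp(nodes[i], li)
        clamp(nodes[j], lj)
        # grow matrix by one row/column for the new node
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = (d[i, x] + d[j, x] - d[i, j]) / 2.0
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = sorted(active, key=lambda x: keys[x])
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    clamp(nodes[i], (d[i, j] + d[i, k] - d[j, k]) / 2.0)
    clamp(nodes[j], (d[i, j] + d[j, k] - d[i, k]) / 2.0)
    clamp(nodes[k], (d[i, k] + d[j, k] - d[i, j]) / 2.0)
    return root


def bootstrap_support(
    alignment: Mapping[str, str],
    replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with bootstrap support on internal edges.

    Alignment columns are resampled with replacement ``replicates`` times;
    each replicate is re-distanced (Poisson, pairwise deletion) and re-built
    with NJ. Support is the percentage of replicates containing each
    internal bipartition of the original tree. Reproducible for fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    taxa, mat = _encode(alignment)
    tree = nj_tree(DistanceMatrix(taxa=taxa, d=_matrix_from_encoded(mat)))
    target = tree.bipartitions()
    counts: dict[frozenset[str], int] = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    ncol = mat.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        sub = mat[:, cols]
        try:
            rep_tree = nj_tree(DistanceMatrix(taxa=taxa, d=_matrix_from_encoded(sub)))
        except ValueError:
            continue  # replicate with an undefined distance contributes nothing
        rep_splits = rep_tree.bipartitions()
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    all_leaves = tree.leaf_names()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        canon = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
        if canon in counts:
            node.support = 100.0 * counts[canon] / replicates
    return tree


# ---------------------------------------------------------------------------
# Convenience multiple alignment (center-star over the exact pairwise aligner)


def align_family(proteins: Mapping[str, str]) -> dict[str, str]:
    """Center-star multiple alignment for small protein families.

    The longest sequence is the center; every other sequence is globally
    aligned to it and the pairwise gap patterns are merged. A convenience
    for desk-scale fixtures, not a progressive-profile aligner.
    """
    ids = list(proteins)
    if len(ids) == 1:
        return dict(proteins)
    center = max(ids, key=lambda i: (len(proteins[i]), i))
    master_center = proteins[center]
    rows: dict[str, str] = {center: master_center}
    for other in ids:
        if other == center:
            continue
        aln = align_global(proteins[center], proteins[other])
        merged_center, merged_rows, new_row = _merge(
            master_center, rows, aln.aligned_a, aln.aligned_b
        )
        master_center = merged_center
        rows = merged_rows
        rows[other] = new_row
    return {i: rows[i] for i in ids}


def _merge(
    master: str, rows: dict[str, str], pair_center: str, pair_other: str
) -> tuple[str, dict[str, str], str]:
    """Merge a new pairwise alignment into the growing master alignment."""
    out_master: list[str] = []
    out_rows: dict[str, list[str]] = {k: [] for k in rows}
    out_new: list[str] = []
    i = j = 0
    while i < len(master) or j < len(pair_center):
        mc = master[i] if i < len(master) else None
        pc = pair_center[j] if j < len(pair_center) else None
        if mc is not None and mc == "-" and (pc is None or pc != "-"):
            out_master.append("-")
            for k in rows:
                out_rows[k].append(rows[k][i])
            out_new.append("-")
            i += 1
        elif pc is not None and pc == "-" and (mc is None or mc != "-"):
            out_master.append("-")
            for k in rows:
                out_rows[k].append("-")
            out_new.append(pair_other[j])
            j += 1
        else:
            out_master.append(mc if mc is not None else "-")
            for k in rows:
                out_rows[k].append(rows[k][i] if i < len(master) else "-")
            out_new.append(pair_other[j] if j < len(pair_center) else "-")
            i += 1
            j += 1
    merged = {k: "".join(v) for k, v in out_rows.items()}
    return "".join(out_master), merged, "".join(out_new)
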