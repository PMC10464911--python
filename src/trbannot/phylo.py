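"""Distance matrices, neighbor-joining trees and bootstrap supports.

Implements the Saitou-Nei neighbor-joining algorithm with the standard
Q-criterion and a deterministic tie-break (lowest index pair joins
first), p / Poisson-corrected / Kimura-2-parameter distances with
pairwise or complete gap deletion, and column-resampling bootstrap with
supports mapped onto the full-data tree. NJ recovers generating trees
exactly from additive distance matrices, which the test suite exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "compute_distances",
    "nj_tree",
    "bootstrap_supports",
]

SATURATION_CEILING = 10.0

_GAPS = set("-.")
_NUC = set("ACGT")
_PURINES = set("AG")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    deletion_mode: str = "pairwise"
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v
        if self.saturated is None:
            self.saturated = np.zeros_like(v, dtype=bool)


@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0          # branch length to parent (clamped >= 0)
    raw_length: float = 0.0      # original NJ estimate (may be negative)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree represented with a (trifurcating) root node."""

    root: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the alphabetically first taxon."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out = set()

        def walk(node):
            clade = frozenset(l.name for l in node.leaves())
            if node is not self.root and not node.is_leaf:
                side = clade if anchor not in clade else all_leaves - clade
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(side)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------


def _pair_distance(a: str, b: str, model: str) -> tuple[float, bool]:
    """Distance for one pre-filtered (no-gap) site pair list."""
    n = len(a)
    if n == 0:
        return 0.0, True
    if model == "k2p":
        ts = tv = 0
        for x, y in zip(a, b):
            if x == y:
                continue
            if (x in _PURINES) == (y in _PURINES):
                ts += 1
            else:
                tv += 1
        P, Q = ts / n, tv / n
        arg1 = 1 - 2 * P - Q
        arg2 = 1 - 2 * Q
        if arg1 <= 0 or arg2 <= 0:
            return SATURATION_CEILING, True
        return -0.5 * math.log(arg1) - 0.25 * math.log(arg2), False
    p = sum(1 for x, y in zip(a, b) if x != y) / n
    if model == "p":
        return p, False
    if model == "poisson":
        if p >= 1:
            return SATURATION_CEILING, True
        return -math.log(1 - p), False
    raise ValueError(f"unknown model {model!r}")


def compute_distances(
    alignment: dict[str, str] | list[tuple[str, str]],
    model: str = "p",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``model``: p (proportion of differing sites), poisson (-ln(1-p)) or
    k2p (nucleotides only). ``deletion``: pairwise skips sites gapped in
    either sequence of a pair; complete drops columns gapped anywhere.
    Saturated entries (log argument <= 0) are set to a ceiling and
    flagged.
    """
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    ids = [k for k, _ in items]
    seqs = [s.upper() for _, s in items]
    if len(set(len(s) for s in seqs)) > 1:
        raise ValueError("alignment sequences differ in length")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    if deletion == "complete":
        keep = [
            i
            for i in range(len(seqs[0]))
            if all(s[i] not in _GAPS for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    n = len(ids)
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            fa, fb = [], []
            for x, y in zip(a, b):
                if x in _GAPS or y in _GAPS:
                    continue
                fa.append(x)
                fb.append(y)
            d, sat = _pair_distance("".join(fa), "".join(fb), model)
            values[i, j] = values[j, i] = d
            saturated[i, j] = saturated[j, i] = sat
    return DistanceMatrix(ids, values, deletion, saturated)


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion resolve to the lowest (i, j) index pair in
    the current node ordering. Negative branch-length estimates are
    clamped to zero with the raw value preserved.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = matrix.values.astype(float).copy()
    nodes = [TreeNode(name=i) for i in matrix.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].raw_length, nodes[j].raw_length = li, lj
        nodes[i].length, nodes[j].length = max(li, 0.0), max(lj, 0.0)
        new_row = np.array(
            [0.5 * (D[i, k] + D[j, k] - dij) for k in range(m) if k not in (i, j)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
    # final three nodes join at the (trifurcating) root
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, l in ((a, la), (b, lb), (c, lc)):
        node.raw_length = l
        node.length = max(l, 0.0)
    return Tree(TreeNode(children=[a, b, c]))


def bootstrap_supports(
    alignment: dict[str, str] | list[tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
    deletion: str = "pairwise",
) -> Tree:
    """Bootstrap column resampling; supports on the full-data NJ tree.

    Supports are the percentage of replicates whose NJ tree contains each
    bipartition of the full-data tree (not a majority-rule consensus
    topology). Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    ids = [k for k, _ in items]
    seqs = [s for _, s in items]
    L = len(seqs[0])
    full = nj_tree(compute_distances(items, model, deletion))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        resampled = [(ids[i], "".join(seqs[i][c] for c in cols)) for i in range(len(ids))]
        try:
            rep = nj_tree(compute_distances(resampled, model, deletion))
        except ValueError:
            continue
        found = rep.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    full.supports = supports
    _attach_supports(full)
    return full


def _attach_supports(tree: Tree) -> None:
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)

    def walk(node):
        if node is not tree.root and not node.is_leaf:
            clade = frozenset(l.name for l in node.leaves())
            side = clade if anchor not in clade else all_leaves - clade
            if side in tree.supports:
                node.support = tree.supports[side]
        for c in node.children:
            walk(c)

    walk(tree.root)
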