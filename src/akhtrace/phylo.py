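"""Distance-based phylogenetics: p-distance, neighbor joining, bootstrap.

Implements the Saitou–Nei neighbor-joining algorithm on uncorrected
protein p-distances, with nonparametric bootstrap over alignment
columns.  Supports are reported as percentages in [0, 100] attached to
the internal edges of the full-data tree, and trees serialize to Newick
with supports as internal-node labels.

Conventions: ties in the Q-criterion break toward the lowest taxon-index
pair; negative branch lengths are clamped to zero (the raw value is kept
on the node for inspection); the unrooted tree is represented with a
basal trifurcation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genes import read_alignment_fasta  # shared aligned-FASTA reader

GAPLIKE = set("-.X*")


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise PhyloError("duplicate taxon labels")
        if self.d.shape != (n, n):
            raise PhyloError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise PhyloError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("nonzero diagonal")
        if np.any(self.d < 0):
            raise PhyloError("negative distances")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.d):
                fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def p_distance(rows: Mapping[str, str]) -> DistanceMatrix:
    """Uncorrected pairwise p-distance with pairwise deletion.

    Columns where either sequence has a gap, ``X`` or ``*`` are excluded
    per pair; a pair with zero comparable sites is an error.
    """
    taxa = tuple(rows)
    if len(taxa) < 2:
        raise PhyloError("need at least 2 taxa")
    seqs = [rows[t] for t in taxa]
    if len({len(s) for s in seqs}) > 1:
        raise PhyloError("rows of unequal length")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            comparable = mismatch = 0
            for x, y in zip(a, b):
                if x in GAPLIKE or y in GAPLIKE:
                    continue
                comparable += 1
                if x != y:
                    mismatch += 1
            if comparable == 0:
                raise PhyloError(
                    f"no comparable sites between {taxa[i]!r} and {taxa[j]!r}"
                )
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(taxa, d)


@dataclass
class Node:
    """Tree node; ``children`` pair subnodes with branch lengths."""

    name: str = ""
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal edges only
    raw_length: float | None = None  # pre-clamp NJ length of the edge above

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [l for c, _ in self.children for l in c.leaves()]


@dataclass
class TreeResult:
    root: Node  # basal trifurcation for >=3 taxa
    taxa: tuple[str, ...]

    def newick(self, decimals: int = 6) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if node.is_leaf:
                inner = node.name
            else:
                label = "" if node.support is None else f"{node.support:g}"
                inner = (
                    "(" + ",".join(fmt(c, l) for c, l in node.children) + ")" + label
                )
            if length is None:
                return inner
            return f"{inner}:{length:.{decimals}f}"

        return fmt(self.root, None) + ";"

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each as the leaf side not holding taxa[0]."""
        all_taxa = frozenset(self.taxa)
        anchor = self.taxa[0]
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self.root and 1 < len(below) < len(all_taxa) - 1:
                out.add(below if anchor not in below else all_taxa - below)
            return below

        walk(self.root)
        return out

    def n_edges(self) -> int:
        def count(node: Node) -> int:
            return sum(1 + count(c) for c, _ in node.children)

        return count(self.root)

    def edge_supports(self) -> dict[frozenset[str], float | None]:
        all_taxa = frozenset(self.taxa)
        anchor = self.taxa[0]
        out: dict[frozenset[str], float | None] = {}

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self.root and 1 < len(below) < len(all_taxa) - 1:
                key = below if anchor not in below else all_taxa - below
                out[key] = node.support
            return below

        walk(self.root)
        return out


def _clamp(node: Node, raw: float) -> tuple[Node, float]:
    node.raw_length = raw
    return node, max(raw, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeResult:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Repeatedly joins the pair minimizing
    ``Q(i,j) = (m-2) d(i,j) - r_i - r_j``; on ties the pair with the
    lowest (insertion-order) indices wins.  Branch lengths follow the
    standard NJ formulas and are clamped at zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]
    D = [list(map(float, row)) for row in dm.d]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i][j] - li
        u = Node(children=[_clamp(nodes[i], li), _clamp(nodes[j], lj)])
        new = len(nodes)
        nodes.append(u)
        for row in D:
            row.append(0.0)
        D.append([0.0] * (new + 1))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - D[i][j])
            D[new][k] = D[k][new] = duk
        active = [k for k in active if k not in (i, j)] + [new]

    a, b, c = active
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    root = Node(
        children=[_clamp(nodes[a], la), _clamp(nodes[b], lb), _clamp(nodes[c], lc)]
    )
    return TreeResult(root, dm.taxa)


def nj_tree(rows: Mapping[str, str]) -> TreeResult:
    return neighbor_joining(p_distance(rows))


def bootstrap(
    rows: Mapping[str, str], n_reps: int = 100, seed: int = 0
) -> TreeResult:
    """NJ tree with bootstrap supports over resampled alignment columns.

    Support of an internal edge = percentage of replicate trees whose NJ
    tree contains the same bipartition.  Reproducible under a fixed seed.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    dm = p_distance(rows)
    if np.all(dm.d == 0):
        warnings.warn(
            "all pairwise distances are zero; tree is star-like and supports "
            "are not meaningful",
            stacklevel=2,
        )
    tree = neighbor_joining(dm)
    taxa = list(rows)
    mat = np.array([list(rows[t]) for t in taxa])
    ncol = mat.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in tree.splits()}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = {t: "".join(mat[i, cols]) for i, t in enumerate(taxa)}
        try:
            rep_splits = nj_tree(rep_rows).splits()
        except PhyloError:  # zero comparable sites in a resample
            continue
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}

    all_taxa = frozenset(taxa)
    anchor = tree.taxa[0]

    def annotate(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c, _ in node.children))
        if node is not tree.root and 1 < len(below) < len(all_taxa) - 1:
            key = below if anchor not in below else all_taxa - below
            node.support = supports.get(key)
        return below

    annotate(tree.root)
    return tree


def nj_from_fasta(path: str | Path) -> TreeResult:
    return nj_tree(read_alignment_fasta(path))
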