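"""Poisson-corrected protein distances, neighbor joining and clade calling.

Distances follow the Poisson correction d = -ln(1 - p) with p the proportion
of differing sites among columns gap-free in *both* sequences of a pair
(pairwise deletion) and uniform rates across sites. Trees are built with the
Studier-Keppler neighbor-joining algorithm; bootstrap support is the
percentage of column-resampled replicate trees containing each original
internal bipartition. A *clade* is a maximal supported subtree holding at
least two distinct ortholog groups; groups never co-occurring in any
supported multi-group subtree are *orphans*.

Trees are returned as :class:`skbio.TreeNode` (unrooted, stored with a
trifurcating root); bootstrap percentages are written on internal node names
so they round-trip through Newick.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "Alignment",
    "CladePartition",
    "poisson_distance",
    "nj_tree",
    "bootstrap_support",
    "tree_splits",
    "extract_clades",
]

logger = logging.getLogger(__name__)

_GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """A protein multiple alignment: ordered taxa with equal-length rows."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len(self.taxa) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(taxa), tuple(rows))

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.length, size=self.length)
        rows = tuple("".join(row[c] for c in cols) for row in self.rows)
        return Alignment(self.taxa, rows)


@dataclass(frozen=True)
class CladePartition:
    clades: tuple[frozenset[str], ...]
    orphans: frozenset[str]


def poisson_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise Poisson distances under pairwise deletion of gap columns."""
    n = len(alignment.taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment.rows[i], alignment.rows[j]
            compared = diffs = 0
            for x, y in zip(a, b):
                if x == _GAP or y == _GAP:
                    continue
                compared += 1
                if x != y:
                    diffs += 1
            if compared == 0:
                raise ValueError(
                    f"no shared gap-free columns for pair "
                    f"({alignment.taxa[i]}, {alignment.taxa[j]})"
                )
            p = diffs / compared
            if p >= 1.0:
                raise ValueError(
                    f"saturated pair ({alignment.taxa[i]}, {alignment.taxa[j]}): "
                    "all compared sites differ"
                )
            mat[i, j] = mat[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(mat, ids=alignment.taxa)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Studier-Keppler neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) label pair. Negative branch lengths are clamped to zero and the
    clamped deficit logged. Requires >= 3 taxa and a symmetric matrix (which
    ``DistanceMatrix`` enforces).
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {i: {j: dm[i, j] for j in ids if j != i} for i in ids}
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    active = list(ids)
    counter = 0

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %.6g at %s", x, where)
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * d[i][j] - r[i] - r[j]
                key = (q, tuple(sorted((i, j))))
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        i, j = best_pair
        dij = d[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        li, lj = clamp(li, f"{i}"), clamp(lj, f"{j}")
        new_id = f"__internal_{counter}"
        counter += 1
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        nodes[new_id] = parent
        d[new_id] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i][k] + d[j][k] - dij)
            d[new_id][k] = d[k][new_id] = dk
        active = [k for k in active if k not in (i, j)] + [new_id]

    # join the last three nodes at an unrooted (trifurcating) root
    a, b, c = active
    la = clamp(0.5 * (d[a][b] + d[a][c] - d[b][c]), a)
    lb = clamp(0.5 * (d[a][b] + d[b][c] - d[a][c]), b)
    lc = clamp(0.5 * (d[a][c] + d[b][c] - d[a][b]), c)
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, in canonical form.

    Each internal edge splits the taxa in two; the side not containing the
    lexicographically smallest taxon is the canonical representative.
    """
    taxa = frozenset(t.name for t in tree.tips())
    ref = min(taxa)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if ref in side:
            side = taxa - side
        splits.add(side)
    return splits


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TreeNode:
    """NJ tree with bootstrap percentages on internal nodes.

    Columns are resampled with replacement per replicate; support for each
    original internal bipartition is the percentage of replicate trees that
    contain it. Replicates producing a saturated or incomparable pair are
    skipped and logged. Reproducible given the seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    tree = nj_tree(poisson_distance(alignment))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(tree)}
    used = 0
    for _ in range(replicates):
        rep = alignment.resample_columns(rng)
        try:
            rep_splits = tree_splits(nj_tree(poisson_distance(rep)))
        except ValueError as exc:
            logger.info("bootstrap replicate skipped: %s", exc)
            continue
        used += 1
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    if used == 0:
        raise ValueError("every bootstrap replicate failed")
    taxa = frozenset(alignment.taxa)
    ref = min(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        canon = taxa - side if ref in side else side
        node.name = str(round(100.0 * counts[canon] / used))
    return tree


def extract_clades(
    tree: TreeNode,
    group_map: Mapping[str, str],
    min_support: float = 50.0,
) -> CladePartition:
    """Partition ortholog groups into supported clades and orphan groups.

    Every taxon must appear in ``group_map`` (taxon -> ortholog group).
    Maximal subtrees with bootstrap support >= ``min_support`` containing at
    least two distinct groups become clades; groups outside every such
    subtree are orphans. Clades are reported in tree traversal order.
    """
    tips = [t.name for t in tree.tips()]
    unmapped = [t for t in tips if t not in group_map]
    if unmapped:
        raise KeyError(f"taxa missing from group map: {unmapped}")
    taxa = frozenset(tips)
    ref = min(taxa)
    all_groups = frozenset(group_map[t] for t in tips)

    def parse_support(node: TreeNode) -> float | None:
        if node.name is None:
            return None
        try:
            return float(node.name)
        except ValueError:
            return None

    # support per canonical split, read off the (unrooted) input tree
    split_support: dict[frozenset[str], float] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        sup = parse_support(node)
        if sup is not None:
            split_support[taxa - side if ref in side else side] = sup

    # walk a midpoint-rooted copy so a family straddling the stored
    # trifurcation still forms a rooted subtree
    rooted = tree.copy()
    try:
        rooted = rooted.root_at_midpoint()
    except Exception:  # zero-length or degenerate trees: keep original rooting
        pass

    def subtree_support(side: frozenset[str]) -> float | None:
        if len(side) < 2 or len(taxa - side) < 2:
            return None
        return split_support.get(taxa - side if ref in side else side)

    clades: list[frozenset[str]] = []

    def walk(node: TreeNode) -> None:
        for child in node.children:
            if child.is_tip():
                continue
            side = frozenset(t.name for t in child.tips())
            sup = subtree_support(side)
            groups = frozenset(group_map[t] for t in side)
            if sup is not None and sup >= min_support and len(groups) >= 2:
                clades.append(groups)
            else:
                walk(child)

    walk(rooted)
    covered = frozenset().union(*clades) if clades else frozenset()
    orphans = all_groups - covered
    return CladePartition(tuple(clades), orphans)
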