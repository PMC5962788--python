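"""Distance-based phylogenetics: K2P/p distances, neighbor joining,
bootstrap supports, conserved-block trimming, and alignment concatenation.

The neighbor-joining implementation follows Saitou & Nei's agglomeration
with the rate-corrected selection criterion, a deterministic tie-break
(lexicographically smallest taxon pair, by the smallest leaf name in each
cluster), and clamping of negative intermediate branch lengths to zero
with the deficit transferred to the sibling edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .seq_io import GAP, Alignment, SequenceRecord


class SaturationError(ValueError):
    """Distance undefined: observed divergence beyond model saturation."""


# ---------------------------------------------------------------------------
# distances

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_SKIP = {GAP, "N"}


def _paired_sites(a: str, b: str) -> Iterable[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    for x, y in zip(a, b):
        if x in _SKIP or y in _SKIP:
            continue
        yield x, y


def k2p_distance(seq_a: SequenceRecord | str, seq_b: SequenceRecord | str) -> float:
    """Kimura two-parameter nucleotide distance with pairwise deletion.

    P is the transition fraction, Q the transversion fraction over the
    sites comparable in both sequences (no gap, no N);
    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).
    """
    a = seq_a.residues if isinstance(seq_a, SequenceRecord) else seq_a
    b = seq_b.residues if isinstance(seq_b, SequenceRecord) else seq_b
    n = ts = tv = 0
    for x, y in _paired_sites(a.upper(), b.upper()):
        n += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturation: P={P:.4f}, Q={Q:.4f} leave no information"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(seq_a: SequenceRecord | str, seq_b: SequenceRecord | str) -> float:
    """Proportion of differing comparable sites (pairwise deletion)."""
    a = seq_a.residues if isinstance(seq_a, SequenceRecord) else seq_a
    b = seq_b.residues if isinstance(seq_b, SequenceRecord) else seq_b
    n = diff = 0
    for x, y in _paired_sites(a.upper(), b.upper()):
        n += 1
        if x != y:
            diff += 1
    if n == 0:
        raise ValueError("no comparable sites")
    return diff / n


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")

    @classmethod
    def from_alignment(
        cls, alignment: Alignment, distance_fn: Callable[[str, str], float]
    ) -> "DistanceMatrix":
        taxa = alignment.taxa
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = distance_fn(
                    alignment.row(taxa[i]), alignment.row(taxa[j])
                )
        return cls(taxa, d)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


# ---------------------------------------------------------------------------
# trees

class TreeNode:
    """Minimal rooted-representation tree node; an unrooted tree is a root
    with three children."""

    __slots__ = ("label", "children", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        children: Optional[list[tuple["TreeNode", float]]] = None,
        support: Optional[float] = None,
    ):
        self.label = label
        self.children = children or []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


class PhyloTree:
    """Branch-lengthed tree with optional per-internal-edge supports."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = root.leaves()
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def newick(self, support_as_label: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label  # type: ignore[return-value]
            inner = ",".join(
                f"{render(child)}:{bl:.6g}" for child, bl in node.children
            )
            lab = ""
            if support_as_label and node.support is not None:
                lab = f"{node.support:g}"
            return f"({inner}){lab}"

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(nd) -> TreeNode:
            if nd.is_leaf():
                return TreeNode(label=nd.taxon.label.replace(" ", "_"))
            node = TreeNode()
            if nd.label is not None:
                try:
                    node.support = float(nd.label)
                except ValueError:
                    pass
            for ch in nd.child_nodes():
                node.children.append(
                    (convert(ch), ch.edge.length if ch.edge.length else 0.0)
                )
            return node

        return cls(convert(tree.seed_node))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, canonicalized as the side NOT containing the
        lexicographically smallest leaf."""
        all_leaves = set(self.leaf_names)
        anchor = min(all_leaves)
        n = len(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.label}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= n - 2:
                    canon = all_leaves - side if anchor in side else side
                    splits.add(frozenset(canon))
                below |= side
            return below

        walk(self.root)
        return splits

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic leaf-to-leaf path lengths."""
        taxa = sorted(self.leaf_names)
        idx = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}  # type: ignore[dict-item]
            below: dict[str, float] = {}
            per_child = []
            for child, bl in node.children:
                dists = {t: x + bl for t, x in walk(child).items()}
                per_child.append(dists)
            for i in range(len(per_child)):
                for j in range(i + 1, len(per_child)):
                    for ta, da in per_child[i].items():
                        for tb, db in per_child[j].items():
                            d[idx[ta], idx[tb]] = d[idx[tb], idx[ta]] = da + db
                below = {t: x for dd in per_child for t, x in dd.items()}
            return below

        walk(self.root)
        return DistanceMatrix(taxa, d)


def nj_build(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining over a distance matrix (>= 3 taxa).

    Deterministic: ties in the joining criterion resolve to the pair whose
    (smallest-leaf-name, smallest-leaf-name) labels sort lexicographically
    first.  Negative intermediate branch lengths are clamped to zero and
    the deficit moved to the sibling edge.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=t) for t in dm.taxa]
    canon: list[str] = list(dm.taxa)  # smallest leaf name per cluster
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - R[i] - R[j]
                pair_key = tuple(sorted((canon[i], canon[j])))
                key = (q, pair_key)
                if best is None or key < best[0]:
                    best = (key, (i, j))
        (_, _), (i, j) = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        k = len(nodes)
        nodes.append(parent)
        canon.append(min(canon[i], canon[j]))
        newrow = np.zeros(len(nodes))
        d = np.pad(d, ((0, 1), (0, 1)))
        for u in active:
            if u in (i, j):
                continue
            d[k, u] = d[u, k] = 0.5 * (d[i, u] + d[j, u] - d[i, j])
        active = [u for u in active if u not in (i, j)] + [k]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    order = sorted([(canon[a], a, la), (canon[b], b, lb), (canon[c], c, lc)])
    root = TreeNode(
        children=[(nodes[u], max(l, 0.0)) for _, u, l in order]
    )
    return PhyloTree(root)


def bootstrap_support(
    alignment: Alignment,
    B: int = 1000,
    distance_fn: Callable[[str, str], float] = p_distance,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from the full alignment with column-bootstrap supports.

    Supports are mapped onto the full-data tree: each internal edge gets
    the percentage of replicate trees containing the same bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    full = nj_build(DistanceMatrix.from_alignment(alignment, distance_fn))
    counts: dict[frozenset[str], int] = {s: 0 for s in full.bipartitions()}
    rng = np.random.default_rng(seed)
    L = alignment.length
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep = alignment.take_columns([int(c) for c in cols])
        try:
            rep_tree = nj_build(DistanceMatrix.from_alignment(rep, distance_fn))
        except (SaturationError, ValueError):
            continue
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    all_leaves = set(full.leaf_names)
    anchor = min(all_leaves)
    n = len(all_leaves)

    def annotate(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.label}  # type: ignore[arg-type]
        below: set[str] = set()
        for child, _ in node.children:
            side = annotate(child)
            if 2 <= len(side) <= n - 2:
                canon = all_leaves - side if anchor in side else side
                child.support = 100.0 * counts.get(frozenset(canon), 0) / B
            below |= side
        return below

    annotate(full.root)
    return full


# ---------------------------------------------------------------------------
# trimming and concatenation

@dataclass(frozen=True)
class TrimParams:
    """Conserved-block trimming thresholds (Gblocks-style; n = rows).

    b1: minimum identical rows for a conserved position (default n/2 + 1);
    b2: minimum for a highly conserved position (default ceil(0.85 n));
    b3: longest tolerated run of non-conserved positions;
    b4: minimum surviving block length;
    b5: gap policy ("none": any gap disqualifies the column).
    """

    b1: Optional[int] = None
    b2: Optional[int] = None
    b3: int = 8
    b4: int = 10
    b5: str = "none"

    def resolved(self, n_rows: int) -> tuple[int, int, int, int]:
        b1 = self.b1 if self.b1 is not None else n_rows // 2 + 1
        b2 = self.b2 if self.b2 is not None else math.ceil(0.85 * n_rows)
        if not b1 <= b2 <= n_rows:
            raise ValueError(f"need b1 <= b2 <= n_rows, got {b1}, {b2}, {n_rows}")
        if self.b3 < 0 or self.b4 < 1:
            raise ValueError("b3 >= 0 and b4 >= 1 required")
        if self.b5 != "none":
            raise ValueError("only gap policy 'none' is implemented")
        return b1, b2, self.b3, self.b4


class EmptyTrimError(ValueError):
    """Trimming removed every column."""


def trim_conserved_blocks(
    alignment: Alignment, params: TrimParams = TrimParams()
) -> Alignment:
    """Keep only conserved blocks, Gblocks-fashion.

    Columns with any gap are rejected outright (b5 = none); remaining
    columns are conserved when the majority residue reaches b1 rows and
    highly conserved at b2.  Runs of more than b3 consecutive
    non-conserved positions are rejected; candidate blocks are trimmed at
    both ends to highly conserved positions and dropped when shorter
    than b4.  Idempotent; never lengthens the alignment.
    """
    n_rows = alignment.n_rows
    b1, b2, b3, b4 = params.resolved(n_rows)
    L = alignment.length
    # status: 'g' rejected gap column, 'n' non-conserved, 'c' conserved, 'h' high
    status: list[str] = []
    for c in range(L):
        col = alignment.column(c)
        if GAP in col:
            status.append("g")
            continue
        top = max(col.count(ch) for ch in set(col))
        if top >= b2:
            status.append("h")
        elif top >= b1:
            status.append("c")
        else:
            status.append("n")

    rejected = [s == "g" for s in status]
    # reject runs of > b3 consecutive non-conserved positions (gap columns
    # break runs since they are already gone)
    c = 0
    while c < L:
        if status[c] == "n" and not rejected[c]:
            s = c
            while c < L and status[c] == "n" and not rejected[c]:
                c += 1
            if c - s > b3:
                for k in range(s, c):
                    rejected[k] = True
        else:
            c += 1
    # candidate blocks = maximal runs of surviving columns
    keep: list[int] = []
    c = 0
    while c < L:
        if rejected[c]:
            c += 1
            continue
        s = c
        while c < L and not rejected[c]:
            c += 1
        block = list(range(s, c))
        # trim ends to highly conserved flanks
        while block and status[block[0]] != "h":
            block.pop(0)
        while block and status[block[-1]] != "h":
            block.pop()
        if len(block) >= b4:
            keep.extend(block)
    if not keep:
        counts = {s: status.count(s) for s in "gnch"}
        raise EmptyTrimError(
            "trimming removed every column "
            f"(gap={counts['g']}, non-conserved={counts['n']}, "
            f"conserved={counts['c']}, high={counts['h']}, b4={b4})"
        )
    return alignment.take_columns(keep)


def concatenate_alignments(
    alignments: Sequence[Alignment], policy: str = "strict"
) -> Alignment:
    """Row-wise concatenation of per-gene alignments into a supermatrix.

    policy "strict" errors on a taxon missing from any partition;
    "gap-fill" pads missing partitions with gaps.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if policy not in ("strict", "gap-fill"):
        raise ValueError(f"unknown policy {policy!r}")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    for p, aln in enumerate(alignments):
        for t in taxa:
            if t in aln:
                parts[t].append(aln.row(t))
            elif policy == "strict":
                raise ValueError(f"taxon {t!r} missing from partition {p + 1}")
            else:
                parts[t].append(GAP * aln.length)
    return Alignment((t, "".join(parts[t])) for t in taxa)
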