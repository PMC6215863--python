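"""Distance phylogenies and incongruence machinery for per-gene trees.

Trees for the three operon genes are built the classical way: pairwise
Poisson-corrected amino-acid distances d = −ln(1 − p) (p = proportion of
differing sites under pairwise gap deletion) followed by Saitou–Nei
neighbor joining.  Lateral transfer of a single gene out of the operon
shows up as *incongruence* between the per-gene trees, quantified by the
Robinson–Foulds distance (symmetric difference of non-trivial splits), and
lineage-rate acceleration shows up as a root-to-tip path-length contrast
between a focal clade and the background, with the tree rooted on a
user-named outgroup.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}

SATURATION_P = 0.95  # pairs at or beyond this proportion of differences error out


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A fixed set of equal-length amino-acid rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in number")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


def read_alignment_fasta(path) -> Alignment:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not names:
        raise ValueError(f"no sequences in {path}")
    return Alignment(names=names, rows=rows)


def write_alignment_fasta(aln: Alignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def concat_alignment(parts: Sequence[Alignment], min_len: int = 910) -> Alignment:
    """Concatenate gene alignments over their shared taxa.

    Taxa missing from any part are excluded; taxa whose concatenated rows
    have fewer than ``min_len`` non-gap residues are dropped (logged).
    """
    if not parts:
        raise ValueError("no alignments to concatenate")
    shared = set(parts[0].names)
    for part in parts[1:]:
        shared &= set(part.names)
    if not shared:
        raise ValueError("no taxa shared by all alignments")
    names = [n for n in parts[0].names if n in shared]
    rows = ["".join(part.row(n) for part in parts) for n in names]
    keep_names, keep_rows = [], []
    for n, r in zip(names, rows):
        nongap = sum(1 for ch in r if ch not in GAP_CHARS)
        if nongap < min_len:
            logger.info(
                "concat_alignment: dropping %s (%d non-gap residues < %d)",
                n, nongap, min_len,
            )
            continue
        keep_names.append(n)
        keep_rows.append(r)
    return Alignment(names=keep_names, rows=keep_rows)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    names: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")


def poisson_distance(aln: Alignment) -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = −ln(1 − p).

    p is the proportion of differing sites among columns where both rows
    are non-gap (pairwise gap deletion).  Pairs with no overlap, or with
    p ≥ 0.95 (effectively saturated), raise with the offending pair named.
    """
    n = len(aln.names)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(r) for r in aln.rows])
    nongap = ~np.isin(arr, list(GAP_CHARS))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"zero-overlap pair ({aln.names[i]}, {aln.names[j]})"
                )
            p = float(np.sum(arr[i][both] != arr[j][both])) / m
            if p >= SATURATION_P:
                raise ValueError(
                    f"saturated pair ({aln.names[i]}, {aln.names[j]}): p = {p:.3f}"
                )
            d[i, j] = d[j, i] = -np.log1p(-p)
    return DistanceMatrix(names=list(aln.names), d=d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch above this node
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """A tree with branch lengths, treated as unrooted for comparisons.

    Stored with an (arbitrary) root; NJ output roots at the final degree-3
    join.  Serializes to and from newick.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- construction / serialization --

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        s = text.strip()
        if not s.endswith(";"):
            raise ValueError("newick string must end with ';'")
        s = s[:-1]
        pos = 0

        def parse_node() -> Node:
            nonlocal pos
            node = Node()
            if s[pos] == "(":
                pos += 1
                node.children.append(parse_node())
                while s[pos] == ",":
                    pos += 1
                    node.children.append(parse_node())
                if s[pos] != ")":
                    raise ValueError(f"unbalanced parentheses at {pos}")
                pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos]
            if label:
                node.name = label
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                node.length = float(s[start:pos])
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in newick at {pos}")
        return cls(root)

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                core = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if not top and lengths:
                core += f":{node.length:.10g}"
            return core

        return fmt(self.root, True) + ";"

    def copy(self) -> "GeneTree":
        return GeneTree(copy.deepcopy(self.root))

    # -- traversal --

    def postorder(self) -> Iterable[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- unrooted splits --

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        below: dict[int, frozenset[str]] = {}
        result: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is self.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                result.add(side)
        return result

    def find_clade(self, leaf_set: Iterable[str]) -> Node:
        """The node whose descendant leaf set equals ``leaf_set`` exactly."""
        target = frozenset(leaf_set)
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            below[id(node)] = (
                frozenset([node.name])
                if node.is_leaf
                else frozenset().union(*(below[id(c)] for c in node.children))
            )
            if below[id(node)] == target:
                return node
        raise KeyError(f"no clade with leaves {sorted(target)}")

    # -- pruning --

    def prune_to(self, keep: Iterable[str]) -> "GeneTree":
        """A copy restricted to ``keep`` leaves, unary nodes suppressed
        (branch lengths summed)."""
        keep_set = set(keep)

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                return copy.deepcopy(node) if node.name in keep_set else None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            new = Node(name=node.name, length=node.length, children=kids)
            return new

        root = rec(self.root)
        if root is None:
            raise ValueError("pruning removed every leaf")
        if len(root.children) == 1:
            root = root.children[0]
            root.length = 0.0
        return GeneTree(root)

    # -- distances on the tree --

    def adjacency(self) -> dict[int, list[tuple["Node", float]]]:
        adj: dict[int, list[tuple[Node, float]]] = {}
        nodes = list(self.postorder())
        for node in nodes:
            adj.setdefault(id(node), [])
            for c in node.children:
                adj[id(node)].append((c, c.length))
                adj.setdefault(id(c), []).append((node, c.length))
        return adj

    def depths_from(self, start: Node) -> dict[str, float]:
        """Path lengths from ``start`` to every leaf."""
        adj = self.adjacency()
        dist: dict[int, float] = {id(start): 0.0}
        out: dict[str, float] = {}
        stack = [start]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out[node.name] = dist[id(node)]
            for nbr, w in adj[id(node)]:
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(node)] + w
                    stack.append(nbr)
        return out


def tree_path_distances(tree: GeneTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (additive) matrix of a tree."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    n = len(names)
    d = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        depths = tree.depths_from(leaf)
        for j, other in enumerate(names):
            d[i, j] = depths[other]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(names=names, d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> GeneTree:
    """Saitou–Nei neighbor joining on the Q-criterion.

    Deterministic: ties on Q break to the lowest (i, j) index pair; negative
    branch-length estimates are clamped to zero with the deficit logged.
    The returned tree is unrooted (degree-3 root from the final join).
    """
    n = len(dm.names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    nodes: dict[int, Node] = {i: Node(name=dm.names[i]) for i in range(n)}
    active = list(range(n))
    nxt = n

    def clamp(val: float, label: str) -> float:
        if val < 0:
            logger.debug("nj_tree: clamping negative branch %.3g at %s", val, label)
            return 0.0
        return val

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(idx)
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major argmin == lowest (i, j) tie-break
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = idx[ai], idx[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        u = Node(
            children=[
                _with_length(nodes[i], clamp(li, nodes[i].name or "internal")),
                _with_length(nodes[j], clamp(lj, nodes[j].name or "internal")),
            ]
        )
        for k in active:
            if k in (i, j):
                continue
            D[nxt, k] = D[k, nxt] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[nxt] = u
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node(
        children=[
            _with_length(nodes[a], clamp(la, "terminal")),
            _with_length(nodes[b], clamp(lb, "terminal")),
            _with_length(nodes[c], clamp(lc, "terminal")),
        ]
    )
    return GeneTree(root)


def _with_length(node: Node, length: float) -> Node:
    node.length = length
    return node


# ---------------------------------------------------------------------------
# Incongruence (Robinson–Foulds)
# ---------------------------------------------------------------------------


@dataclass
class IncongruenceReport:
    pair: tuple[str, str]
    n_shared: int
    rf: int
    rf_normalized: float
    discordant_splits: list[tuple[str, ...]]


def rf_distance(
    t1: GeneTree, t2: GeneTree, labels: tuple[str, str] = ("tree1", "tree2")
) -> IncongruenceReport:
    """Robinson–Foulds distance after pruning to the shared leaf set.

    rf is the size of the symmetric difference of non-trivial splits,
    normalized by 2(n−3), its maximum for binary trees on n leaves.
    """
    shared = set(t1.leaf_names) & set(t2.leaf_names)
    n = len(shared)
    if n < 4:
        raise ValueError(f"only {n} shared leaves; need >= 4 for internal splits")
    s1 = t1.prune_to(shared).splits()
    s2 = t2.prune_to(shared).splits()
    diff = s1 ^ s2
    rf = len(diff)
    return IncongruenceReport(
        pair=labels,
        n_shared=n,
        rf=rf,
        rf_normalized=rf / (2 * (n - 3)),
        discordant_splits=sorted(tuple(sorted(s)) for s in diff),
    )


# ---------------------------------------------------------------------------
# Lineage rate acceleration
# ---------------------------------------------------------------------------


@dataclass
class RateReport:
    focal_clade: frozenset[str]
    outgroup: frozenset[str]
    rate_ratio: float
    focal_mean_depth: float
    background_mean_depth: float


def _outgroup_attachment(tree: GeneTree, outgroup: frozenset[str]) -> Node:
    """The ingroup-side node of the edge separating the outgroup.

    If no edge splits the outgroup off exactly (e.g. estimation noise made
    it non-monophyletic), falls back to the edge whose leaf side has
    maximal Jaccard similarity to the outgroup, with a warning.
    """
    all_leaves = frozenset(tree.leaf_names)
    below: dict[int, frozenset[str]] = {}
    parent: dict[int, Node] = {}
    for node in tree.postorder():
        below[id(node)] = (
            frozenset([node.name])
            if node.is_leaf
            else frozenset().union(*(below[id(c)] for c in node.children))
        )
        for c in node.children:
            parent[id(c)] = node

    def ingroup_side(node: Node) -> Node:
        # the edge above `node` separates the outgroup below it; the
        # attachment is its parent — unless that parent is a degree-2 root
        # (absent from the unrooted tree), in which case it is the sibling.
        par = parent[id(node)]
        if par is tree.root and len(tree.root.children) == 2:
            sib = [c for c in tree.root.children if c is not node][0]
            return sib
        return par

    best, best_score = None, -1.0
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = below[id(node)]
        if side == outgroup:
            return ingroup_side(node)
        if all_leaves - side == outgroup:
            return node
        jac = len(side & outgroup) / len(side | outgroup)
        if jac > best_score:
            best, best_score = node, jac
    logger.warning(
        "outgroup %s not monophyletic in tree; rooting at closest edge "
        "(Jaccard %.2f)", sorted(outgroup), best_score,
    )
    return ingroup_side(best)


def rate_ratio(
    tree: GeneTree, focal: Iterable[str], outgroup: Iterable[str]
) -> RateReport:
    """Root-to-tip path-length contrast of a focal clade vs the background.

    The tree is rooted at the node where the outgroup attaches to the
    ingroup; the ratio is the mean root-to-tip path over focal leaves
    divided by the mean over the remaining (non-focal, non-outgroup)
    leaves.  A clock-like tree gives a ratio near 1; a lineage whose
    branches were scaled by m gives a ratio near m.
    """
    focal = frozenset(focal)
    outgroup = frozenset(outgroup)
    leaves = frozenset(tree.leaf_names)
    background = leaves - focal - outgroup
    if not focal or not focal <= leaves:
        raise ValueError("focal clade empty or not a subset of the leaves")
    if not background:
        raise ValueError("no background leaves left outside focal + outgroup")
    attach = _outgroup_attachment(tree, outgroup)
    depths = tree.depths_from(attach)
    f = float(np.mean([depths[x] for x in sorted(focal)]))
    b = float(np.mean([depths[x] for x in sorted(background)]))
    if b <= 0:
        raise ValueError("background mean root-to-tip depth is zero")
    return RateReport(
        focal_clade=focal,
        outgroup=outgroup,
        rate_ratio=f / b,
        focal_mean_depth=f,
        background_mean_depth=b,
    )
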