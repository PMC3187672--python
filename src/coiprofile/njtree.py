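"""Neighbor-joining tree construction and unrooted-tree topology queries.

The tree is used strictly as a similarity profile: no bootstrap, no
outgroup rooting.  NJ is the standard Saitou-Nei agglomeration with a
deterministic tie-break (lexicographically smallest cluster-label pair) and
negative-limb clamping (deficit transferred to the sister limb, logged).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix


class TreeError(ValueError):
    pass


@dataclass(eq=False)
class Node:
    label: str | None = None
    #: neighbor -> branch length (undirected adjacency; lengths mirrored)
    neighbors: dict["Node", float] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return len(self.neighbors) == 1

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, deg={len(self.neighbors)})"


class UnrootedTree:
    """Unrooted tree with labeled leaves and non-negative branch lengths."""

    def __init__(self, nodes: list[Node]):
        self.nodes = nodes
        self.leaf_nodes = {n.label: n for n in nodes if n.is_leaf}
        if len(self.leaf_nodes) != sum(1 for n in nodes if n.is_leaf):
            raise TreeError("duplicate leaf labels")
        #: (length_before_clamp, edge description) entries, filled by NJ
        self.clamp_log: list[str] = []

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.leaf_nodes)

    def edges(self) -> list[tuple[Node, Node, float]]:
        seen: set[frozenset[int]] = set()
        out = []
        for node in self.nodes:
            for other, length in node.neighbors.items():
                key = frozenset((id(node), id(other)))
                if key not in seen:
                    seen.add(key)
                    out.append((node, other, length))
        return out

    def _side_leaves(self, start: Node, away_from: Node) -> frozenset[str]:
        """Leaf labels on ``start``'s side of the edge (start, away_from)."""
        stack = [(start, away_from)]
        leaves = []
        while stack:
            node, parent = stack.pop()
            if node.is_leaf and node.label is not None:
                leaves.append(node.label)
            for nb in node.neighbors:
                if nb is not parent:
                    stack.append((nb, node))
        return frozenset(leaves)

    def _canonical(self, side: frozenset[str]) -> frozenset[str]:
        ref = min(self.leaf_nodes)
        if ref in side:
            return frozenset(self.leaf_nodes) - side
        return side

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits, one per internal edge.

        Each split is represented canonically as the side NOT containing the
        lexicographically smallest leaf.
        """
        out: set[frozenset[str]] = set()
        for a, b, _ in self.edges():
            if a.is_leaf or b.is_leaf:
                continue
            out.add(self._canonical(self._side_leaves(a, b)))
        return out

    def edge_sides(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """(side_a, side_b, length) for every edge, trivial edges included."""
        out = []
        for a, b, length in self.edges():
            sa = self._side_leaves(a, b)
            out.append((sa, frozenset(self.leaf_nodes) - sa, length))
        return out

    def split_lengths(self) -> dict[frozenset[str], float]:
        """Canonical split -> branch length, for every edge (incl. leaf edges)."""
        return {
            self._canonical(sa): length for sa, _, length in self.edge_sides()
        }

    # ------------------------------------------------------------- newick

    def to_newick(self) -> str:
        """Serialize with branch lengths from an arbitrary internal root.

        Labels containing whitespace or Newick punctuation are quoted.
        """
        root = next(
            (n for n in self.nodes if not n.is_leaf),
            None,
        )
        if root is None:  # two-leaf tree
            a, b, length = self.edges()[0]
            return f"({_quote(a.label)}:{_fmt(length)},{_quote(b.label)}:0);"

        def render(node: Node, parent: Node | None) -> str:
            children = [nb for nb in node.neighbors if nb is not parent]
            if not children:
                return _quote(node.label)
            inner = ",".join(
                f"{render(c, node)}:{_fmt(node.neighbors[c])}"
                for c in sorted(
                    children, key=lambda c: min(self._side_leaves(c, node))
                )
            )
            return f"({inner})"

        return render(root, None) + ";"

    def ascii_art(self) -> str:
        """Minimal indented rendering for reports."""
        root = next((n for n in self.nodes if not n.is_leaf), self.nodes[0])
        lines: list[str] = []

        def walk(node: Node, parent: Node | None, depth: int, blen: float):
            name = node.label if node.is_leaf else "+"
            lines.append("  " * depth + f"{name} ({blen:.4f})")
            for nb in sorted(
                (c for c in node.neighbors if c is not parent),
                key=lambda c: min(self._side_leaves(c, node)),
            ):
                walk(nb, node, depth + 1, node.neighbors[nb])

        walk(root, None, 0, 0.0)
        return "\n".join(lines)


def _fmt(x: float) -> str:
    return repr(float(x))


_PLAIN_LABEL = re.compile(r"^[^\s(),:;'\[\]]+$")


def _quote(label: str | None) -> str:
    if label is None:
        return ""
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _link(a: Node, b: Node, length: float) -> None:
    a.neighbors[b] = length
    b.neighbors[a] = length


def neighbor_joining(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining on a fully defined distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster label, cluster label) pair, where a cluster's label is the
    smallest leaf id it contains.  Negative limb lengths are clamped to 0
    with the deficit moved to the sister limb; every clamp is logged on the
    returned tree.
    """
    n = len(dm)
    if n < 3:
        raise TreeError(f"neighbor joining needs >=3 taxa, got {n}")
    bad = dm.undefined_pairs()
    if bad:
        shown = ", ".join(f"({a!r},{b!r})" for a, b in bad[:5])
        raise TreeError(
            f"distance matrix has {len(bad)} undefined entr"
            f"{'y' if len(bad) == 1 else 'ies'}: {shown}"
        )

    D = dm.values.astype(float).copy()
    nodes = [Node(label=sid) for sid in dm.ids]
    labels = list(dm.ids)  # cluster label = min leaf id in cluster
    all_nodes = list(nodes)
    clamp_log: list[str] = []

    def clamp(li: float, lj: float, who_i: str, who_j: str) -> tuple[float, float]:
        if li < 0:
            clamp_log.append(
                f"clamped limb {who_i} from {li:.6g} to 0 (moved to {who_j})"
            )
            lj += li
            li = 0.0
        if lj < 0:
            clamp_log.append(
                f"clamped limb {who_j} from {lj:.6g} to 0 (moved to {who_i})"
            )
            li += lj
            lj = 0.0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        return li, lj

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (m - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        best_ij: tuple[int, int] | None = None
        for a, b in zip(*np.nonzero(np.isclose(q, qmin, rtol=0, atol=1e-12))):
            if a >= b:
                continue
            la, lb = labels[active[a]], labels[active[b]]
            key = (min(la, lb), max(la, lb))
            if best is None or key < best:
                best = key
                best_ij = (int(a), int(b))
        assert best_ij is not None
        a, b = best_ij
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (sums[a] - sums[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj, labels[i], labels[j])
        parent = Node()
        all_nodes.append(parent)
        _link(parent, nodes[i], li)
        _link(parent, nodes[j], lj)
        # distances from the new cluster to the remaining ones
        new_row = np.empty(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        idx = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[idx, k] = D[k, idx] = new_row[k]
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [idx]

    # final three clusters join at a central node (three-point formulas)
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    for length, lab in ((li, labels[i]), (lj, labels[j]), (lk, labels[k])):
        if length < 0:
            clamp_log.append(f"clamped final limb {lab} from {length:.6g} to 0")
    center = Node()
    all_nodes.append(center)
    _link(center, nodes[i], max(li, 0.0))
    _link(center, nodes[j], max(lj, 0.0))
    _link(center, nodes[k], max(lk, 0.0))

    tree = UnrootedTree(all_nodes)
    tree.clamp_log = clamp_log
    return tree


def to_newick(tree: UnrootedTree) -> str:
    return tree.to_newick()


def bipartitions(tree: UnrootedTree) -> set[frozenset[str]]:
    return tree.bipartitions()


# ------------------------------------------------------------ newick reader


_TOKEN = re.compile(r"\s*(\(|\)|,|;|:|'(?:[^']|'')*'|[^\s(),:;']+)")


def from_newick(text: str) -> UnrootedTree:
    """Parse a Newick string into an :class:`UnrootedTree`.

    The serialization root is dissolved: a degree-2 root node is contracted
    so the result is a proper unrooted tree.  Provided primarily for tests
    and report round-trips.
    """
    tokens = _TOKEN.findall(text)
    if not tokens or tokens[-1] != ";":
        raise TreeError("newick string must end with ';'")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    all_nodes: list[Node] = []

    def parse_clade() -> tuple[Node, float]:
        node = Node()
        all_nodes.append(node)
        if peek() == "(":
            take()
            while True:
                child, blen = parse_clade()
                _link(node, child, blen)
                tok = take()
                if tok == ")":
                    break
                if tok != ",":
                    raise TreeError(f"unexpected token {tok!r}")
            if peek() not in ("(", ")", ",", ":", ";", None):
                take()  # internal label, ignored
        else:
            raw = take()
            if raw.startswith("'"):
                raw = raw[1:-1].replace("''", "'")
            node.label = raw
        blen = 0.0
        if peek() == ":":
            take()
            blen = float(take())
        return node, blen

    root, _ = parse_clade()
    if take() != ";":
        raise TreeError("trailing content after ';'")

    # dissolve a degree-2 serialization root
    if len(root.neighbors) == 2:
        (a, la), (b, lb) = root.neighbors.items()
        del a.neighbors[root]
        del b.neighbors[root]
        _link(a, b, la + lb)
        all_nodes.remove(root)
    return UnrootedTree(all_nodes)


def enumerate_topologies(leaves: list[str]):
    """Yield every unrooted binary topology over ``leaves`` (n <= ~7).

    Each topology is an :class:`UnrootedTree` with unit branch lengths.
    Used by least-squares oracles in tests.
    """
    if len(leaves) < 3:
        raise TreeError("need >=3 leaves")

    first = [Node(label=leaves[0]), Node(label=leaves[1]), Node(label=leaves[2])]
    center = Node()
    for leaf in first:
        _link(center, leaf, 1.0)
    trees = [first + [center]]
    for name in leaves[3:]:
        new_trees = []
        for nodes in trees:
            tree = UnrootedTree(nodes)
            for a, b, _ in tree.edges():
                clone_map: dict[int, Node] = {}
                for node in nodes:
                    clone_map[id(node)] = Node(label=node.label)
                for node in nodes:
                    for nb, ln in node.neighbors.items():
                        clone_map[id(node)].neighbors[clone_map[id(nb)]] = ln
                ca, cb = clone_map[id(a)], clone_map[id(b)]
                mid = Node()
                del ca.neighbors[cb]
                del cb.neighbors[ca]
                _link(mid, ca, 1.0)
                _link(mid, cb, 1.0)
                leaf = Node(label=name)
                _link(mid, leaf, 1.0)
                new_trees.append(list(clone_map.values()) + [mid, leaf])
        trees = new_trees
    return [UnrootedTree(nodes) for nodes in trees]
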