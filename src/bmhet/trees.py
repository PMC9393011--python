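"""Rooted phylogenies with regime-painted branches.

A phylogeny is a rooted tree with branch lengths in arbitrary time units.
A *painted* phylogeny additionally carries, on every branch, an ordered
sequence of ``(regime, duration)`` segments running rootward to tipward.
Regimes partition evolutionary time into categories within which the
parameters of a trait-evolution model are shared.

The painted-tree serialization used here is the "simmap" extension of
Newick, in which each branch-length annotation is replaced by
``:{state,length:state,length:...}``.

The quantity that connects a painting to a Gaussian trait model is the
per-regime shared-ancestry matrix ``C_k``: entry (i, j) is the amount of
time spent in regime k on the path from the root to the most recent common
ancestor of tips i and j (for i == j, on the path from the root to tip i).
Summed over regimes, the ``C_k`` recover the ordinary single-rate
Brownian-motion covariance structure ``C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Node",
    "Phylo",
    "PaintedTree",
    "SharedTimeMatrices",
    "NewickParseError",
    "PaintingError",
    "parse_newick",
    "write_newick",
    "parse_simmap",
    "write_simmap",
    "paint_clade",
    "paint_uniform",
    "paint_from_reconstruction",
    "rescale_to_height",
    "shared_time_matrices",
]

SEGMENT_SUM_ATOL = 1e-8
SEGMENT_SUM_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised for malformed Newick / simmap input; carries the offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class PaintingError(ValueError):
    """Raised when a branch painting is internally inconsistent."""


class Node:
    """A node of a rooted tree.

    ``length`` is the length of the branch subtending the node (``None``
    at the root).  ``segments`` is the painting of that branch, ordered
    rootward to tipward, or ``None`` on unpainted trees.
    """

    __slots__ = ("label", "length", "children", "parent", "segments")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.segments: list[tuple[str, float]] | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.label!r} length={self.length}>"


class Phylo:
    """A rooted phylogeny with mandatory branch lengths and unique tip labels."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if any(lb is None for lb in labels):
            raise ValueError("all tips must be labeled")
        if len(set(labels)) != len(labels):
            dup = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        for node in self.preorder():
            if node.is_root:
                continue
            if node.length is None:
                raise ValueError(
                    f"branch leading to {node.label or '<internal>'} has no length; "
                    "branch lengths are required"
                )
            if node.length < 0:
                raise ValueError(f"negative branch length {node.length}")

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def edges(self) -> list[Node]:
        """Non-root nodes, i.e. one per branch."""
        return [n for n in self.preorder() if not n.is_root]

    # -- queries -----------------------------------------------------------

    def find(self, label: str) -> Node:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labeled {label!r}")

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of a set of tip labels."""
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        tipsets: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                tipsets[node] = {node.label}
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= tipsets[c]
                tipsets[node] = s
            if want <= tipsets[node]:
                return node
        raise AssertionError("unreachable")

    def depths(self) -> dict[Node, float]:
        """Distance from the root to the tipward end of each branch."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if not node.is_root:
                out[node] = out[node.parent] + node.length
        return out

    @property
    def height(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.tips())

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def copy(self) -> "Phylo":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            if node.segments is not None:
                new.segments = list(node.segments)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return type(self)(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} with {self.n_tips} tips>"


class PaintedTree(Phylo):
    """A phylogeny whose every branch carries (regime, duration) segments."""

    def _validate(self) -> None:
        super()._validate()
        for node in self.edges():
            if not node.segments:
                raise PaintingError(
                    f"branch leading to {node.label or '<internal>'} is unpainted"
                )
            total = sum(d for _, d in node.segments)
            if node.length > 0 and any(d <= 0 for _, d in node.segments):
                raise PaintingError("segment durations must be > 0")
            if abs(total - node.length) > SEGMENT_SUM_ATOL + SEGMENT_SUM_RTOL * max(
                node.length, 1.0
            ):
                raise PaintingError(
                    f"segments sum to {total}, branch length is {node.length} "
                    f"(branch to {node.label or '<internal>'})"
                )

    @property
    def regimes(self) -> list[str]:
        """Regime labels in order of first appearance (root-to-tip preorder)."""
        seen: list[str] = []
        for node in self.edges():
            for state, _ in node.segments:
                if state not in seen:
                    seen.append(state)
        return seen

    def tip_regimes(self) -> dict[str, str]:
        """Regime of the tipmost segment of each terminal branch."""
        return {t.label: t.segments[-1][0] for t in self.tips()}

    def time_in_regime(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for node in self.edges():
            for state, dur in node.segments:
                out[state] = out.get(state, 0.0) + dur
        return out

    def n_transitions(self) -> int:
        """Number of painted regime changes, counting across parent branches."""
        count = 0
        for node in self.edges():
            states = [s for s, _ in node.segments]
            count += sum(1 for a, b in zip(states, states[1:]) if a != b)
            if not node.parent.is_root and node.parent.segments:
                if node.parent.segments[-1][0] != states[0]:
                    count += 1
        return count

    def strip_paint(self) -> Phylo:
        tree = self.copy()
        for node in tree.preorder():
            node.segments = None
        return Phylo(tree.root)


@dataclass(frozen=True)
class SharedTimeMatrices:
    """Per-regime shared-ancestry matrices C_k for an ordered set of taxa."""

    taxa: tuple[str, ...]
    regimes: tuple[str, ...]
    stack: np.ndarray  # shape (K, n, n)

    def __post_init__(self):
        K, n, m = self.stack.shape
        assert n == m == len(self.taxa) and K == len(self.regimes)

    def matrix(self, regime: str) -> np.ndarray:
        return self.stack[self.regimes.index(regime)]

    @property
    def total(self) -> np.ndarray:
        """The single-regime shared-ancestry matrix C = sum_k C_k."""
        return self.stack.sum(axis=0)

    def reorder(self, taxa: Sequence[str]) -> "SharedTimeMatrices":
        idx = [self.taxa.index(t) for t in taxa]
        return SharedTimeMatrices(
            tuple(taxa), self.regimes, self.stack[:, idx][:, :, idx]
        )


# ---------------------------------------------------------------------------
# Newick / simmap parsing
# ---------------------------------------------------------------------------


class _Reader:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise NewickParseError(f"expected {ch!r}, found {self.peek()!r}", self.pos)
        self.pos += 1

    def skip_ws(self) -> None:
        while self.peek() and self.peek() in " \t\r\n":
            self.pos += 1


_LABEL_END = set("(),:;{}[]\t\r\n ")


def _read_label(r: _Reader) -> str | None:
    if r.peek() in ("'", '"'):
        quote = r.take()
        start = r.pos
        out = []
        while True:
            ch = r.take()
            if not ch:
                raise NewickParseError("unterminated quoted label", start)
            if ch == quote:
                if r.peek() == quote:  # escaped quote
                    out.append(r.take())
                    continue
                break
            out.append(ch)
        return "".join(out)
    out = []
    while r.peek() and r.peek() not in _LABEL_END:
        out.append(r.take())
    return "".join(out) or None


def _read_number(r: _Reader) -> float:
    start = r.pos
    while r.peek() != "" and r.peek() in "+-.eE0123456789":
        r.pos += 1
    token = r.text[start : r.pos]
    try:
        return float(token)
    except ValueError:
        raise NewickParseError(f"malformed number {token!r}", start) from None


def _read_segments(r: _Reader) -> list[tuple[str, float]]:
    """Read a simmap annotation ``{s,l:s,l:...}`` (rootward to tipward)."""
    open_at = r.pos
    r.expect("{")
    segments: list[tuple[str, float]] = []
    while True:
        state = _read_label(r)
        if state is None:
            raise NewickParseError("empty regime label in simmap annotation", r.pos)
        r.expect(",")
        dur = _read_number(r)
        if dur < 0:
            raise NewickParseError(f"negative segment duration {dur}", r.pos)
        segments.append((state, dur))
        ch = r.take()
        if ch == "}":
            break
        if ch != ":":
            raise NewickParseError(
                f"expected ':' or '}}' in simmap annotation, found {ch!r}", r.pos - 1
            )
    if not segments:
        raise NewickParseError("empty simmap annotation", open_at)
    return segments


def _parse_tree(text: str, simmap: bool, segment_order: str = "rootward") -> Node:
    r = _Reader(text)
    r.skip_ws()

    def parse_subtree() -> Node:
        r.skip_ws()
        node = Node()
        if r.peek() == "(":
            r.take()
            while True:
                node.add_child(parse_subtree())
                r.skip_ws()
                ch = r.take()
                if ch == ")":
                    break
                if ch != ",":
                    raise NewickParseError(
                        f"expected ',' or ')', found {ch!r}", r.pos - 1
                    )
            r.skip_ws()
            node.label = _read_label(r)
        else:
            node.label = _read_label(r)
            if node.label is None:
                raise NewickParseError("expected a taxon label", r.pos)
        r.skip_ws()
        if r.peek() == ":":
            r.take()
            r.skip_ws()
            if r.peek() == "{":
                segs = _read_segments(r)
                if segment_order == "tipward":
                    segs = segs[::-1]
                if any(d > 0 for _, d in segs):
                    segs = [(s, d) for s, d in segs if d > 0]
                else:  # zero-length branch: keep one zero-duration marker
                    segs = segs[:1]
                node.segments = segs
                node.length = sum(d for _, d in segs)
                # an explicit :length after the annotation cross-checks the sum
                if r.peek() == ":":
                    r.take()
                    stated = _read_number(r)
                    if abs(stated - node.length) > SEGMENT_SUM_ATOL + (
                        SEGMENT_SUM_RTOL * max(abs(stated), 1.0)
                    ):
                        raise NewickParseError(
                            f"segment durations sum to {node.length}, "
                            f"stated branch length is {stated}",
                            r.pos,
                        )
                    node.length = stated
            else:
                node.length = _read_number(r)
                if simmap:
                    raise NewickParseError(
                        "expected a simmap annotation '{...}'", r.pos
                    )
        return node

    root = parse_subtree()
    r.skip_ws()
    if r.peek() == ":":  # root branch length; read and discard onto root
        r.take()
        if r.peek() == "{":
            root.segments = _read_segments(r)
            root.length = sum(d for _, d in root.segments)
        else:
            root.length = _read_number(r)
    r.skip_ws()
    r.expect(";")
    r.skip_ws()
    if r.pos != len(r.text):
        raise NewickParseError("trailing characters after ';'", r.pos)
    # the root's own branch (if any) is dropped: the model starts at the root
    root.length = None
    root.segments = None
    return root


def parse_newick(text: str) -> Phylo:
    """Parse a rooted Newick string with mandatory branch lengths."""
    return Phylo(_parse_tree(text, simmap=False))


def parse_simmap(text: str, segment_order: str = "rootward") -> PaintedTree:
    """Parse a painted tree in the simmap-extended Newick dialect.

    Parameters
    ----------
    segment_order:
        ``"rootward"`` (default) reads each ``{s,l:...}`` annotation as
        listed from the rootward end of the branch; ``"tipward"`` accepts
        the reversed convention.
    """
    if segment_order not in ("rootward", "tipward"):
        raise ValueError("segment_order must be 'rootward' or 'tipward'")
    return PaintedTree(_parse_tree(text, simmap=True, segment_order=segment_order))


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_node(node: Node, simmap: bool, parts: list[str]) -> None:
    if node.children:
        parts.append("(")
        for i, c in enumerate(node.children):
            if i:
                parts.append(",")
            _write_node(c, simmap, parts)
        parts.append(")")
    if node.label is not None:
        label = node.label
        if set(label) & _LABEL_END:
            label = "'" + label.replace("'", "''") + "'"
        parts.append(label)
    if node.parent is not None:
        if simmap:
            ann = ":".join(f"{s},{_fmt(d)}" for s, d in node.segments)
            parts.append(":{" + ann + "}")
        else:
            parts.append(":" + _fmt(node.length))


def write_newick(tree: Phylo) -> str:
    """Serialize to Newick with full-precision branch lengths."""
    parts: list[str] = []
    _write_node(tree.root, simmap=False, parts=parts)
    return "".join(parts) + ";"


def write_simmap(tree: PaintedTree) -> str:
    """Serialize a painted tree to the simmap dialect (rootward order)."""
    parts: list[str] = []
    _write_node(tree.root, simmap=True, parts=parts)
    return "".join(parts) + ";"


# ---------------------------------------------------------------------------
# Painting
# ---------------------------------------------------------------------------


def paint_uniform(tree: Phylo, regime: str) -> PaintedTree:
    """Paint every branch with a single regime."""
    out = tree.copy()
    for node in out.edges():
        node.segments = [(regime, node.length)]
    return PaintedTree(out.root)


def paint_clade(
    tree: Phylo,
    node: Node | str | Sequence[str],
    regime: str,
    base_regime: str,
    shift_fraction: float = 0.5,
) -> PaintedTree:
    """Paint one derived clade against a base regime.

    All branches strictly inside the clade get ``regime``; the stem branch
    is split so that the first ``shift_fraction`` of its length (rootward)
    remains in ``base_regime``; every other branch is ``base_regime``.
    The default 0.5 puts the shift halfway along the stem.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise ValueError("shift_fraction must be in [0, 1]")
    out = tree.copy()
    if isinstance(node, Node):
        # locate the corresponding node in the copy by path
        path = []
        cur = node
        while cur.parent is not None:
            path.append(cur.parent.children.index(cur))
            cur = cur.parent
        target = out.root
        for i in reversed(path):
            target = target.children[i]
    elif isinstance(node, str):
        target = out.find(node)
    else:
        target = out.mrca(list(node))
    if target.is_root:
        raise ValueError("cannot paint the whole tree as a derived clade")

    inside: set[Node] = set()
    stack = [target]
    while stack:
        cur = stack.pop()
        inside.add(cur)
        stack.extend(cur.children)

    for n in out.edges():
        if n is target:
            rootward = shift_fraction * n.length
            segs = []
            if rootward > 0:
                segs.append((base_regime, rootward))
            if n.length - rootward > 0:
                segs.append((regime, n.length - rootward))
            n.segments = segs or [(regime, 0.0)]
        elif n in inside:
            n.segments = [(regime, n.length)] if n.length > 0 else [(regime, 0.0)]
        else:
            n.segments = (
                [(base_regime, n.length)] if n.length > 0 else [(base_regime, 0.0)]
            )
    return PaintedTree(out.root)


def paint_from_reconstruction(
    tree: Phylo, node_states: Mapping[Node, str]
) -> PaintedTree:
    """Paint from an ancestral-state assignment, shifts at branch midpoints.

    Branches whose two endpoint states agree are painted uniformly; a branch
    whose endpoints differ is split 50/50, parent state rootward.  Keys of
    ``node_states`` may be ``Node`` objects of ``tree`` or node/tip labels.
    """

    def state_of(node: Node) -> str:
        if node in node_states:
            return node_states[node]
        if node.label is not None and node.label in node_states:
            return node_states[node.label]
        raise KeyError(
            f"no state assigned to node {node.label or '<internal>'}"
        )

    out = tree.copy()
    orig = list(tree.preorder())
    copies = list(out.preorder())
    mapping = dict(zip(copies, orig))
    for n in out.edges():
        parent_state = state_of(mapping[n.parent])
        child_state = state_of(mapping[n])
        if parent_state == child_state or n.length == 0:
            n.segments = (
                [(child_state, n.length)] if n.length > 0 else [(child_state, 0.0)]
            )
        else:
            half = 0.5 * n.length
            n.segments = [(parent_state, half), (child_state, half)]
    return PaintedTree(out.root)


def rescale_to_height(tree: Phylo, target_height: float):
    """Rescale all branch (and segment) lengths to a given total height.

    The height is the maximum root-to-tip distance.  Rescaling time is
    absorbed by the Brownian rates (sigma^2 scales inversely), so relative
    model fits are unchanged.
    """
    if target_height <= 0:
        raise ValueError("target_height must be > 0")
    h = tree.height
    if h == 0:
        raise ValueError("cannot rescale a zero-height tree")
    f = target_height / h
    out = tree.copy()
    for node in out.edges():
        node.length *= f
        if node.segments is not None:
            node.segments = [(s, d * f) for s, d in node.segments]
    return type(tree)(out.root)


# ---------------------------------------------------------------------------
# Shared-time matrices
# ---------------------------------------------------------------------------


def shared_time_matrices(
    tree: PaintedTree, taxa: Sequence[str] | None = None
) -> SharedTimeMatrices:
    """Per-regime shared-ancestry matrices.

    ``C_k[i, j]`` is the time spent in regime k on the path from the root
    to the MRCA of taxa i and j (to tip i itself on the diagonal).  The
    matrices sum over k to the standard Brownian-motion structure C.
    """
    regimes = tuple(tree.regimes)
    kindex = {r: i for i, r in enumerate(regimes)}
    K = len(regimes)

    all_tips = tree.tip_labels
    if taxa is None:
        taxa = all_tips
    else:
        missing = [t for t in taxa if t not in set(all_tips)]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
    tindex = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)

    # cumulative time-in-regime from the root to the tipward end of each branch
    depth: dict[Node, np.ndarray] = {tree.root: np.zeros(K)}
    for node in tree.preorder():
        if node.is_root:
            continue
        vec = depth[node.parent].copy()
        for state, dur in node.segments:
            vec[kindex[state]] += dur
        depth[node] = vec

    stack = np.zeros((K, n, n))
    tipsets: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            tipsets[node] = [tindex[node.label]] if node.label in tindex else []
            if node.label in tindex:
                i = tindex[node.label]
                stack[:, i, i] = depth[node]
        else:
            lists = [tipsets[c] for c in node.children]
            vec = depth[node]
            for a in range(len(lists)):
                for b in range(a + 1, len(lists)):
                    for i in lists[a]:
                        ii = np.asarray(lists[b])
                        stack[:, i, ii] = vec[:, None]
                        stack[:, ii, i] = vec[:, None]
            merged: list[int] = []
            for l in lists:
                merged.extend(l)
            tipsets[node] = merged
    return SharedTimeMatrices(tuple(taxa), regimes, stack)
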