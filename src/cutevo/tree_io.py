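"""Rooted time-calibrated trees: parsing, validation, pruning, SIMMAP output.

The in-memory container is :class:`Chronogram`, a lightweight rooted tree
whose branch lengths are in absolute time units (Ma for the study system).
Plain newick and NEXUS input go through dendropy; the SIMMAP dialect used to
serialize stochastic character maps (``tip:{state,dur:state,dur}``) has no
reader or writer among the installed libraries, so a small dedicated
serializer/parser lives here.

Two time coordinates are used throughout the package:

* ``age``: time before present; tips sit at age 0, the root at the root age.
* ``forward time`` ``t_f = root_age - age``: elapsed time since the root,
  the axis of the trait-accumulation grid.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import dendropy

from .errors import NewickParseError, UltrametricError, ValidationError

#: Default relative tolerance (vs root age) for the ultrametric check.
DEFAULT_ULTRA_TOL = 1e-6


class Node:
    """Tree node; ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("id", "label", "length", "parent", "children")

    def __init__(self, label=None, length=None):
        self.id: int = -1
        self.label: str | None = label
        self.length: float | None = length
        self.parent: "Node | None" = None
        self.children: list["Node"] = []

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {self.id} {kind} {self.label or ''}>"


class Chronogram:
    """Rooted tree with branch lengths; node ids assigned in postorder.

    Postorder ids are deterministic for identical input text, so node-indexed
    reports (ancestral-state tables, transition events) are reproducible.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()

    # -- structure ---------------------------------------------------------

    def _index(self) -> None:
        self.nodes: list[Node] = list(self._postorder(self.root))
        for i, node in enumerate(self.nodes):
            node.id = i
        labels = [n.label for n in self.nodes if n.is_tip and n.label is not None]
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {', '.join(map(str, dups))}")

    @staticmethod
    def _postorder(node: Node):
        stack = [(node, False)]
        while stack:
            n, done = stack.pop()
            if done:
                yield n
            else:
                stack.append((n, True))
                for c in reversed(n.children):
                    stack.append((c, False))

    def postorder(self) -> list[Node]:
        return self.nodes

    def preorder(self) -> list[Node]:
        return list(reversed(self.nodes))

    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes if n.is_tip)

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def node(self, node_id: int) -> Node:
        return self.nodes[node_id]

    def copy(self) -> "Chronogram":
        return parse_newick(write_newick(self))

    # -- time --------------------------------------------------------------

    def depths(self) -> dict[int, float]:
        """Root-to-node path length for every node."""
        out: dict[int, float] = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node.id] = out[node.parent.id] + (node.length or 0.0)
        return out

    @property
    def root_age(self) -> float:
        depths = self.depths()
        return max(depths[t.id] for t in self.tips())

    @property
    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.nodes if n is not self.root)

    def max_ultrametric_deviation(self) -> float:
        depths = self.depths()
        tip_depths = [depths[t.id] for t in self.tips()]
        return max(tip_depths) - min(tip_depths)

    def validate_ultrametric(self, tol: float = DEFAULT_ULTRA_TOL) -> None:
        """Raise :class:`UltrametricError` if tip depths disagree.

        ``tol`` is relative to the root age (absolute for a zero-age tree).
        """
        dev = self.max_ultrametric_deviation()
        scale = max(self.root_age, 1.0e-300)
        if dev > tol * scale:
            raise UltrametricError(
                f"tree is not ultrametric: max root-to-tip deviation {dev:g} "
                f"exceeds tolerance {tol:g} x root age {self.root_age:g}",
                max_deviation=dev,
            )


def node_ages(tree: Chronogram, tol: float = DEFAULT_ULTRA_TOL) -> dict[int, float]:
    """Age (time before present) of every node of an ultrametric tree.

    Tips are at age 0 and the root at the maximum root-to-tip path sum.
    """
    tree.validate_ultrametric(tol)
    depths = tree.depths()
    root_age = max(depths[t.id] for t in tree.tips())
    return {nid: root_age - d for nid, d in depths.items()}


# -- newick ----------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Chronogram:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if label is not None:
            label = label.replace(" ", "_")
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return Chronogram(root)


def _check_lengths(tree: Chronogram) -> None:
    for node in tree.nodes:
        if node is tree.root:
            continue
        if node.length is None:
            raise NewickParseError(
                f"branch leading to node '{node.label or node.id}' has no length"
            )
        if math.isnan(node.length):
            raise NewickParseError("NaN branch length")
        if node.length < 0:
            raise NewickParseError(f"negative branch length {node.length}")


def parse_newick(text: str) -> Chronogram:
    """Parse a newick string (branch lengths required; polytomies allowed)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    tree = _from_dendropy(dtree)
    _check_lengths(tree)
    return tree


def read_newick(path) -> Chronogram:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_nexus_trees(path_or_text: str) -> list[Chronogram]:
    """Read every tree from a NEXUS trees block (convenience, read-only)."""
    import os

    kwargs = dict(schema="nexus", preserve_underscores=True)
    if os.path.exists(str(path_or_text)):
        dtrees = dendropy.TreeList.get(path=str(path_or_text), **kwargs)
    else:
        dtrees = dendropy.TreeList.get(data=path_or_text, **kwargs)
    out = []
    for dtree in dtrees:
        tree = _from_dendropy(dtree)
        _check_lengths(tree)
        out.append(tree)
    return out


def _fmt_length(x: float) -> str:
    return format(float(x), ".17g")


def write_newick(tree: Chronogram) -> str:
    """Serialize to newick; round-trips lengths to double precision."""

    def render(node: Node) -> str:
        if node.is_tip:
            body = node.label or ""
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label and node is not tree.root:
                body += node.label
        if node is tree.root or node.length is None:
            return body
        return f"{body}:{_fmt_length(node.length)}"

    return render(tree.root) + ";"


def write_newick_file(tree: Chronogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- pruning ---------------------------------------------------------------


def prune_to_taxa(tree: Chronogram, keep) -> Chronogram:
    """Restrict a tree to a subset of tips.

    Degree-2 nodes created by the removal are suppressed with their incident
    branch lengths summed, so patristic distances between retained tips (and
    ultrametricity) are preserved.  Requires ``|keep| >= 2``.
    """
    keep = set(keep)
    present = set(tree.tip_labels())
    missing = keep - present
    if missing:
        raise ValidationError(
            "taxa not in tree: " + ", ".join(sorted(map(str, missing)))
        )
    if len(keep) < 2:
        raise ValidationError("prune_to_taxa requires at least 2 retained tips")

    work = tree.copy()
    tips = [t for t in work.tips() if t.label not in keep]
    for tip in tips:
        node = tip
        parent = node.parent
        parent.children.remove(node)
        # walk up removing now-childless internals
        while parent is not None and not parent.children:
            node, parent = parent, parent.parent
            if parent is None:
                raise ValidationError("pruning removed every tip")
            parent.children.remove(node)
    # suppress degree-2 internal nodes
    def suppress(node: Node):
        for child in list(node.children):
            suppress(child)
        if node.parent is not None and len(node.children) == 1:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            child.parent = node.parent
            idx = node.parent.children.index(node)
            node.parent.children[idx] = child

    suppress(work.root)
    root = work.root
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    return Chronogram(root)


# -- SIMMAP ----------------------------------------------------------------


#: Relative tolerance for segment-duration sums vs branch lengths.
SEGMENT_SUM_TOL = 1e-8


def _check_segments(tree: Chronogram, history) -> None:
    for node in tree.nodes:
        if node is tree.root:
            continue
        segs = history.branch_segments.get(node.id)
        if segs is None:
            raise ValidationError(f"history missing segments for branch {node.id}")
        total = sum(d for _, d in segs)
        blen = node.length or 0.0
        if abs(total - blen) > SEGMENT_SUM_TOL * max(blen, 1.0):
            raise ValidationError(
                f"segment durations on branch {node.id} sum to {total:g}, "
                f"branch length is {blen:g}"
            )


def write_simmap(tree: Chronogram, history) -> str:
    """Serialize one stochastic map as SIMMAP-annotated newick.

    Branch annotations read ``{state,duration:state,duration}`` with segments
    listed in parent-to-child (rootward-to-tipward) order.
    """
    _check_segments(tree, history)
    labels = history.state_labels

    def annot(node: Node) -> str:
        segs = history.branch_segments[node.id]
        inner = ":".join(f"{labels[s]},{format(d, '.12g')}" for s, d in segs)
        return "{" + inner + "}"

    def render(node: Node) -> str:
        if node.is_tip:
            body = node.label or ""
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        if node is tree.root:
            return body
        return f"{body}:{annot(node)}"

    return render(tree.root) + ";"


_SIMMAP_TOKEN = re.compile(r"[(),;]|[^(),;:]+|:")


def parse_simmap(text: str):
    """Parse SIMMAP-annotated newick into ``(Chronogram, CharacterHistory)``.

    Inverse of :func:`write_simmap` (round-trips segment structure).
    """
    from .stochastic_mapping import CharacterHistory

    pos = 0
    text = text.strip()
    seg_map: dict[int, list[tuple[str, float]] | None] = {}

    def fail(msg: str):
        raise NewickParseError(f"SIMMAP parse error at offset {pos}: {msg}")

    def parse_clade() -> tuple[Node, list[tuple[str, float]] | None]:
        nonlocal pos
        node = Node()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                child, segs = parse_clade()
                seg_map[id(child)] = segs
                node.add_child(child)
                if pos >= len(text):
                    fail("unexpected end of input inside clade")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                fail(f"unexpected character {text[pos]!r}")
        # label
        m = re.match(r"[^(),;:{}\[\]]+", text[pos:])
        if m:
            node.label = m.group(0)
            pos += m.end()
        segs = None
        if pos < len(text) and text[pos] == ":":
            pos += 1
            if pos >= len(text) or text[pos] != "{":
                fail("expected '{' after ':'")
            end = text.find("}", pos)
            if end < 0:
                fail("unterminated '{' annotation")
            inner = text[pos + 1 : end]
            pos = end + 1
            segs = []
            for part in inner.split(":"):
                state, _, dur = part.partition(",")
                if not dur:
                    fail(f"malformed segment {part!r}")
                segs.append((state.strip(), float(dur)))
        return node, segs

    root, root_segs = parse_clade()
    if pos >= len(text) or text[pos] != ";":
        fail("missing terminal ';'")
    if root_segs is not None:
        fail("root must not carry a branch annotation")

    # collect state labels in first-seen (preorder) order
    labels: list[str] = []

    def collect(node: Node):
        segs = seg_map.get(id(node))
        if segs:
            for s, _ in segs:
                if s not in labels:
                    labels.append(s)
        for c in node.children:
            collect(c)

    collect(root)
    label_index = {s: i for i, s in enumerate(labels)}

    # branch length = sum of segment durations
    def finalize(node: Node):
        segs = seg_map.get(id(node))
        if segs is not None:
            node.length = sum(d for _, d in segs)
        for c in node.children:
            finalize(c)

    finalize(root)
    root.length = None
    tree = Chronogram(root)

    branch_segments: dict[int, list[tuple[int, float]]] = {}
    node_states: dict[int, int] = {}
    for node in tree.nodes:
        segs = seg_map.get(id(node))
        if node is tree.root:
            continue
        if segs is None:
            raise NewickParseError(
                f"branch leading to '{node.label or node.id}' lacks a SIMMAP annotation"
            )
        branch_segments[node.id] = [(label_index[s], d) for s, d in segs]
        node_states[node.id] = label_index[segs[-1][0]]
    if tree.root.children:
        first = tree.root.children[0]
        segs = branch_segments[first.id]
        node_states[tree.root.id] = segs[0][0]
    history = CharacterHistory(
        state_labels=tuple(labels),
        node_states=node_states,
        branch_segments=branch_segments,
    )
    return tree, history
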