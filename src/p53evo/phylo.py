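"""Time-calibrated trees, Newick I/O, and the tree surgery the study needs.

The species phylogeny used for ancestral reconstruction is a chronogram:
branch lengths in millions of years (My), all leaves at age 0.  Three
surgical operations are supported, mirroring how the analysis tree is built
from a reference phylogeny: pruning non-target taxa, grafting missing
species at a stated divergence age, and duplicating a whole clade at a
whole-genome-duplication (WGD) age so each species appears once per paralog
(suffixes ``_P1``/``_P2``).  Internal nodes may carry integer ids, written
to and read from Newick as ``[&id=N]`` comment annotations.

Also houses the synteny rule that assigns a p53 gene copy to a paralog
class from its flanking-gene neighborhood.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

ULTRAMETRIC_TOL = 1e-6  # My


class NewickParseError(ValueError):
    pass


class TreeSurgeryError(ValueError):
    pass


class TreeNode:
    """A node of a rooted tree; ``length`` is the edge above (None at root)."""

    __slots__ = ("label", "length", "node_id", "children", "parent")

    def __init__(self, label=None, length=None, node_id=None):
        self.label: str | None = label
        self.length: float | None = length
        self.node_id: int | None = node_id
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label or self.node_id or '?'} {kind}>"


class TimeTree:
    """Rooted tree with branch lengths; optionally a chronogram in My."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [lf.label for lf in self.leaves()]
        if any(lb is None for lb in labels):
            raise ValueError("every leaf must be labeled")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [nd for nd in self.preorder() if not nd.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.leaves()]

    def find_leaf(self, label: str) -> TreeNode:
        for lf in self.leaves():
            if lf.label == label:
                return lf
        raise KeyError(f"no leaf named {label!r}")

    def find_node(self, node_id: int) -> TreeNode:
        for nd in self.preorder():
            if nd.node_id == node_id:
                return nd
        raise KeyError(f"no node with id {node_id}")

    # -- metrics ------------------------------------------------------------

    def depths(self) -> dict[TreeNode, float]:
        d: dict[TreeNode, float] = {self.root: 0.0}
        for nd in self.preorder():
            if nd is self.root:
                continue
            if nd.length is None or nd.length < 0:
                raise ValueError("all non-root branches need nonnegative lengths")
            d[nd] = d[nd.parent] + nd.length
        return d

    @property
    def height(self) -> float:
        d = self.depths()
        return max(d[lf] for lf in self.leaves())

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        d = self.depths()
        ages = [d[lf] for lf in self.leaves()]
        return max(ages) - min(ages) <= tol

    def node_age(self, node: TreeNode) -> float:
        """Age (My before present) of a node in a chronogram."""
        if not self.is_ultrametric():
            raise ValueError("node ages are only defined for chronograms")
        d = self.depths()
        return self.height - d[node]

    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Pairwise patristic distances between leaves (label order sorted)."""
        d = self.depths()
        leaves = sorted(self.leaves(), key=lambda lf: lf.label)
        paths: list[dict[TreeNode, float]] = []
        for lf in leaves:
            anc: dict[TreeNode, float] = {}
            nd = lf
            while nd is not None:
                anc[nd] = d[lf] - d[nd]
                nd = nd.parent
            paths.append(anc)
        n = len(leaves)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                # most recent common ancestor = shallowest shared node
                shared = [nd for nd in paths[i] if nd in paths[j]]
                mrca = max(shared, key=lambda nd: d[nd])
                mat[i, j] = mat[j, i] = paths[i][mrca] + paths[j][mrca]
        return [lf.label for lf in leaves], mat

    # -- utilities ----------------------------------------------------------

    def copy(self) -> "TimeTree":
        def clone(nd: TreeNode) -> TreeNode:
            new = TreeNode(nd.label, nd.length, nd.node_id)
            for ch in nd.children:
                new.add_child(clone(ch))
            return new

        return TimeTree(clone(self.root))

    def assign_node_ids(self, start: int = 1) -> None:
        """Number internal nodes in postorder, skipping ids already set."""
        used = {nd.node_id for nd in self.preorder() if nd.node_id is not None}
        nxt = start
        for nd in self.postorder():
            if nd.is_leaf or nd.node_id is not None:
                continue
            while nxt in used:
                nxt += 1
            nd.node_id = nxt
            used.add(nxt)

    def __len__(self) -> int:
        return len(self.leaves())


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy; id dialect as [&id=N] annotations)


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        nid = dnode.annotations.get_value("id", None)
        node = TreeNode(
            label=label,
            length=dnode.edge.length,
            node_id=int(nid) if nid is not None else None,
        )
        for ch in dnode.child_nodes():
            node.add_child(convert(ch))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return TimeTree(root)


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Internal-node ``[&id=N]`` comment annotations are read into
    ``node_id``.  Malformed input and duplicate leaf labels raise
    :class:`NewickParseError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    try:
        return _from_dendropy(dtree)
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc


def serialize_newick(
    tree: TimeTree,
    id_annotations: bool = True,
    precision: int = 12,
) -> str:
    """Write Newick with mandatory branch lengths.

    When ``id_annotations`` is on, internal-node ids are emitted as
    ``[&id=N]`` before the branch-length colon, a dialect dendropy and most
    viewers re-read as node annotations.
    """

    def fmt(nd: TreeNode, is_root: bool) -> str:
        if nd.is_leaf:
            core = nd.label
        else:
            core = "(" + ",".join(fmt(ch, False) for ch in nd.children) + ")"
            if nd.label:
                core += nd.label
        if id_annotations and nd.node_id is not None and not nd.is_leaf:
            core += f"[&id={nd.node_id}]"
        if not is_root:
            length = 0.0 if nd.length is None else nd.length
            core += f":{length:.{precision}g}"
        return core

    return fmt(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# Tree surgery


def prune_taxa(tree: TimeTree, names: Iterable[str]) -> TimeTree:
    """Remove the listed leaves, suppressing unary nodes (lengths summed).

    Pairwise patristic distances among the remaining leaves are unchanged.
    """
    names = set(names)
    unknown = names - set(tree.leaf_labels)
    if unknown:
        raise TreeSurgeryError(f"cannot prune unknown taxa: {sorted(unknown)}")
    if not names:
        return tree.copy()
    if len(names) >= len(tree.leaf_labels):
        raise TreeSurgeryError("pruning would remove every leaf")
    out = tree.copy()
    for name in names:
        leaf = out.find_leaf(name)
        parent = leaf.parent
        if parent is None:
            raise TreeSurgeryError("cannot prune the only node of the tree")
        parent.children.remove(leaf)
        # walk upward suppressing any node left unary
        node = parent
        while node is not None and len(node.children) == 1:
            (only,) = node.children
            if node.parent is None:
                # unary root: child becomes the new root
                only.parent = None
                only.length = None
                out.root = only
                node = None
            else:
                only.length = (only.length or 0.0) + (node.length or 0.0)
                gp = node.parent
                gp.children[gp.children.index(node)] = only
                only.parent = gp
                node = gp
    return TimeTree(out.root)


def _locate(tree: TimeTree, node_ref) -> TreeNode:
    if isinstance(node_ref, TreeNode):
        return node_ref
    if isinstance(node_ref, int):
        return tree.find_node(node_ref)
    return tree.find_leaf(node_ref)


def graft_leaf(
    tree: TimeTree,
    attach_edge,
    divergence_age: float,
    new_label: str,
) -> TimeTree:
    """Attach a new extant leaf on the edge above ``attach_edge``.

    ``divergence_age`` (My) must lie strictly inside the age span of that
    edge; the result stays ultrametric and leaves all prior pairwise
    distances untouched.
    """
    if not tree.is_ultrametric():
        raise TreeSurgeryError("graft_leaf requires a chronogram")
    if new_label in tree.leaf_labels:
        raise TreeSurgeryError(f"leaf {new_label!r} already present")
    out = tree.copy()
    ref = _locate(tree, attach_edge)
    # re-find the corresponding node in the copy by position
    node = _corresponding(tree, out, ref)
    if node.parent is None:
        raise TreeSurgeryError("cannot graft on the root's nonexistent parent edge")
    child_age = tree.node_age(ref)
    parent_age = child_age + node.length
    if not (child_age < divergence_age < parent_age):
        raise TreeSurgeryError(
            f"divergence age {divergence_age} My outside the open interval "
            f"({child_age:.6g}, {parent_age:.6g}) of the attachment edge"
        )
    parent = node.parent
    mid = TreeNode(length=parent_age - divergence_age)
    parent.children[parent.children.index(node)] = mid
    mid.parent = parent
    node.length = divergence_age - child_age
    mid.add_child(node)
    mid.add_child(TreeNode(label=new_label, length=divergence_age))
    return TimeTree(out.root)


def _corresponding(src: TimeTree, dst: TimeTree, node: TreeNode) -> TreeNode:
    """Find in ``dst`` (a copy of ``src``) the node matching ``node``."""
    path: list[int] = []
    nd = node
    while nd.parent is not None:
        path.append(nd.parent.children.index(nd))
        nd = nd.parent
    out = dst.root
    for idx in reversed(path):
        out = out.children[idx]
    return out


def duplicate_clade(
    tree: TimeTree,
    clade_root,
    split_age: float,
    suffixes: tuple[str, str] = ("_P1", "_P2"),
) -> TimeTree:
    """Duplicate a clade at a WGD split age, suffixing paralog leaf labels.

    A new bifurcation is created at ``split_age`` on the edge above the
    clade root; its two children are copies of the clade, with ``suffixes``
    appended to every leaf label.  Ultrametricity is preserved.
    """
    if not tree.is_ultrametric():
        raise TreeSurgeryError("duplicate_clade requires a chronogram")
    if suffixes[0] == suffixes[1]:
        raise TreeSurgeryError("paralog suffixes must differ")
    out = tree.copy()
    ref = _locate(tree, clade_root)
    node = _corresponding(tree, out, ref)
    clade_age = tree.node_age(ref)
    if split_age < clade_age:
        raise TreeSurgeryError(
            f"split age {split_age} My is below the clade root age {clade_age:.6g} My"
        )
    if node.parent is None:
        raise TreeSurgeryError("cannot duplicate the whole tree at the root")
    parent_age = clade_age + node.length
    if split_age >= parent_age:
        raise TreeSurgeryError(
            f"split age {split_age} My does not lie on the edge above the clade "
            f"(spans ({clade_age:.6g}, {parent_age:.6g}) My)"
        )

    def clone_with_suffix(nd: TreeNode, suffix: str) -> TreeNode:
        label = nd.label + suffix if nd.is_leaf else nd.label
        new = TreeNode(label, nd.length, None)
        for ch in nd.children:
            new.add_child(clone_with_suffix(ch, suffix))
        return new

    parent = node.parent
    split = TreeNode(length=parent_age - split_age)
    parent.children[parent.children.index(node)] = split
    split.parent = parent
    for suffix in suffixes:
        copy = clone_with_suffix(node, suffix)
        copy.length = split_age - clade_age
        split.add_child(copy)
    return TimeTree(out.root)


# ---------------------------------------------------------------------------
# Synteny-based paralog classification


SIDES = ("upstream", "downstream")
STRANDS = ("sense", "antisense")


@dataclass(frozen=True)
class NeighborGene:
    gene: str
    side: str
    strand: str

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")


@dataclass(frozen=True)
class GeneNeighborhood:
    """Ordered flanking genes around a focal p53 gene copy."""

    genes: tuple[NeighborGene, ...] = ()

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "GeneNeighborhood":
        return cls(tuple(NeighborGene(g, s, st) for g, s, st in rows))

    @classmethod
    def from_csv(cls, path) -> "GeneNeighborhood":
        import pandas as pd

        df = pd.read_csv(path)
        required = {"gene", "side", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"neighborhood CSV needs columns {sorted(required)}")
        return cls.from_rows(
            (str(r.gene), str(r.side), str(r.strand)) for r in df.itertuples()
        )

    def on_side(self, side: str) -> tuple[NeighborGene, ...]:
        return tuple(g for g in self.genes if g.side == side)


@dataclass(frozen=True)
class ParalogCall:
    klass: str  # "ClassI" | "ClassII" | "unknown"
    conflict: bool = False


def _is_e3_ligase(symbol: str) -> bool:
    s = symbol.lower()
    return "e3" in s or "ligase" in s or s.startswith(("rnf", "trim", "ube", "mdm"))


def _is_capga(symbol: str) -> bool:
    return symbol.lower().startswith("capg")


def classify_paralog(nbhd: GeneNeighborhood) -> ParalogCall:
    """Assign a p53 copy to a paralog class from its gene neighborhood.

    Class II (paralog 2): *gps2* upstream in sense orientation, and an
    antisense E3-ubiquitin-ligase gene followed by a *capga* homolog
    downstream.  Class I (paralog 1): *slc2a4* upstream in antisense
    orientation.  Evidence for both at once is a conflict and yields
    ``unknown`` with the conflict flag set.
    """
    upstream = nbhd.on_side("upstream")
    downstream = nbhd.on_side("downstream")

    class2_up = any(g.gene.lower() == "gps2" and g.strand == "sense" for g in upstream)
    class2_down = False
    for i, g in enumerate(downstream):
        if _is_e3_ligase(g.gene) and g.strand == "antisense":
            if any(_is_capga(h.gene) for h in downstream[i + 1 :]):
                class2_down = True
                break
    is_class2 = class2_up and class2_down

    is_class1 = any(
        g.gene.lower() == "slc2a4" and g.strand == "antisense" for g in upstream
    )

    if is_class1 and is_class2:
        return ParalogCall("unknown", conflict=True)
    if is_class2:
        return ParalogCall("ClassII")
    if is_class1:
        return ParalogCall("ClassI")
    return ParalogCall("unknown")
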