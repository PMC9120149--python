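"""Rooted trees with node-type annotations.

Both the species tree and the gene trees of this pipeline are rooted
trees whose internal nodes carry a type label: ``acquisition`` (a gene
entering the proto-eukaryotic lineage), ``duplication`` (a pre-LECA gene
duplication), ``LECA`` (the last eukaryotic common ancestor of a family)
or ``speciation``.  Leaves are species (species tree) or LECA
orthogroups (gene trees).

Newick parsing is delegated to :mod:`dendropy`; this module wraps the
parsed tree into a light-weight node structure convenient for the
pruning and parsimony algorithms downstream.  Annotations are accepted
either as plain internal-node labels (``(A,B)duplication``) or as
bracketed comments (``(A,B)[&&NHX:type=duplication]`` or simply
``(A,B)[duplication]``).
"""

from __future__ import annotations

import io
import logging
import warnings
from typing import Iterator, Optional

import dendropy

logger = logging.getLogger(__name__)

NODE_TYPES = {"acquisition", "duplication", "LECA", "speciation", "leaf"}

#: lower-case lookup so that e.g. "Duplication" or "leca" round-trip
_TYPE_BY_LOWER = {t.lower(): t for t in NODE_TYPES}


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    name:
        Node name; leaf names are taxon labels, unnamed internal nodes
        get deterministic preorder names ``N1, N2, ...`` at parse time.
    node_type:
        One of :data:`NODE_TYPES`.
    length:
        Length of the branch leading into this node (``None`` if the
        source tree carries no lengths; the root has no branch).
    """

    __slots__ = ("name", "node_type", "length", "children", "parent")

    def __init__(
        self,
        name: str = "",
        node_type: str = "speciation",
        length: Optional[float] = None,
    ) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        self.name = name
        self.node_type = node_type
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    # -- construction -------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    # -- queries ------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, {self.node_type!r})"


class AnnotatedTree:
    """A rooted tree with typed nodes.

    The root may be multifurcating (the unresolved-eukaryotic-root
    variant of the species tree); other multifurcations are preserved
    as-is.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._index: dict[str, TreeNode] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._index.clear()
        counter = 0
        for node in self.root.preorder():
            if not node.name:
                counter += 1
                node.name = f"N{counter}"
            if node.name in self._index:
                raise ValueError(f"duplicate node name {node.name!r}")
            self._index[node.name] = node

    # -- queries ------------------------------------------------------
    def node(self, name: str) -> TreeNode:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    @property
    def root_is_multifurcating(self) -> bool:
        return len(self.root.children) > 2

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def branches(self) -> list[TreeNode]:
        """All non-root nodes; a branch is named by its child node."""
        return [n for n in self.root.preorder() if n.parent is not None]

    # -- serialization ------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner}){node.name}"
            if node.node_type not in ("leaf", "speciation"):
                body += f"[&&NHX:type={node.node_type}]"
            if node.length is not None and node.parent is not None:
                body += f":{node.length:g}"
            return body

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnnotatedTree({len(self.leaf_names)} leaves)"


def _type_from_comments(comments: list[str]) -> Optional[str]:
    for comment in comments:
        text = comment.strip().lstrip("&")
        if text.lower().startswith("nhx:"):
            for field in text[4:].split(":"):
                if "=" in field:
                    key, _, value = field.partition("=")
                    if key.strip().lower() == "type":
                        return _TYPE_BY_LOWER.get(value.strip().lower())
        elif text.lower() in _TYPE_BY_LOWER:
            return _TYPE_BY_LOWER[text.lower()]
    return None


def parse_newick(text: str) -> AnnotatedTree:
    """Parse an annotated Newick string into an :class:`AnnotatedTree`.

    Internal-node type labels are read from plain labels or bracketed
    comments; internal nodes without a recognised annotation default to
    ``speciation`` (with a warning).  Unifurcations (e.g. the spurious
    outer pair of parentheses in ``((A,B));``) are collapsed.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> TreeNode:
        children = dnode.child_nodes()
        if dnode.taxon is not None:
            name = dnode.taxon.label or ""
        else:
            name = dnode.label or ""
        length = dnode.edge.length
        if not children:
            node_type = "leaf"
            if name in _TYPE_BY_LOWER:
                raise ValueError(f"leaf named like a node type: {name!r}")
        else:
            node_type = None
            if name.lower() in _TYPE_BY_LOWER:
                node_type = _TYPE_BY_LOWER[name.lower()]
                name = ""
            if node_type is None:
                node_type = _type_from_comments(dnode.comments or [])
            if node_type is None:
                node_type = "speciation"
                if not name:
                    warnings.warn(
                        "unlabeled internal node treated as speciation",
                        stacklevel=3,
                    )
        node = TreeNode(name=name, node_type=node_type, length=length)
        for child in children:
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)

    # collapse unifurcations introduced by redundant parentheses; typed
    # unary nodes (e.g. an acquisition with a single descendant lineage,
    # as in gene trees without prokaryotic outgroups) are meaningful and
    # are kept
    def collapse(node: TreeNode) -> TreeNode:
        while len(node.children) == 1 and node.node_type == "speciation":
            warnings.warn("collapsing unary node", stacklevel=3)
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            node = child
        node.children = [collapse(c) for c in node.children]
        for c in node.children:
            c.parent = node
        return node

    root = collapse(root)
    root.parent = None
    root.length = None
    tree = AnnotatedTree(root)
    if tree.root_is_multifurcating:
        logger.info("tree has a multifurcating (unresolved) root")
    return tree


def collapse_branch(tree: AnnotatedTree, node_name: str) -> AnnotatedTree:
    """Collapse an internal branch, attaching the node's children to its
    parent (used e.g. to form the unresolved-root species-tree variant).
    """
    source = parse_newick(tree.to_newick())  # deep copy
    node = source.node(node_name)
    if node.parent is None or node.is_leaf:
        raise ValueError("can only collapse an internal non-root branch")
    parent = node.parent
    position = parent.children.index(node)
    for offset, child in enumerate(node.children):
        child.parent = parent
        parent.children.insert(position + offset, child)
    parent.children.remove(node)
    return AnnotatedTree(source.root)


def read_annotated_tree(path) -> AnnotatedTree:
    """Read an annotated Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_annotated_tree(tree: AnnotatedTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
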