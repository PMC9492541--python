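"""Rooted, labelled species trees.

The species tree is the coordinate system of every downstream accounting
step: reconciliation event tables, per-node compositions and fusion-ancestry
checks all address nodes by their labels here.  Internally the tree is a
plain parent map plus a deterministic preorder, which is all the pipeline
needs; newick reading and writing go through :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy


class TreeError(ValueError):
    """Raised for structurally invalid species trees."""


@dataclass(frozen=True)
class SpeciesTree:
    """A rooted species tree with uniquely labelled tips and internal nodes.

    Parameters
    ----------
    parent :
        Mapping child label -> parent label, for every non-root node.
    root :
        Label of the single root node.
    children :
        Mapping label -> tuple of child labels, in newick order.
    groups :
        Optional mapping label -> group tag (e.g. ``"Metazoa"``); tags on
        internal nodes apply to the clade they subtend.
    branch_lengths :
        Optional mapping child label -> length of the branch into it.
    """

    parent: dict[str, str]
    root: str
    children: dict[str, tuple[str, ...]]
    groups: dict[str, str] = field(default_factory=dict)
    branch_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.children)
        if self.root not in labels:
            raise TreeError(f"root {self.root!r} not among node labels")
        for child, par in self.parent.items():
            if par not in labels or child not in labels:
                raise TreeError(f"dangling parent link {child!r} -> {par!r}")
        if self.root in self.parent:
            raise TreeError("root must not have a parent")
        # every non-root node must be reachable from the root
        seen = set(self.preorder())
        if seen != labels:
            missing = sorted(labels - seen)
            raise TreeError(f"nodes unreachable from root: {missing}")

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            label = stack.pop()
            yield label
            stack.extend(reversed(self.children[label]))

    @property
    def nodes(self) -> list[str]:
        return list(self.preorder())

    @property
    def tips(self) -> list[str]:
        return [n for n in self.preorder() if not self.children[n]]

    @property
    def internal_nodes(self) -> list[str]:
        return [n for n in self.preorder() if self.children[n]]

    def depth(self, label: str) -> int:
        """Number of branches between ``label`` and the root."""
        d = 0
        while label != self.root:
            label = self.parent[label]
            d += 1
        return d

    def ancestors(self, label: str) -> list[str]:
        """Proper ancestors of ``label``, nearest first, ending at the root."""
        out = []
        while label != self.root:
            label = self.parent[label]
            out.append(label)
        return out

    def is_ancestor(self, putative_ancestor: str, node: str) -> bool:
        """True iff ``putative_ancestor`` is a PROPER ancestor of ``node``."""
        return putative_ancestor in self.ancestors(node)

    def path_to(self, ancestor: str, descendant: str) -> list[str]:
        """Nodes strictly below ``ancestor`` down to ``descendant`` inclusive.

        Raises ``TreeError`` if ``descendant`` is not inside ``ancestor``'s
        clade.
        """
        if descendant == ancestor:
            return []
        path = [descendant]
        node = descendant
        while node != self.root:
            node = self.parent[node]
            if node == ancestor:
                return list(reversed(path))
            path.append(node)
        raise TreeError(f"{descendant!r} does not descend from {ancestor!r}")

    def clade_tips(self, label: str) -> set[str]:
        stack = [label]
        out: set[str] = set()
        while stack:
            node = stack.pop()
            kids = self.children[node]
            if not kids:
                out.add(node)
            stack.extend(kids)
        return out

    def validate_groups(self) -> None:
        """Check that identical group tags label monophyletic tip sets."""
        by_tag: dict[str, set[str]] = {}
        for label, tag in self.groups.items():
            by_tag.setdefault(tag, set()).update(
                self.clade_tips(label) if self.children[label] else {label}
            )
        for tag, tip_set in by_tag.items():
            mrca = self._mrca(tip_set)
            if self.clade_tips(mrca) != tip_set:
                raise TreeError(f"group {tag!r} is not monophyletic")

    def _mrca(self, labels: Iterable[str]) -> str:
        paths = [[lab] + self.ancestors(lab) for lab in labels]
        common = set(paths[0]).intersection(*map(set, paths[1:])) if len(paths) > 1 else set(paths[0])
        for node in paths[0]:
            if node in common:
                return node
        raise TreeError("no common ancestor (disconnected tree?)")


def parse_species_tree(newick_text: str, auto_label: bool = False) -> SpeciesTree:
    """Parse a rooted newick string into a :class:`SpeciesTree`.

    Internal nodes must carry labels unless ``auto_label`` is set, in which
    case unlabelled internal nodes are named ``N1``, ``N2``, ... in preorder.
    The root must be bifurcating (a trifurcating root denotes an unrooted
    tree and is rejected).
    """
    dtree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,
        preserve_underscores=True,
    )
    seed = dtree.seed_node
    if len(seed.child_nodes()) != 2:
        name = seed.label or "<root>"
        raise TreeError(
            f"root node {name!r} has {len(seed.child_nodes())} children; "
            "a rooted bifurcating tree is required"
        )

    counter = 0
    parent: dict[str, str] = {}
    children: dict[str, tuple[str, ...]] = {}
    lengths: dict[str, float] = {}

    def label_of(node: dendropy.Node) -> str:
        nonlocal counter
        if node.is_leaf():
            lab = node.taxon.label if node.taxon else node.label
        else:
            lab = node.label
        if lab is None or lab == "":
            if not auto_label:
                raise TreeError("unlabelled internal node (enable auto-labelling)")
            counter += 1
            lab = f"N{counter}"
            node.label = lab
        return lab

    seen: set[str] = set()
    dupes: set[str] = set()

    def walk(node: dendropy.Node) -> str:
        lab = label_of(node)
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
        kid_labels = []
        for kid in node.child_nodes():
            kl = walk(kid)
            parent[kl] = lab
            if kid.edge.length is not None:
                lengths[kl] = float(kid.edge.length)
            kid_labels.append(kl)
        children[lab] = tuple(kid_labels)
        return lab

    root = walk(seed)
    if dupes:
        raise TreeError(f"duplicate node labels: {sorted(dupes)}")
    return SpeciesTree(parent=parent, root=root, children=children, branch_lengths=lengths)


def write_newick(tree: SpeciesTree, include_lengths: bool = True) -> str:
    """Serialize to a newick string; inverse of :func:`parse_species_tree`."""

    def render(label: str) -> str:
        kids = tree.children[label]
        body = label if not kids else "(" + ",".join(render(k) for k in kids) + ")" + label
        if include_lengths and label in tree.branch_lengths:
            body += f":{tree.branch_lengths[label]:g}"
        return body

    return render(tree.root) + ";"
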