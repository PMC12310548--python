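"""Germline-rooted subclone lineage trees and their complexity metrics.

The tree is the minimum-spanning arborescence of the subclone sequences
(plus the germline) under Hamming distance, rooted at the germline by
default.  This is a deterministic, parsimony-flavored reconstruction that
supports the descriptive node taxonomy — root, leaves, split nodes (>1
child), pass-through nodes (exactly 1 child) — and the complexity metrics
(node counts, depth, total branch length) that track diversification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .clones import CloneProfile
from .io import GermlineReference

__all__ = [
    "LineageNode",
    "LineageTree",
    "TreeMetrics",
    "build_lineage_tree",
    "tree_metrics",
    "to_newick",
    "to_dot",
]


@dataclass
class LineageNode:
    node_id: str
    sequence: str
    role: str = ""  # root | leaf | split | pass_through | internal_observed
    abundance_pct: float = 0.0  # 0 for inferred/germline nodes
    observed: bool = True
    children: list[str] = field(default_factory=list)
    parent: Optional[str] = None


@dataclass
class LineageTree:
    root_id: str
    nodes: dict[str, LineageNode]

    def depth(self, node_id: str) -> int:
        d = 0
        node = self.nodes[node_id]
        while node.parent is not None:
            node = self.nodes[node.parent]
            d += 1
        return d


@dataclass
class TreeMetrics:
    n_nodes: int
    n_leaves: int
    n_split: int
    n_pass_through: int
    max_depth: int
    total_branch_length: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y and x != "N" and y != "N" for x, y in zip(a, b))


def build_lineage_tree(profile: CloneProfile,
                       germline: GermlineReference,
                       root: str = "germline",
                       subdivide_edges: bool = False,
                       observed_internal_role: bool = False) -> LineageTree:
    """Deterministic Hamming-distance minimum-spanning arborescence.

    Nodes are the subclone sequences (trimmed to the germline window) plus
    the germline when ``root="germline"``; with ``root="major"`` the tree
    is rooted at the major subclone instead.  Prim's construction with ties
    broken by (distance, attachment order of the parent, child abundance
    descending, child sequence) makes the result reproducible.  With
    ``subdivide_edges`` every edge longer than 1 nt gains inferred
    intermediate nodes carrying one mutation each (abundance 0).  One-child
    observed nodes get role "internal_observed" instead of "pass_through"
    when ``observed_internal_role`` is set.
    """
    window = len(germline.sequence)
    entries = []  # (sequence, abundance_pct, observed)
    if root == "germline":
        entries.append((germline.sequence, 0.0, False))
    elif root != "major":
        raise ValueError(f"unknown root policy {root!r}")
    seen = {e[0] for e in entries}
    for sub in sorted(profile.subclones, key=lambda s: (-s.frequency, s.sequence)):
        seq = sub.sequence[:window]
        if len(seq) != window:
            raise ValueError("subclone sequence shorter than the germline window")
        if seq in seen:  # germline identical to a subclone: keep abundance
            entries = [(s, sub.frequency * 100.0 if s == seq else a, obs or s == seq)
                       for s, a, obs in entries]
            continue
        seen.add(seq)
        entries.append((seq, sub.frequency * 100.0, True))

    # Prim from the root with deterministic tie-breaks
    nodes: dict[str, LineageNode] = {}
    order: list[str] = []  # attachment order, used for parent tie-break

    def add_node(seq, abundance, observed, parent_id):
        node_id = f"n{len(nodes)}"
        nodes[node_id] = LineageNode(node_id=node_id, sequence=seq,
                                     abundance_pct=abundance, observed=observed,
                                     parent=parent_id)
        if parent_id is not None:
            nodes[parent_id].children.append(node_id)
        order.append(node_id)
        return node_id

    root_seq, root_ab, root_obs = entries[0]
    root_id = add_node(root_seq, root_ab, root_obs, None)
    remaining = entries[1:]
    while remaining:
        best = None
        for seq, ab, obs in remaining:
            for rank, parent_id in enumerate(order):
                d = _hamming(seq, nodes[parent_id].sequence)
                key = (d, rank, -ab, seq)
                if best is None or key < best[0]:
                    best = (key, seq, ab, obs, parent_id)
        _, seq, ab, obs, parent_id = best
        add_node(seq, ab, obs, parent_id)
        remaining = [e for e in remaining if e[0] != seq]

    tree = LineageTree(root_id=root_id, nodes=nodes)
    if subdivide_edges:
        _subdivide(tree)
    assign_roles(tree, observed_internal_role=observed_internal_role)
    return tree


def _subdivide(tree: LineageTree) -> None:
    """Insert inferred one-mutation intermediates along edges longer than 1."""
    for child_id in list(tree.nodes):
        child = tree.nodes[child_id]
        if child.parent is None:
            continue
        parent = tree.nodes[child.parent]
        diffs = [i for i, (a, b) in enumerate(zip(parent.sequence, child.sequence))
                 if a != b and a != "N" and b != "N"]
        if len(diffs) <= 1:
            continue
        parent.children.remove(child_id)
        current, seq = parent, list(parent.sequence)
        for pos in diffs[:-1]:
            seq[pos] = child.sequence[pos]
            node_id = f"i{len(tree.nodes)}"
            node = LineageNode(node_id=node_id, sequence="".join(seq),
                               observed=False, parent=current.node_id)
            tree.nodes[node_id] = node
            current.children.append(node_id)
            current = node
        child.parent = current.node_id
        current.children.append(child_id)


def assign_roles(tree: LineageTree, observed_internal_role: bool = False) -> None:
    """(Re)derive node roles from the child lists."""
    for node in tree.nodes.values():
        if node.node_id == tree.root_id:
            node.role = "root"
        elif not node.children:
            node.role = "leaf"
        elif len(node.children) >= 2:
            node.role = "split"
        elif observed_internal_role and node.observed:
            node.role = "internal_observed"
        else:
            node.role = "pass_through"


def tree_metrics(tree: LineageTree) -> TreeMetrics:
    """Counts, depth and summed nucleotide branch length of a lineage tree."""
    n_leaves = n_split = n_pass = 0
    total_branch = 0
    max_depth = 0
    for node in tree.nodes.values():
        if node.node_id != tree.root_id:
            if not node.children:
                n_leaves += 1
            elif len(node.children) >= 2:
                n_split += 1
            else:
                n_pass += 1
            total_branch += _hamming(node.sequence,
                                     tree.nodes[node.parent].sequence)
            max_depth = max(max_depth, tree.depth(node.node_id))
    return TreeMetrics(n_nodes=len(tree.nodes), n_leaves=n_leaves,
                       n_split=n_split, n_pass_through=n_pass,
                       max_depth=max_depth, total_branch_length=total_branch)


# ---------------------------------------------------------------------------
# export


def to_newick(tree: LineageTree) -> str:
    """Newick string with role and abundance carried as node comments."""

    def render(node_id: str) -> str:
        node = tree.nodes[node_id]
        label = (f"{node.node_id}[&&NHX:role={node.role}:"
                 f"abundance={node.abundance_pct:.4f}]")
        if not node.children:
            return label
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){label}"

    return render(tree.root_id) + ";"


def to_dot(tree: LineageTree) -> str:
    """Graphviz DOT rendering of the arborescence."""
    lines = ["digraph lineage {"]
    for node in tree.nodes.values():
        lines.append(
            f'  {node.node_id} [label="{node.role}\\n{node.abundance_pct:.2f}%"];')
        for child in node.children:
            d = _hamming(node.sequence, tree.nodes[child].sequence)
            lines.append(f'  {node.node_id} -> {child} [label="{d}"];')
    lines.append("}")
    return "\n".join(lines)
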