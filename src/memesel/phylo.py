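"""Phylogeny container with a deterministic, branch-indexed layout.

Trees are read from Newick (via dendropy) into a flat array-based
structure: nodes are stored in post-order with children sorted by name, so
branch indices — and therefore every per-branch quantity downstream
(mixture weights, posteriors, simulation truth records) — are stable
across runs and machines. Every non-root node owns the branch to its
parent; a tree with N nodes has N - 1 branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be turned into a valid tree."""


@dataclass
class Branch:
    """The edge from ``child`` up to ``parent``; named after its child node."""

    id: int
    name: str
    child: int
    parent: int
    length: float | None


@dataclass
class Phylogeny:
    names: list[str]
    parent: list[int]          # -1 for the root
    children: list[list[int]]  # sorted per the deterministic order
    postorder: list[int]       # root last
    is_leaf: list[bool]
    branches: list[Branch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.branches:
            order = [v for v in self.postorder if self.parent[v] >= 0]
            self.branches = [
                Branch(id=i, name=self.names[v], child=v,
                       parent=self.parent[v], length=None)
                for i, v in enumerate(order)
            ]
        self._branch_of_child = {b.child: b for b in self.branches}

    # ---- basic accessors ----------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[v] for v in range(self.n_nodes) if self.is_leaf[v]]

    def branch_of_child(self, node: int) -> Branch:
        return self._branch_of_child[node]

    def branch_lengths(self) -> list[float | None]:
        return [b.length for b in self.branches]

    def has_all_lengths(self) -> bool:
        return all(b.length is not None for b in self.branches)

    def with_branch_lengths(self, lengths) -> "Phylogeny":
        """Copy of the tree with branch lengths replaced (array by branch id)."""
        tree = Phylogeny(
            names=list(self.names),
            parent=list(self.parent),
            children=[list(c) for c in self.children],
            postorder=list(self.postorder),
            is_leaf=list(self.is_leaf),
            branches=[
                Branch(b.id, b.name, b.child, b.parent, float(lengths[b.id]))
                for b in self.branches
            ],
        )
        for b in tree.branches:
            if b.length < 0:
                raise ValueError(f"negative branch length on {b.name!r}")
        return tree

    # ---- newick io -----------------------------------------------------

    def to_newick(self, digits: int = 6) -> str:
        def fmt(v: int) -> str:
            if self.is_leaf[v]:
                label = _quote_if_needed(self.names[v])
            else:
                label = ""
                kids = ",".join(fmt(c) for c in self.children[v])
                label = f"({kids})" + (
                    _quote_if_needed(self.names[v])
                    if not self.names[v].startswith("Node") else ""
                )
            if self.parent[v] >= 0:
                length = self.branch_of_child(v).length
                if length is not None:
                    label += f":{length:.{digits}g}"
            return label

        return fmt(self.root) + ";"


def _quote_if_needed(name: str) -> str:
    if any(ch in name for ch in "(),:;[] \t'\""):
        return "'" + name.replace("'", "''") + "'"
    return name


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Polytomies and missing branch lengths are allowed; duplicate or empty
    leaf names and negative lengths are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    if len(dnodes) < 2:
        raise NewickParseError("tree must contain at least one branch")

    index = {id(nd): i for i, nd in enumerate(dnodes)}
    names: list[str | None] = [None] * len(dnodes)
    is_leaf = [nd.is_leaf() for nd in dnodes]
    parent = [-1] * len(dnodes)
    raw_children: list[list[int]] = [[] for _ in dnodes]
    lengths: list[float | None] = [None] * len(dnodes)

    seen: set[str] = set()
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            raw_children[parent[i]].append(i)
            if nd.edge.length is not None:
                if nd.edge.length < 0:
                    raise NewickParseError(
                        f"negative branch length {nd.edge.length} "
                        f"on {nd.taxon.label if nd.taxon else 'internal node'}"
                    )
                lengths[i] = float(nd.edge.length)
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else None
            if not label:
                raise NewickParseError("leaf with empty name")
            if label in seen:
                raise NewickParseError(f"duplicate leaf name {label!r}")
            seen.add(label)
            names[i] = label
        elif nd.label:
            names[i] = str(nd.label)

    # Deterministic child ordering: sort by node name, where unlabeled
    # internal nodes inherit the smallest leaf name in their clade.
    sort_key: list[str] = [""] * len(dnodes)

    def fill_keys(v: int) -> str:
        if is_leaf[v]:
            sort_key[v] = names[v]
        else:
            keys = sorted(fill_keys(c) for c in raw_children[v])
            sort_key[v] = names[v] if names[v] else keys[0]
        return sort_key[v]

    root_old = index[id(dnodes[0])]
    fill_keys(root_old)

    # Re-number nodes in deterministic post-order.
    old_postorder: list[int] = []

    def walk(v: int) -> None:
        for c in sorted(raw_children[v], key=lambda x: sort_key[x]):
            walk(c)
        old_postorder.append(v)

    walk(root_old)
    new_of_old = {old: new for new, old in enumerate(old_postorder)}

    n = len(dnodes)
    out_names = [""] * n
    out_parent = [-1] * n
    out_children: list[list[int]] = [[] for _ in range(n)]
    out_leaf = [False] * n
    n_internal = 0
    for old, new in new_of_old.items():
        out_leaf[new] = is_leaf[old]
        if names[old]:
            out_names[new] = names[old]
        if out_parent is not None and parent[old] >= 0:
            out_parent[new] = new_of_old[parent[old]]
    for old in old_postorder:
        new = new_of_old[old]
        if not is_leaf[old] and not names[old]:
            out_names[new] = f"Node{n_internal}"
        if not is_leaf[old]:
            n_internal += 1
        out_children[new] = sorted(
            (new_of_old[c] for c in raw_children[old]),
            key=lambda x: sort_key[old_postorder[x]],
        )

    tree = Phylogeny(
        names=out_names,
        parent=out_parent,
        children=out_children,
        postorder=list(range(n)),
        is_leaf=out_leaf,
    )
    for b in tree.branches:
        b.length = lengths[old_postorder[b.child]]
    return tree


@dataclass
class TreeAlignmentReport:
    missing_in_alignment: list[str]
    missing_in_tree: list[str]

    @property
    def ok(self) -> bool:
        return not self.missing_in_alignment and not self.missing_in_tree


def validate_tree_alignment(tree: Phylogeny, alignment) -> TreeAlignmentReport:
    """Check that tree leaves and alignment sequence names match exactly.

    Matching is case-sensitive; fuzzy matching would hide data errors.
    """
    leaves = set(tree.leaf_names)
    seqs = set(alignment.names)
    return TreeAlignmentReport(
        missing_in_alignment=sorted(leaves - seqs),
        missing_in_tree=sorted(seqs - leaves),
    )
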