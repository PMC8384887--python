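"""Labeled phylogenies for branch- and clade-partitioned codon models.

Branch groups follow the codeml labeling convention: a ``#name`` suffix
on a taxon or internal-node label assigns that single branch to group
``name``; a ``$name`` suffix assigns the branch and every branch of the
subtree below it.  Unlabeled branches belong to the ``background`` group
(id 0).  Groups can also be supplied programmatically with
:meth:`LabeledTree.label_clade` or a taxon->group mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

BACKGROUND = "background"


@dataclass
class LabeledTree:
    """Array-backed rooted tree with per-branch group labels.

    Nodes are indexed 0..n_nodes-1 with tips first (in ``taxa`` order);
    ``parent[i]`` is -1 for the root.  ``group[i]`` labels the branch
    above node i (the root entry is ignored).
    """

    taxa: list[str]
    parent: np.ndarray
    blen: np.ndarray
    children: list[list[int]]
    group: np.ndarray
    group_names: list[str]
    _postorder: list[int] = field(init=False, repr=False)

    def __post_init__(self):
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        self._postorder = [n for n in reversed(order) if self.children[n]]

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def postorder_internal(self) -> list[int]:
        """Internal nodes, children-before-parents."""
        return self._postorder

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def group_id(self, name: str) -> int:
        return self.group_names.index(name)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str | None = None, path=None) -> "LabeledTree":
        if (newick is None) == (path is None):
            raise ValueError("supply exactly one of newick or path")
        src = {"data": newick} if newick else {"path": str(path)}
        tree = dendropy.Tree.get(
            schema="newick", suppress_internal_node_taxa=True, **src
        )
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "LabeledTree":
        nodes = list(tree.preorder_node_iter())
        tips = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]

        def raw_label(node):
            if node.taxon is not None:
                return node.taxon.label or ""
            return node.label or ""

        group_names = [BACKGROUND]
        taxa = []
        tip_groups = []  # (marker, name) or None
        for n in tips:
            name, marker = _split_label(raw_label(n))
            if not name:
                raise ValueError("tip without a label")
            taxa.append(name)
            tip_groups.append(marker)
        internal_groups = [_split_label(raw_label(n))[1] for n in internals]

        index = {id(n): i for i, n in enumerate(tips)}
        for i, n in enumerate(internals):
            index[id(n)] = len(tips) + i

        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.intp)
        blen = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        group = np.zeros(n_nodes, dtype=np.intp)

        def name_to_id(name: str) -> int:
            if name not in group_names:
                group_names.append(name)
            return group_names.index(name)

        # resolve structure
        for n in nodes:
            i = index[id(n)]
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                children[parent[i]].append(i)
            blen[i] = n.edge.length if n.edge.length is not None else 0.0

        # branch labels: '$' marks propagate to the whole subtree
        markers = {}
        for n, marker in zip(tips, [g for g in tip_groups]):
            if marker:
                markers[index[id(n)]] = marker
        for n, marker in zip(internals, internal_groups):
            if marker:
                markers[index[id(n)]] = marker

        def assign_subtree(node_idx, gid):
            group[node_idx] = gid
            for c in children[node_idx]:
                assign_subtree(c, gid)

        def depth(node_idx):
            d = 0
            while parent[node_idx] != -1:
                node_idx = parent[node_idx]
                d += 1
            return d

        # whole-clade markers first (outermost first) so single-branch
        # markers inside a labeled clade still win
        clade_marks = sorted(
            (i for i, (k, _) in markers.items() if k == "$"), key=depth
        )
        for node_idx in clade_marks:
            assign_subtree(node_idx, name_to_id(markers[node_idx][1]))
        for node_idx, (kind, name) in markers.items():
            if kind == "#":
                group[node_idx] = name_to_id(name)

        return cls(taxa, parent, blen, children, group, group_names)

    # ------------------------------------------------------------------
    # labeling helpers
    # ------------------------------------------------------------------
    def label_clade(
        self, taxa: list[str], name: str, include_stem: bool = True
    ) -> "LabeledTree":
        """Assign the MRCA subtree of ``taxa`` to group ``name`` (new tree)."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        tip_ids = {self.taxa.index(t) for t in taxa}
        # MRCA: intersect root paths
        paths = []
        for t in tip_ids:
            path = []
            node = t
            while node != -1:
                path.append(node)
                node = self.parent[node]
            paths.append(path)
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        mrca = paths[0][min(i for i, n in enumerate(paths[0]) if n in common)]

        group = self.group.copy()
        names = list(self.group_names)
        if name not in names:
            names.append(name)
        gid = names.index(name)

        stack = list(self.children[mrca])
        while stack:
            n = stack.pop()
            group[n] = gid
            stack.extend(self.children[n])
        if include_stem:
            group[mrca] = gid
        return LabeledTree(
            list(self.taxa), self.parent.copy(), self.blen.copy(),
            [list(c) for c in self.children], group, names,
        )

    def label_taxa(self, mapping: dict[str, str]) -> "LabeledTree":
        """Assign terminal branches to groups via a taxon->group map."""
        group = self.group.copy()
        names = list(self.group_names)
        for taxon, name in mapping.items():
            if taxon not in self.taxa:
                raise KeyError(f"taxon not in tree: {taxon}")
            if name not in names:
                names.append(name)
            group[self.taxa.index(taxon)] = names.index(name)
        return LabeledTree(
            list(self.taxa), self.parent.copy(), self.blen.copy(),
            [list(c) for c in self.children], group, names,
        )

    def with_free_branch_groups(self) -> "LabeledTree":
        """One group per branch (free-ratios parameterization)."""
        group = np.zeros(self.n_nodes, dtype=np.intp)
        names = []
        root = self.root
        g = 0
        for n in range(self.n_nodes):
            if n == root:
                continue
            names.append(self.branch_name(n))
            group[n] = g
            g += 1
        return LabeledTree(
            list(self.taxa), self.parent.copy(), self.blen.copy(),
            [list(c) for c in self.children], group, names,
        )

    def branch_name(self, node: int) -> str:
        if node < self.n_tips:
            return self.taxa[node]
        return f"node{node}"

    def to_newick(self) -> str:
        def render(node):
            gid = self.group[node]
            tag = (
                f"#{self.group_names[gid]}"
                if gid != 0 and node != self.root
                else ""
            )
            if not self.children[node]:
                return f"{self.taxa[node]}{tag}:{self.blen[node]:g}"
            inner = ",".join(render(c) for c in self.children[node])
            if node == self.root:
                return f"({inner});"
            return f"({inner}){tag}:{self.blen[node]:g}"

        return render(self.root)


def _split_label(label: str) -> tuple[str, tuple[str, str] | None]:
    """Split 'taxon#grp' / 'taxon$grp' into (taxon, (marker, group))."""
    label = (label or "").strip()
    for marker in ("#", "$"):
        if marker in label:
            name, grp = label.split(marker, 1)
            grp = grp.strip() or "1"
            return name.strip(), (marker, grp)
    return label, None
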