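"""Rooted phylogenies: newick I/O, pruning, MRCA lookup, postorder indexing.

The tree container wraps a :class:`dendropy.Tree` and exposes flat postorder
arrays (children, parent, edge length, tip label per node) that the parsimony,
Mk-likelihood and Brownian-motion engines traverse directly.  Nodes are
addressed by postorder index; hypothesis nodes are always specified as the
MRCA of a taxon set, never by a bare integer, so analyses are robust to
re-indexing when taxa are added or pruned.

Trees may lack branch lengths (legal for parsimony).  Operations that need
lengths raise :class:`MissingBranchLengthError` rather than silently assuming
unit lengths; ``assign_unit_lengths`` makes the assumption explicit.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "TreeError",
    "MissingBranchLengthError",
    "parse_newick",
]


class TreeError(ValueError):
    """Invalid tree structure or invalid query against a tree."""


class NewickParseError(TreeError):
    """Malformed newick input (unbalanced parentheses, duplicates, empty)."""


class MissingBranchLengthError(TreeError):
    """An operation that requires branch lengths met a tree without them."""


class PhyloTree:
    """A rooted phylogeny with optional branch lengths and polytomy support.

    Parameters
    ----------
    dtree:
        A rooted :class:`dendropy.Tree`.  The tree is not copied; treat the
        wrapper as owning it.

    Attributes
    ----------
    n_nodes : int
        Total node count (tips + internal).  Node ids are postorder indices,
        so every child id is smaller than its parent's and ``root_id ==
        n_nodes - 1``.
    children : list[list[int]]
        Child ids per node (empty for tips).
    parent : list[int | None]
        Parent id per node (``None`` for the root).
    edge_length : list[float | None]
        Length of the edge above each node; ``None`` when absent in the
        source newick (absent is distinct from zero).
    tip_label : list[str | None]
        Taxon label for tips, ``None`` for internal nodes.
    """

    def __init__(self, dtree: dendropy.Tree):
        if dtree.seed_node is None:
            raise TreeError("empty tree")
        self._dtree = dtree
        self._index()

    # ------------------------------------------------------------------
    # construction / serialization
    # ------------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a single rooted newick statement.

        Quoted labels are honoured; underscores are kept verbatim (not
        translated to spaces).  Raises :class:`NewickParseError` on malformed
        input, naming the offending position where the parser reports one,
        and on duplicate or empty tip labels.
        """
        if not text or not text.strip():
            raise NewickParseError("empty newick input")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"malformed newick: {exc}") from exc
        tree = cls(dtree)
        labels = tree.tip_labels
        if any(lbl is None or lbl == "" for lbl in labels):
            raise NewickParseError("tip with empty label")
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        return tree

    def write_newick(self) -> str:
        """Serialize to a single-line newick string ending in ';'."""
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s

    # ------------------------------------------------------------------
    # indexing
    # ------------------------------------------------------------------

    def _index(self) -> None:
        nodes = list(self._dtree.postorder_node_iter())
        self._nodes = nodes
        self._id_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[list[int]] = [
            [self._id_of[id(ch)] for ch in nd.child_nodes()] for nd in nodes
        ]
        self.parent: list[int | None] = [
            self._id_of[id(nd.parent_node)] if nd.parent_node is not None else None
            for nd in nodes
        ]
        self.edge_length: list[float | None] = [nd.edge.length for nd in nodes]
        self.tip_label: list[str | None] = [
            (nd.taxon.label if nd.taxon is not None else None) if nd.is_leaf() else None
            for nd in nodes
        ]
        # a leaf may carry its label on the node rather than a taxon
        for i, nd in enumerate(nodes):
            if nd.is_leaf() and self.tip_label[i] is None:
                self.tip_label[i] = nd.label

    @property
    def root_id(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.tip_label[i] for i in self.tip_ids]

    @property
    def internal_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def is_tip(self, node_id: int) -> bool:
        return not self.children[node_id]

    @property
    def has_branch_lengths(self) -> bool:
        """True when every non-root node carries a length."""
        return all(
            self.edge_length[i] is not None for i in range(self.n_nodes - 1)
        )

    def require_branch_lengths(self, what: str = "this operation") -> None:
        if not self.has_branch_lengths:
            raise MissingBranchLengthError(
                f"{what} requires branch lengths on every edge; the tree has "
                "edges without lengths. Use assign_unit_lengths() to make the "
                "unit-length assumption explicit, or supply a calibrated tree."
            )

    def assign_unit_lengths(self) -> "PhyloTree":
        """Return a copy with every edge length set to 1."""
        clone = dendropy.Tree(self._dtree)
        for nd in clone:
            if nd.parent_node is not None:
                nd.edge.length = 1.0
        return PhyloTree(clone)

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------

    def _check_taxa(self, taxa: Iterable[str]) -> set[str]:
        taxa = set(taxa)
        missing = sorted(taxa - set(self.tip_labels))
        if missing:
            raise TreeError(f"taxa not found in tree: {missing}")
        return taxa

    def mrca(self, taxa: Iterable[str]) -> int:
        """Postorder id of the most recent common ancestor of ``taxa``."""
        taxa = self._check_taxa(taxa)
        if len(taxa) < 2:
            raise TreeError("mrca requires at least 2 taxa")
        # deepest node whose subtree covers all requested tips
        need = len(taxa)
        count = [0] * self.n_nodes
        for i in self.tip_ids:
            if self.tip_label[i] in taxa:
                count[i] = 1
        for i in range(self.n_nodes):
            for c in self.children[i]:
                count[i] += count[c]
            if count[i] == need:
                return i
        raise TreeError("mrca not found (tree inconsistent)")  # pragma: no cover

    def subtree_taxa(self, node_id: int) -> frozenset[str]:
        """Tip labels below (and including) ``node_id``."""
        stack, out = [node_id], []
        while stack:
            i = stack.pop()
            if self.is_tip(i):
                out.append(self.tip_label[i])
            else:
                stack.extend(self.children[i])
        return frozenset(out)

    def node_depths(self) -> list[float]:
        """Distance from the root to every node (requires branch lengths)."""
        self.require_branch_lengths("node depth computation")
        depth = [0.0] * self.n_nodes
        # preorder = reversed postorder; root (last) stays at depth 0
        for i in reversed(range(self.n_nodes - 1)):
            depth[i] = depth[self.parent[i]] + self.edge_length[i]
        return depth

    def tip_distance_matrix(self) -> tuple[list[str], "list[list[float]]"]:
        """Pairwise patristic distances between tips (requires lengths)."""
        self.require_branch_lengths("patristic distances")
        depth = self.node_depths()
        anc: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i in reversed(range(self.n_nodes)):
            anc[i].add(i)
            if self.parent[i] is not None:
                anc[i] |= anc[self.parent[i]]
        tips = self.tip_ids
        labels = [self.tip_label[i] for i in tips]
        dist = [[0.0] * len(tips) for _ in tips]
        for a_i, a in enumerate(tips):
            for b_i in range(a_i + 1, len(tips)):
                b = tips[b_i]
                m = max(anc[a] & anc[b], key=depth.__getitem__)
                d = depth[a] + depth[b] - 2.0 * depth[m]
                dist[a_i][b_i] = dist[b_i][a_i] = d
        return labels, dist

    # ------------------------------------------------------------------
    # pruning
    # ------------------------------------------------------------------

    def prune_to_taxa(self, taxa: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to ``taxa``.

        Degree-2 internal nodes created by the pruning are suppressed with
        their incident branch lengths summed, so pairwise path lengths among
        retained tips are conserved.
        """
        taxa = self._check_taxa(taxa)
        if len(taxa) < 2:
            raise TreeError("prune_to_taxa requires at least 2 retained taxa")
        clone = self._dtree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(taxa))
        clone.purge_taxon_namespace()
        return PhyloTree(clone)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._dtree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self.tip_ids)} tips, {self.n_nodes} nodes>"


def parse_newick(text: str) -> PhyloTree:
    """Functional alias for :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(text)


def load_tree(path: str) -> PhyloTree:
    """Read a newick file (.nwk/.tre), ignoring comment lines starting '#'."""
    with open(path) as fh:
        text = "".join(line for line in fh if not line.lstrip().startswith("#"))
    return PhyloTree.from_newick(text)
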