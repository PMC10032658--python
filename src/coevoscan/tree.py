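"""Rooted phylogeny container shared by all modules.

A :class:`Phylogeny` is a lightweight array-backed rooted tree with branch
lengths.  Newick parsing, writing and pruning delegate to :mod:`dendropy`;
the array form (parent pointers + per-node branch lengths) is what the
numerical routines (Brownian covariance, independent contrasts, trait
simulation) traverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths.

    Nodes are indexed 0..n-1 in preorder (root first).  ``parent[i]`` is the
    index of node i's parent (-1 for the root) and ``lengths[i]`` the length
    of the branch above node i (0 for the root).  ``labels[i]`` is the taxon
    label for leaves and ``None`` for internal nodes.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list
    children: list = field(default_factory=list)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = len(self.parent)
        if len(self.lengths) != n or len(self.labels) != n:
            raise ValueError("parent, lengths and labels must have equal length")
        if (self.lengths < 0).any():
            raise ValueError("branch lengths must be non-negative")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("exactly one root required, at index 0")
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i in range(1, n):
                self.children[self.parent[i]].append(i)
        leaf_labels = [self.labels[i] for i in self.leaf_indices()]
        if any(lab is None for lab in leaf_labels):
            raise ValueError("every leaf must carry a label")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise ValueError("leaf labels must be unique")

    # -- structure -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def leaf_indices(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> list:
        return [self.labels[i] for i in self.leaf_indices()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices())

    def postorder(self) -> list:
        """Node indices, children always before their parent."""
        order, stack = [], [0]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):  # preorder: parent precedes child
            d[i] = d[self.parent[i]] + self.lengths[i]
        return d

    def total_branch_length(self) -> float:
        return float(self.lengths[1:].sum())

    def edges(self) -> list:
        """(parent, child) pairs, one per branch, in preorder of the child."""
        return [(int(self.parent[i]), i) for i in range(1, self.n_nodes)]

    # -- conversion ----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        root = dtree.seed_node
        nodes = []
        stack = [root]
        while stack:  # preorder
            nd = stack.pop()
            nodes.append(nd)
            stack.extend(reversed(nd.child_nodes()))
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.array(
            [-1 if nd is root else index[id(nd.parent_node)] for nd in nodes]
        )
        lengths = np.array(
            [0.0 if nd is root else float(nd.edge.length or 0.0) for nd in nodes]
        )
        labels = [
            (nd.taxon.label if nd.taxon is not None else nd.label) for nd in nodes
        ]
        return cls(parent=parent, lengths=lengths, labels=labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        dtree.seed_node = dnodes[0]
        for i in range(1, self.n_nodes):
            dnodes[self.parent[i]].add_child(dnodes[i])
            dnodes[i].edge.length = float(self.lengths[i])
        for i in self.leaf_indices():
            dnodes[i].taxon = taxa.new_taxon(self.labels[i])
        return dtree

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"newick parse error: {exc}") from exc
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                body = self.labels[i]
            else:
                body = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if i == 0:
                return body
            return f"{body}:{self.lengths[i]:.10g}"

        return render(0) + ";"

    # -- operations ----------------------------------------------------

    def prune_to(self, species) -> "Phylogeny":
        """Subtree induced by ``species``; unary nodes are collapsed so
        leaf-to-leaf path lengths are preserved."""
        species = set(species)
        missing = species - set(self.leaf_labels)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        dtree = self.to_dendropy()
        dtree.retain_taxa_with_labels(sorted(species))
        # collapse the root if it became unary: keeps leaf-leaf distances
        while len(dtree.seed_node.child_nodes()) == 1:
            child = dtree.seed_node.child_nodes()[0]
            dtree.seed_node = child
            child.parent_node = None
        return Phylogeny.from_dendropy(dtree)

    def leaf_index_map(self) -> dict:
        return {self.labels[i]: i for i in self.leaf_indices()}
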