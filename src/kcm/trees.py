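"""Phylogeny container and Newick I/O.

Parsing and serialisation are delegated to dendropy; internally the tree is
flattened into parent/children index arrays with leaves first, which is what
the pruning engine and the branch-length optimiser operate on.  Under the
time-reversible generators built by this package the likelihood does not
depend on root placement, so unrooted (basal-trifurcation) inputs are used
as-is with the trifurcation acting as the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    """Malformed Newick or tree/alignment mismatch."""


@dataclass
class Phylogeny:
    """A (multifurcating) rooted tree flattened to index arrays.

    Nodes ``0 .. n_taxa-1`` are the leaves in ``taxon_labels`` order;
    internal nodes follow in postorder, the root last.  ``lengths[i]`` is
    the branch length above node ``i`` (0 for the root); ``parent[i]`` is
    the parent index (-1 for the root).
    """

    taxon_labels: list
    parent: np.ndarray
    lengths: np.ndarray
    children: list = field(repr=False, default=None)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise TreeError("negative branch length")
        if self.children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self.children = ch

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def postorder_internal(self):
        """Internal node indices, children-before-parent."""
        return range(self.n_taxa, self.n_nodes)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate taxon labels in tree")
        index = {id(lf): i for i, lf in enumerate(leaves)}
        order = []  # internal nodes in postorder
        for nd in tree.postorder_node_iter():
            if not nd.is_leaf():
                index[id(nd)] = len(leaves) + len(order)
                order.append(nd)
        n = len(leaves) + len(order)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(taxon_labels=labels, parent=parent, lengths=lengths)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    # -- serialisation ----------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                label = self.taxon_labels[i]
                quoted = f"'{label}'" if any(c in label for c in " (),:;") else label
                return f"{quoted}:{self.lengths[i]:.{precision}g}"
            inner = ",".join(render(c) for c in self.children[i])
            if self.parent[i] < 0:
                return f"({inner});"
            return f"({inner}):{self.lengths[i]:.{precision}g}"
        return render(self.root)

    def copy(self) -> "Phylogeny":
        return Phylogeny(taxon_labels=list(self.taxon_labels),
                         parent=self.parent.copy(),
                         lengths=self.lengths.copy())

    def leaf_order(self, taxa) -> np.ndarray:
        """Map an external taxa list onto leaf indices; error on mismatch."""
        pos = {t: i for i, t in enumerate(self.taxon_labels)}
        missing = [t for t in taxa if t not in pos]
        extra = [t for t in self.taxon_labels if t not in set(taxa)]
        if missing or extra:
            raise TreeError(
                f"tree/alignment taxa mismatch: absent from tree {missing}, "
                f"absent from alignment {extra}")
        return np.array([pos[t] for t in taxa], dtype=np.int64)


def read_tree(path) -> Phylogeny:
    """Read a Newick tree file (branch lengths required for fixed-tree fits)."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeError(f"empty tree file: {path}")
    return Phylogeny.from_newick(text)


def write_tree(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
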