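"""Alignment and tree input/output.

Alignments are gapped amino-acid FASTA files; trees are Newick with branch
lengths (read and written through dendropy).  The :class:`Alignment` holds
the integer-encoded character matrix used by the likelihood machinery, and
:func:`alignment_summary` computes the usual descriptive statistics of an
aligned dataset (taxa, columns, residues, gaps, mean ungapped length, mean
pairwise identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO

from .alphabet import GAP_CODE, decode, encode


class AlignmentError(ValueError):
    """Ragged rows, duplicate ids, or empty input."""


@dataclass
class Alignment:
    """A gapped amino-acid alignment.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, one per row.
    matrix : (n_taxa, n_columns) int8 array
        Residue codes in alphabet order; gaps are -1 and are treated as
        missing data by the likelihood machinery.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentError("one id required per row")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise AlignmentError(f"duplicate sequence ids: {sorted(dupes)}")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        """Number of alignment columns (the N of the BIC penalty)."""
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(seq_id)]

    def sequence(self, seq_id: str) -> str:
        return decode(self.row(seq_id))

    def ungapped_lengths(self) -> np.ndarray:
        """Per-sequence ungapped length N_i."""
        return (self.matrix != GAP_CODE).sum(axis=1)

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        rows = [self.ids.index(i) for i in keep_ids]
        return Alignment(list(keep_ids), self.matrix[rows].copy())

    @classmethod
    def from_sequences(cls, ids: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if not seqs:
            raise AlignmentError("empty alignment")
        return cls(list(ids), np.vstack([encode(s) for s in seqs]))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.matrix):
                fh.write(f">{sid}\n{decode(row)}\n")


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    if format != "fasta":
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:  # Biopython raises on ragged input
        raise AlignmentError(str(exc)) from exc
    return Alignment.from_sequences([rec.id for rec in msa],
                                    [str(rec.seq) for rec in msa])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    aln.to_fasta(path)


def alignment_summary(aln: Alignment) -> dict[str, float]:
    """Descriptive statistics of an alignment.

    ``mean_pairwise_identity`` averages, over all unordered sequence pairs,
    the fraction of identical residues among columns where neither sequence
    is gapped; pairs with no mutually ungapped column contribute 0.
    """
    if aln.n_taxa == 0 or aln.n_columns == 0:
        raise AlignmentError("empty alignment")
    present = aln.matrix != GAP_CODE
    total_residues = int(present.sum())
    total_gaps = aln.n_taxa * aln.n_columns - total_residues
    identities = []
    for i, j in combinations(range(aln.n_taxa), 2):
        both = present[i] & present[j]
        n_both = int(both.sum())
        if n_both == 0:
            identities.append(0.0)
        else:
            same = int((aln.matrix[i][both] == aln.matrix[j][both]).sum())
            identities.append(same / n_both)
    return {
        "n_taxa": aln.n_taxa,
        "n_columns": aln.n_columns,
        "total_residues": total_residues,
        "total_gaps": total_gaps,
        "mean_ungapped_length": float(aln.ungapped_lengths().mean()),
        "mean_pairwise_identity": float(np.mean(identities)) if identities else 1.0,
    }


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeError(ValueError):
    """Malformed Newick or invalid branch lengths."""


@dataclass
class PhyloTree:
    """A rooted tree over labelled leaves with branch lengths.

    Nodes are indexed 0..n_nodes-1 in a postorder consistent ordering
    (children before parents, root last).  ``branch_lengths[i]`` is the
    length of the edge above node i, in expected substitutions per site
    (NaN for the root).  Leaves carry labels; internal nodes may carry an
    optional label used as an annotation slot on output.
    """

    children: list[list[int]]
    parent: np.ndarray
    branch_lengths: np.ndarray
    labels: list[str | None]
    is_leaf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        bl = self.branch_lengths[~np.isnan(self.branch_lengths)]
        if (bl < 0).any():
            raise TreeError("negative branch length")

    # -- structure -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_leaf[i]]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def node_by_label(self, label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab == label:
                return i
        raise KeyError(f"no node labelled {label!r}")

    def leaf_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in range(self.n_nodes) if self.is_leaf[i]}

    def copy(self) -> "PhyloTree":
        return PhyloTree([list(c) for c in self.children], self.parent.copy(),
                         self.branch_lengths.copy(), list(self.labels))

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic distances between all leaf pairs."""
        root = self.root
        depth = np.zeros(self.n_nodes)
        for node in self.preorder():
            if node != root:
                depth[node] = depth[self.parent[node]] + self.branch_lengths[node]
        # ancestors sets for LCA by walking up
        dists: dict[tuple[str, str], float] = {}
        leaves = [i for i in range(self.n_nodes) if self.is_leaf[i]]
        anc: dict[int, list[int]] = {}
        for leaf in leaves:
            path = []
            node = leaf
            while node >= 0:
                path.append(node)
                node = int(self.parent[node])
            anc[leaf] = path
        for a, b in combinations(leaves, 2):
            sa = set(anc[a])
            lca = next(n for n in anc[b] if n in sa)
            d = depth[a] + depth[b] - 2 * depth[lca]
            key = tuple(sorted((self.labels[a], self.labels[b])))
            dists[key] = d
        return dists

    # -- conversion ----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[list[int]] = [[] for _ in nodes]
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.full(len(nodes), np.nan)
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = str(nd.label)
        return cls(children, parent, lengths, labels)

    def to_dendropy(self, annotations: Mapping[int, str | float] | None = None
                    ) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_leaf[i]:
                dnodes[i].taxon = taxa.require_taxon(label=self.labels[i])
            elif self.labels[i] is not None:
                dnodes[i].label = str(self.labels[i])
            if annotations is not None and i in annotations:
                val = annotations[i]
                dnodes[i].label = (f"{val:.6g}" if isinstance(val, float) else str(val))
            if self.parent[i] >= 0:
                dnodes[self.parent[i]].add_child(dnodes[i])
                dnodes[i].edge.length = float(self.branch_lengths[i])
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = dnodes[self.root]
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self, annotations: Mapping[int, str | float] | None = None) -> str:
        """Newick string; branch lengths to 10 significant digits.

        ``annotations`` maps node index -> value.  Internal-node annotations
        occupy the node-label slot; leaf annotations are emitted as a
        FigTree-style ``[&label=...]`` comment after the taxon name.
        """
        ann = annotations or {}

        def fmt(val: str | float) -> str:
            return f"{val:.6g}" if isinstance(val, float) else str(val)

        def rec(i: int) -> str:
            if self.is_leaf[i]:
                s = self.labels[i]
                if i in ann:
                    s += f"[&label={fmt(ann[i])}]"
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
                if i in ann:
                    s += fmt(ann[i])
                elif self.labels[i] is not None:
                    s += str(self.labels[i])
            if self.parent[i] >= 0:
                s += f":{self.branch_lengths[i]:.10g}"
            return s

        return rec(self.root) + ";"


def read_tree(path: str | Path) -> PhyloTree:
    """Read a Newick tree file with branch lengths."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_tree(tree: PhyloTree, path: str | Path,
               annotations: Mapping[int, str | float] | None = None) -> None:
    """Write ``tree`` as Newick; ``annotations`` become internal node labels."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick(annotations) + "\n")
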