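"""Marginal sequence reconstruction at internal and terminal nodes.

A "reconstruction" is the per-site posterior distribution over the 20 amino
acids at one hidden node, with every other hidden node integrated out.  For
an internal node this is conventional marginal ancestral sequence
reconstruction (ASR).  For a terminal node the leaf's own observations are
masked (treated as missing data) so the posterior is conditioned only on
the remaining sequences — extant sequence reconstruction (ESR).  Masking
the leaf natively is mathematically equivalent to the long-branch
two-daughter grafting construction sometimes used to coerce ASR software
into reconstructing a tip (a branch of length ~1000 transmits no
information), and that equivalence is exercised in the test-suite.

Two cross-validation drivers are provided.  Sequence-wise CV fits the model
once on the full alignment, then reconstructs each leaf with its entire
sequence masked.  Site-wise CV deletes a single residue, re-optimizes branch
lengths and model parameters on the reduced data, and reconstructs just
that site; it is the stricter but far more expensive protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import GAP_CODE, N_STATES, decode
from .evomodel import EvoModel
from .phylolik import ModelFit, PruningEngine, optimize
from .seqio import Alignment, PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class ReconDistribution:
    """Per-site categorical distributions over amino acids at one node.

    ``probabilities`` has shape (n_sites, 20); rows at masked sites (gaps in
    the true sequence, for tip reconstructions) carry no distribution and
    are zeroed.  ``provenance`` records how the distribution was produced:
    ``asr``, ``esr-sequencewise`` or ``esr-sitewise``.
    """

    node: str
    probabilities: np.ndarray
    gap_mask: np.ndarray
    provenance: str = "asr"

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        self.probabilities = self.probabilities.copy()
        self.probabilities[self.gap_mask] = 0.0

    @property
    def n_sites(self) -> int:
        return self.probabilities.shape[0]

    @property
    def unmasked_sites(self) -> np.ndarray:
        return np.flatnonzero(~self.gap_mask)

    def site_distribution(self, site: int) -> np.ndarray:
        if self.gap_mask[site]:
            raise ValueError(f"site {site} is masked (gap in the true sequence)")
        return self.probabilities[site]


@dataclass
class SmpSequence:
    """The single most probable (SMP) sequence of a reconstruction."""

    node: str
    codes: np.ndarray          # -1 at masked sites
    site_probabilities: np.ndarray
    ties: list[int] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return decode(self.codes)


def smp(recon: ReconDistribution) -> SmpSequence:
    """Most probable residue at each unmasked site (ties -> first in alphabet).

    Exact probability ties are broken deterministically toward the lowest
    alphabet index and recorded in ``ties``.
    """
    codes = np.full(recon.n_sites, GAP_CODE, dtype=np.int8)
    probs = np.zeros(recon.n_sites)
    ties: list[int] = []
    sites = recon.unmasked_sites
    p = recon.probabilities[sites]
    best = p.argmax(axis=1)  # numpy argmax takes the first maximum
    codes[sites] = best
    probs[sites] = p[np.arange(len(sites)), best]
    n_max = (p == probs[sites][:, None]).sum(axis=1)
    for site in sites[n_max > 1]:
        ties.append(int(site))
    if ties:
        logger.info("SMP ties at %d site(s): %s", len(ties), ties[:10])
    return SmpSequence(recon.node, codes, probs, ties)


# ---------------------------------------------------------------------------
# Posteriors
# ---------------------------------------------------------------------------

def _gap_mask_for(aln: Alignment, label: str) -> np.ndarray:
    return aln.row(label) == GAP_CODE


def marginal_posterior(aln: Alignment, tree: PhyloTree, model: EvoModel,
                       node: str | int, *,
                       mask: np.ndarray | None = None,
                       engine: PruningEngine | None = None
                       ) -> ReconDistribution:
    """Marginal posterior distribution at one node under fitted parameters.

    ``node`` may be an internal node index or a leaf label.  For a leaf,
    ``mask`` selects the sites whose observed state is hidden before
    conditioning (default: all sites, i.e. the whole sequence is withheld);
    the returned distribution is then an extant reconstruction.  For
    internal nodes the result is a conventional marginal ASR distribution.
    """
    if isinstance(node, str):
        node_idx = tree.node_by_label(node)
        node_label = node
    else:
        node_idx = int(node)
        if not 0 <= node_idx < tree.n_nodes:
            raise KeyError(f"no node with index {node}")
        node_label = tree.labels[node_idx] or f"node{node_idx}"
    is_leaf = bool(tree.is_leaf[node_idx])
    if engine is None:
        masks = None
        if is_leaf:
            leaf_mask = (np.ones(aln.n_columns, dtype=bool)
                         if mask is None else np.asarray(mask, dtype=bool))
            masks = {node_label: leaf_mask}
        engine = PruningEngine(aln, tree, model, masks=masks)
    post = engine.posterior(node_idx)
    if is_leaf:
        gap_mask = _gap_mask_for(aln, node_label)
        provenance = "esr-sequencewise"
    else:
        gap_mask = np.zeros(aln.n_columns, dtype=bool)
        provenance = "asr"
    return ReconDistribution(node_label, post, gap_mask, provenance)


def reconstruct_ancestors(aln: Alignment, tree: PhyloTree, model: EvoModel,
                          nodes: Iterable[int] | None = None
                          ) -> dict[int, ReconDistribution]:
    """Marginal ASR distributions for all (or selected) internal nodes."""
    engine = PruningEngine(aln, tree, model)
    engine.compute_up()
    if nodes is None:
        nodes = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]
    out: dict[int, ReconDistribution] = {}
    for node in nodes:
        label = tree.labels[node] or f"node{node}"
        out[node] = ReconDistribution(
            label, engine.posterior(node),
            np.zeros(aln.n_columns, dtype=bool), "asr")
    return out


def esr_sequence_wise(aln: Alignment, tree: PhyloTree, model: EvoModel, *,
                      fit: ModelFit | None = None,
                      leaves: Sequence[str] | None = None,
                      refit: bool = True,
                      **fit_kwargs) -> dict[str, ReconDistribution]:
    """Sequence-wise CV: one full-data ML fit, then per-leaf masked posteriors.

    The training set is the full alignment; model parameters and branch
    lengths come from a single ML fit (or a supplied ``fit``, or the input
    values when ``refit`` is False).  Each leaf is then reconstructed with
    its entire sequence masked.  Gaps of the true sequence are applied to
    the returned distributions as the gap mask.
    """
    if fit is None and refit:
        fit = optimize(aln, tree, model, **fit_kwargs)
    if fit is not None:
        tree, model = fit.tree, fit.model
    if leaves is None:
        leaves = tree.leaf_labels
    out: dict[str, ReconDistribution] = {}
    for label in leaves:
        engine = PruningEngine(
            aln, tree, model,
            masks={label: np.ones(aln.n_columns, dtype=bool)})
        post = engine.posterior(tree.node_by_label(label))
        out[label] = ReconDistribution(label, post, _gap_mask_for(aln, label),
                                       "esr-sequencewise")
    return out


def esr_site_wise(aln: Alignment, tree: PhyloTree, model: EvoModel,
                  leaf: str, sites: Sequence[int] | None = None, *,
                  reoptimize: bool = True,
                  **fit_kwargs) -> ReconDistribution:
    """Site-wise CV reconstruction of one leaf.

    For each requested site the leaf's residue is deleted (set to gap),
    branch lengths and model parameters are re-optimized on the reduced
    alignment (topology fixed), and the site's posterior is computed with
    the residue masked.  Sites that are gapped in the true sequence are
    skipped.  With ``reoptimize`` False the input parameters are reused,
    which reduces exactly to the sequence-wise computation at that site.
    """
    row = aln.row(leaf).copy()
    gap_mask = row == GAP_CODE
    if sites is None:
        sites = np.flatnonzero(~gap_mask)
    probs = np.zeros((aln.n_columns, N_STATES))
    leaf_row = aln.ids.index(leaf)
    for site in sites:
        if gap_mask[site]:
            continue
        train = Alignment(list(aln.ids), aln.matrix.copy())
        train.matrix[leaf_row, site] = GAP_CODE
        if reoptimize:
            fit = optimize(train, tree, model, **fit_kwargs)
            use_tree, use_model = fit.tree, fit.model
        else:
            use_tree, use_model = tree, model
        site_mask = np.zeros(aln.n_columns, dtype=bool)
        site_mask[site] = True
        engine = PruningEngine(train, use_tree, use_model,
                               masks={leaf: site_mask})
        post = engine.posterior(use_tree.node_by_label(leaf))
        probs[site] = post[site]
    mask = gap_mask.copy()
    if sites is not None:
        requested = np.zeros(aln.n_columns, dtype=bool)
        requested[np.asarray(list(sites), dtype=int)] = True
        mask |= ~requested
    return ReconDistribution(leaf, probs, mask, "esr-sitewise")


# ---------------------------------------------------------------------------
# Sampling alternative sequences
# ---------------------------------------------------------------------------

def sample_sequences(recon: ReconDistribution, n: int = 1, *,
                     mode: str = "unbiased", threshold: float = 0.2,
                     seed: int | np.random.Generator | None = None
                     ) -> list[SmpSequence]:
    """Draw alternative sequences from a reconstruction distribution.

    ``unbiased``
        independent per-site draws from the categorical distribution.
    ``biased``
        per-site draws restricted to residues with probability at least
        ``threshold`` (renormalized); sites where no residue reaches the
        threshold fall back to the SMP residue.
    ``altall``
        the deterministic alternative sequence: the second most probable
        residue wherever its probability exceeds ``threshold`` (0.2 by
        default), the SMP residue elsewhere.  ``n`` is ignored (one
        sequence is returned).
    """
    if mode not in ("unbiased", "biased", "altall"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sites = recon.unmasked_sites
    P = recon.probabilities[sites]
    smp_seq = smp(recon)

    def assemble(codes_sites: np.ndarray) -> SmpSequence:
        codes = np.full(recon.n_sites, GAP_CODE, dtype=np.int8)
        probs = np.zeros(recon.n_sites)
        codes[sites] = codes_sites
        probs[sites] = P[np.arange(len(sites)), codes_sites]
        return SmpSequence(recon.node, codes, probs)

    if mode == "altall":
        order = np.argsort(-P, axis=1)
        first, second = order[:, 0], order[:, 1]
        p_second = P[np.arange(len(sites)), second]
        pick = np.where(p_second > threshold, second, smp_seq.codes[sites])
        return [assemble(pick.astype(np.int8))]

    if mode == "biased":
        P = np.where(P >= threshold, P, 0.0)
        empty = P.sum(axis=1) <= 0
        if empty.any():
            logger.info("biased sampling: %d site(s) below threshold, "
                        "falling back to SMP residue", int(empty.sum()))
            P[empty, smp_seq.codes[sites[empty]]] = 1.0
        P = P / P.sum(axis=1, keepdims=True)

    cum = np.cumsum(P, axis=1)
    cum /= cum[:, -1:]
    out = []
    for _ in range(n):
        u = rng.random(len(sites))
        draws = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        out.append(assemble(draws))
    return out


# ---------------------------------------------------------------------------
# Taxon pruning
# ---------------------------------------------------------------------------

def prune_leaves(tree: PhyloTree, aln: Alignment, remove: Sequence[str]
                 ) -> tuple[PhyloTree, Alignment]:
    """Remove the named leaves; splice out degree-2 nodes, summing lengths.

    Pairwise path lengths among the surviving leaves are preserved exactly.
    """
    keep = [lab for lab in tree.leaf_labels if lab not in set(remove)]
    if len(keep) < 3:
        raise ValueError("pruning would leave fewer than 3 taxa")
    children = [list(c) for c in tree.children]
    parent = tree.parent.copy()
    lengths = tree.branch_lengths.copy()
    alive = np.ones(tree.n_nodes, dtype=bool)
    label_to_node = tree.leaf_index()
    for lab in remove:
        node = label_to_node[lab]
        alive[node] = False
        p = int(parent[node])
        children[p].remove(node)
        # splice chains of degree-1 internal nodes upward
        while p >= 0 and len(children[p]) == 1 and alive[p]:
            child = children[p][0]
            gp = int(parent[p])
            if gp < 0:
                # root with a single child: child becomes the new root
                alive[p] = False
                parent[child] = -1
                lengths[child] = np.nan
                break
            lengths[child] = lengths[child] + lengths[p]
            parent[child] = gp
            children[gp].remove(p)
            children[gp].append(child)
            alive[p] = False
            p = gp
    # compact indices
    old_ids = np.flatnonzero(alive)
    new_index = {old: new for new, old in enumerate(old_ids)}
    new_children = [[new_index[c] for c in children[o]] for o in old_ids]
    new_parent = np.array([new_index[parent[o]] if parent[o] >= 0 and alive[parent[o]]
                           else -1 for o in old_ids])
    new_tree = PhyloTree(new_children, new_parent, lengths[old_ids],
                         [tree.labels[o] for o in old_ids])
    return new_tree, aln.subset(keep)


def prune_short_branches(tree: PhyloTree, aln: Alignment, n_remove: int,
                         step: int = 1
                         ) -> list[tuple[PhyloTree, Alignment, list[str]]]:
    """Iteratively remove the leaves with the shortest terminal branches.

    Returns the series of (pruned tree, pruned alignment, removed labels)
    after every ``step`` removals, mirroring the taxon-sampling experiment
    in which reconstruction accuracy is tracked as short-branch taxa are
    progressively discarded.
    """
    if n_remove >= tree.n_leaves - 3:
        raise ValueError("cannot prune that many taxa")
    series: list[tuple[PhyloTree, Alignment, list[str]]] = []
    current_tree, current_aln = tree, aln
    removed: list[str] = []
    for k in range(1, n_remove + 1):
        leaves = [(current_tree.branch_lengths[i], current_tree.labels[i])
                  for i in range(current_tree.n_nodes) if current_tree.is_leaf[i]]
        _, victim = min(leaves)
        current_tree, current_aln = prune_leaves(current_tree, current_aln, [victim])
        removed.append(victim)
        if k % step == 0 or k == n_remove:
            series.append((current_tree, current_aln, list(removed)))
    return series
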