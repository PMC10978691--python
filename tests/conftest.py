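"""Shared fixtures and independent brute-force oracles.

The enumeration oracle builds the explicit joint probability tensor over all
hidden-node states by broadcasting one factor per node (equilibrium prior at
the root, a transition-matrix factor per edge), then sums axes.  It never
uses the package's pruning recursion, so it is an independent check of both
the total likelihood and every marginal posterior on small trees.
"""

from __future__ import annotations

import numpy as np
import pytest

import phyloesr as pe
from phyloesr.alphabet import GAP_CODE, N_STATES
from phyloesr.evomodel import EvoModel, TransitionCalculator, build_rate_matrix


@pytest.fixture
def four_leaf_tree() -> pe.PhyloTree:
    return pe.PhyloTree.from_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.4):0.25);")


@pytest.fixture
def four_leaf_aln() -> pe.Alignment:
    return pe.Alignment.from_sequences(["A", "B", "C", "D"],
                                       ["ARN", "RRC", "ARC", "AKC"])


def random_reversible_model(rng: np.random.Generator, *,
                            gamma: bool = False) -> EvoModel:
    """A random GTR-style model: Dirichlet frequencies, lognormal exchangeabilities."""
    S = np.zeros((N_STATES, N_STATES))
    tri = np.triu_indices(N_STATES, k=1)
    vals = rng.lognormal(0.0, 1.0, size=len(tri[0]))
    S[tri] = vals
    S += S.T
    pi = rng.dirichlet(np.full(N_STATES, 5.0))
    model = EvoModel(name="random", matrix="GTR20", exchangeabilities=S,
                     frequencies=pi, free_frequencies=False,
                     free_exchangeabilities=False)
    if gamma:
        model.alpha = float(rng.uniform(0.8, 2.5))
        model.n_rate_categories = 3
    return model


def joint_tensor_posteriors(aln: pe.Alignment, tree: pe.PhyloTree,
                            model: EvoModel,
                            masked_leaves: set[str] = frozenset()
                            ) -> tuple[float, dict[int, np.ndarray]]:
    """Brute-force lnL and per-node marginal posteriors by joint enumeration.

    Hidden nodes (internal nodes plus masked leaves) each get a tensor axis
    of size 20; observed leaves are folded in as transition-row vectors.
    Returns the total log-likelihood and, per hidden node, the (n_sites, 20)
    posterior matrix.
    """
    cats = model.rate_categories()
    calc = TransitionCalculator(build_rate_matrix(model), model.frequencies)
    pi = model.frequencies
    hidden = [i for i in range(tree.n_nodes)
              if not tree.is_leaf[i] or tree.labels[i] in masked_leaves]
    axis = {node: k for k, node in enumerate(hidden)}
    n_sites = aln.n_columns
    lnl = 0.0
    post = {node: np.zeros((n_sites, N_STATES)) for node in hidden}
    for s in range(n_sites):
        site_lik = 0.0
        site_joint = {node: np.zeros(N_STATES) for node in hidden}
        for c, (rate, weight) in enumerate(zip(cats.rates, cats.weights)):
            tensor = np.ones([N_STATES] * len(hidden))

            def bcast(vec_or_mat: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
                shape = [1] * len(hidden)
                for ax, size in zip(axes, vec_or_mat.shape):
                    shape[ax] = size
                return vec_or_mat.reshape(shape)

            tensor = tensor * bcast(pi, (axis[tree.root],))
            for node in range(tree.n_nodes):
                if node == tree.root:
                    continue
                parent = int(tree.parent[node])
                P = calc(rate * tree.branch_lengths[node])
                if node in axis:
                    ax_p, ax_c = axis[parent], axis[node]
                    if ax_p < ax_c:
                        tensor = tensor * bcast(P, (ax_p, ax_c))
                    else:  # reshape fills axes in order: transpose first
                        tensor = tensor * bcast(P.T, (ax_c, ax_p))
                else:
                    code = aln.row(tree.labels[node])[s]
                    if code == GAP_CODE:
                        continue  # sums to one over the leaf state
                    tensor = tensor * bcast(P[:, code], (axis[parent],))
            site_lik += weight * tensor.sum()
            for node in hidden:
                other = tuple(a for a in range(len(hidden)) if a != axis[node])
                site_joint[node] += weight * tensor.sum(axis=other)
        lnl += np.log(site_lik)
        for node in hidden:
            post[node][s] = site_joint[node] / site_joint[node].sum()
    return float(lnl), post
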