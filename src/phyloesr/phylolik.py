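"""Phylogenetic likelihood on a fixed topology, ML fitting, and model selection.

The likelihood of a gapped amino-acid alignment on a rooted tree is computed
by Felsenstein pruning with per-node rescaling: conditional ("inside")
partial vectors are propagated leafwards-to-root per site and per rate
category, gaps contribute a unit partial (missing data), and categories are
integrated with their mixture weights.  "Outside" partial vectors propagated
root-to-leaves support marginal reconstruction posteriors and fast
per-branch length optimization.

``optimize`` fits branch lengths and model parameters (frequencies, gamma
shape, invariant fraction, GTR exchangeabilities) by coordinate rounds:
each round sweeps every branch with bounded scalar optimization against
cached outside/inside partials, then takes a few quasi-Newton steps on the
transformed model parameters.  Convergence is declared when the
round-to-round log-likelihood gain falls below ``tol``.

Model selection follows the sign convention in which both criteria are
penalized log-likelihoods and larger (less negative) is better:
AIC = lnL - K and BIC = lnL - K ln(N)/2, where K counts 2*n_taxa - 3 branch
lengths plus 19 (FO), 1 (gamma), 1 (invariant sites) and 189 (GTR20), and
N is the number of alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alphabet import GAP_CODE, N_STATES
from .evomodel import EvoModel, TransitionCalculator, _TRI, build_rate_matrix
from .seqio import Alignment, PhyloTree

BRANCH_BOUNDS = (1e-8, 100.0)


class PairingError(ValueError):
    """Alignment ids and tree leaf labels do not match."""


@dataclass
class SiteLikelihoodTable:
    """Per-site log-likelihoods and the partials behind them."""

    site_log_likelihoods: np.ndarray  # (n_sites,)
    rates: np.ndarray
    weights: np.ndarray

    @property
    def total(self) -> float:
        return float(self.site_log_likelihoods.sum())


class PruningEngine:
    """Pruning likelihood and inside/outside partials for one dataset.

    Parameters
    ----------
    aln, tree : the data; every tree leaf label must be an alignment id.
    model : concrete :class:`EvoModel`.
    masks : optional mapping of leaf label -> boolean site mask.  Masked
        sites of that leaf are treated as unobserved (missing data), which
        is how extant-sequence reconstruction hides the test sequence.
    """

    def __init__(self, aln: Alignment, tree: PhyloTree, model: EvoModel,
                 masks: Mapping[str, np.ndarray] | None = None) -> None:
        leaf_labels = set(tree.leaf_labels)
        if not leaf_labels.issubset(set(aln.ids)):
            missing = leaf_labels - set(aln.ids)
            raise PairingError(f"tree leaves missing from alignment: {sorted(missing)[:5]}")
        self.aln = aln
        self.tree = tree
        self.n_sites = aln.n_columns
        self.postorder = tree.postorder()
        self.preorder = self.postorder[::-1]
        self.root = tree.root
        # leaf node index -> alignment row codes
        self.leaf_codes = {node: aln.row(label)
                           for label, node in tree.leaf_index().items()}
        self.masks: dict[int, np.ndarray] = {}
        if masks:
            label_to_node = tree.leaf_index()
            for label, mask in masks.items():
                self.masks[label_to_node[label]] = np.asarray(mask, dtype=bool)
        self._down: np.ndarray | None = None
        self._downedge: np.ndarray | None = None
        self._up: np.ndarray | None = None
        self._logsc: np.ndarray | None = None
        self.set_model(model)

    # ------------------------------------------------------------------
    def set_model(self, model: EvoModel) -> None:
        self.model = model
        cats = model.rate_categories()
        self.rates = cats.rates
        self.weights = cats.weights
        self.pi = model.frequencies
        self.calc = TransitionCalculator(build_rate_matrix(model), self.pi)
        self._P = np.empty((self.tree.n_nodes, len(self.rates), N_STATES, N_STATES))
        for node in range(self.tree.n_nodes):
            if node != self.root:
                self._set_P(node, self.tree.branch_lengths[node])
        self._invalidate()

    def _set_P(self, node: int, t: float) -> None:
        self._P[node] = self.calc(self.rates * t)

    def set_branch_length(self, node: int, t: float) -> None:
        self.tree.branch_lengths[node] = t
        self._set_P(node, t)
        self._invalidate()

    def _invalidate(self) -> None:
        self._down = self._downedge = self._up = self._logsc = None

    # ------------------------------------------------------------------
    def _leaf_partial(self, node: int) -> np.ndarray:
        codes = self.leaf_codes[node]
        part = np.zeros((self.n_sites, N_STATES))
        observed = codes != GAP_CODE
        if node in self.masks:
            observed = observed & ~self.masks[node]
        part[~observed] = 1.0
        idx = np.flatnonzero(observed)
        part[idx, codes[idx]] = 1.0
        C = len(self.rates)
        return np.broadcast_to(part, (C, self.n_sites, N_STATES)).copy()

    def compute_down(self) -> None:
        """Inside (postorder) partials, edge-propagated partials, scale logs."""
        n_nodes = self.tree.n_nodes
        C, S = len(self.rates), self.n_sites
        down = np.empty((n_nodes, C, S, N_STATES))
        downedge = np.empty_like(down)
        logsc = np.zeros((n_nodes, S))
        for node in self.postorder:
            kids = self.tree.children[node]
            if not kids:
                down[node] = self._leaf_partial(node)
            else:
                acc = downedge[kids[0]].copy()
                sc = logsc[kids[0]].copy()
                for child in kids[1:]:
                    acc *= downedge[child]
                    sc += logsc[child]
                m = acc.max(axis=(0, 2))
                m[m <= 0] = 1.0
                acc /= m[None, :, None]
                down[node] = acc
                logsc[node] = sc + np.log(m)
            if node != self.root:
                downedge[node] = np.matmul(down[node],
                                           self._P[node].transpose(0, 2, 1))
        self._down, self._downedge, self._logsc = down, downedge, logsc

    def site_log_likelihoods(self) -> np.ndarray:
        if self._down is None:
            self.compute_down()
        root_part = self._down[self.root]  # (C, S, 20)
        per_cat = root_part @ self.pi      # (C, S)
        lik = self.weights @ per_cat       # (S,)
        lik = np.clip(lik, 1e-300, None)
        return np.log(lik) + self._logsc[self.root]

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    def compute_up(self) -> None:
        """Outside (preorder) partials; root outside partial is pi."""
        if self._down is None:
            self.compute_down()
        n_nodes = self.tree.n_nodes
        C, S = len(self.rates), self.n_sites
        up = np.empty((n_nodes, C, S, N_STATES))
        up[self.root] = self.pi[None, None, :]
        for node in self.preorder:
            kids = self.tree.children[node]
            for child in kids:
                F = up[node].copy()
                for sib in kids:
                    if sib != child:
                        F *= self._downedge[sib]
                u = np.matmul(F, self._P[child])
                m = u.max(axis=(0, 2))
                m[m <= 0] = 1.0
                up[child] = u / m[None, :, None]
        self._up = up

    def posterior(self, node: int) -> np.ndarray:
        """Marginal posterior state distribution at ``node``: (n_sites, 20).

        Rate-category uncertainty is integrated with the mixture weights;
        every other hidden node is integrated out by the inside/outside
        construction.
        """
        if self._up is None:
            self.compute_up()
        joint = self._up[node] * self._down[node]       # (C, S, 20)
        post = np.einsum("c,csk->sk", self.weights, joint)
        norm = post.sum(axis=1, keepdims=True)
        norm[norm <= 0] = 1.0
        return post / norm

    # -- branch-length machinery ---------------------------------------
    def _branch_outside(self, node: int) -> np.ndarray:
        """Outside partial at the top of the branch above ``node``."""
        parent = int(self.tree.parent[node])
        F = self._up[parent].copy()
        for sib in self.tree.children[parent]:
            if sib != node:
                F *= self._downedge[sib]
        return F

    def _branch_loglik(self, F: np.ndarray, down_node: np.ndarray,
                       t: float) -> float:
        P = self.calc(self.rates * t)                    # (C, 20, 20)
        M = np.matmul(F, P)                              # (C, S, 20)
        per_cat = np.einsum("csk,csk->cs", M, down_node)
        lik = np.clip(self.weights @ per_cat, 1e-300, None)
        return float(np.log(lik).sum())

    def optimize_branch(self, node: int) -> float:
        """Optimize one branch length against cached partials.

        The profile likelihood in t is unimodal but flattens into the
        equilibrium plateau at large t, which defeats naive golden-section
        search over the full bounds; a coarse log-spaced scan around the
        current value brackets the optimum before the bounded refine, and a
        worse-than-current result is never accepted.
        """
        F = self._branch_outside(node)
        down_node = self._down[node]
        t_cur = float(self.tree.branch_lengths[node])
        obj = lambda t: -self._branch_loglik(F, down_node, t)
        grid = np.unique(np.clip(np.concatenate([
            t_cur * np.array([0.25, 0.5, 1.0, 2.0, 4.0]),
            [1e-6, 1e-3, 1e-2, 0.1, 0.3, 1.0, 3.0, 10.0]]),
            BRANCH_BOUNDS[0], BRANCH_BOUNDS[1]))
        vals = np.array([obj(t) for t in grid])
        best = int(vals.argmin())
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        # modest per-sweep precision: sweeps iterate, so 1e-4 relative is enough
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": max(1e-9, 1e-4 * (hi - lo))})
        t = float(res.x)
        if res.fun > obj(t_cur):
            t = t_cur
        self.tree.branch_lengths[node] = t
        self._set_P(node, t)
        # refresh this branch's edge partial and outside partial in place so
        # later branches in the sweep see the update
        self._downedge[node] = np.matmul(self._down[node],
                                         self._P[node].transpose(0, 2, 1))
        u = np.matmul(F, self._P[node])
        m = u.max(axis=(0, 2))
        m[m <= 0] = 1.0
        self._up[node] = u / m[None, :, None]
        return t

    def sweep_branches(self) -> None:
        """One preorder sweep of per-branch optimizations."""
        self.compute_down()
        self.compute_up()
        for node in self.preorder:
            if node != self.root:
                self.optimize_branch(node)
        self._down = self._up = None  # force fresh partials next use


# ---------------------------------------------------------------------------
# Model parameter transforms
# ---------------------------------------------------------------------------

def _pack(model: EvoModel) -> np.ndarray:
    x: list[float] = []
    if model.free_frequencies:
        ref = model.frequencies[-1]
        x.extend(np.log(model.frequencies[:-1] / ref))
    if model.has_gamma:
        x.append(math.log(model.alpha))
    if model.has_invariant:
        p = min(max(model.p_invariant, 1e-6), 0.999)
        x.append(math.log(p / (1 - p)))
    if model.free_exchangeabilities:
        s = np.array([model.exchangeabilities[i, j] for i, j in _TRI])
        s = np.clip(s, 1e-8, None)
        x.extend(np.log(s[:-1] / s[-1]))
    return np.array(x)


def _unpack(model: EvoModel, x: np.ndarray) -> EvoModel:
    out = model.copy()
    k = 0
    if model.free_frequencies:
        z = np.concatenate([x[k:k + N_STATES - 1], [0.0]])
        z -= z.max()
        w = np.exp(z)
        out.frequencies = w / w.sum()
        k += N_STATES - 1
    if model.has_gamma:
        out.alpha = float(np.clip(math.exp(x[k]), 1e-3, 1e6))
        k += 1
    if model.has_invariant:
        out.p_invariant = float(1.0 / (1.0 + math.exp(-x[k])))
        k += 1
    if model.free_exchangeabilities:
        n = len(_TRI) - 1
        s = np.concatenate([np.exp(np.clip(x[k:k + n], -30, 30)), [1.0]])
        S = np.zeros((N_STATES, N_STATES))
        for (i, j), val in zip(_TRI, s):
            S[i, j] = S[j, i] = val
        out.exchangeabilities = S
        k += n
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A maximized model: log-likelihood, parameter count, AIC/BIC, fits."""

    lnL: float
    K: int
    N: int
    model: EvoModel
    tree: PhyloTree
    n_rounds: int = 0
    converged: bool = True
    history: list[float] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return aic(self.lnL, self.K)

    @property
    def bic(self) -> float:
        return bic(self.lnL, self.K, self.N)


def count_parameters(model: EvoModel, n_taxa: int) -> int:
    """Free parameters: 2*n_taxa-3 branch lengths plus model additions."""
    if n_taxa < 3:
        raise ValueError("parameter counting requires at least 3 taxa")
    return 2 * n_taxa - 3 + model.n_free_parameters()


def aic(lnL: float, K: float) -> float:
    """Penalized log-likelihood AIC = lnL - K (larger is better)."""
    return lnL - K


def bic(lnL: float, K: float, N: int) -> float:
    """Penalized log-likelihood BIC = lnL - K ln(N) / 2 (larger is better)."""
    if N < 1:
        raise ValueError("N must be at least 1")
    return lnL - K * math.log(N) / 2.0


def log_likelihood(aln: Alignment, tree: PhyloTree, model: EvoModel,
                   masks: Mapping[str, np.ndarray] | None = None
                   ) -> tuple[float, SiteLikelihoodTable]:
    """Total pruning log-likelihood and its per-site table."""
    engine = PruningEngine(aln, tree, model, masks=masks)
    site = engine.site_log_likelihoods()
    cats = model.rate_categories()
    return float(site.sum()), SiteLikelihoodTable(site, cats.rates, cats.weights)


def optimize(aln: Alignment, tree: PhyloTree, model: EvoModel, *,
             tol: float = 1e-4, max_rounds: int = 100,
             max_sweeps_per_round: int = 30,
             param_steps_per_round: int = 10,
             optimize_branch_lengths: bool = True,
             verbose: bool = False) -> ModelFit:
    """ML fit of branch lengths and free model parameters on a fixed topology.

    Each round runs per-branch scalar-optimization sweeps to convergence,
    then a bounded quasi-Newton step block on the transformed model
    parameters; rounds repeat until the round-to-round log-likelihood
    improvement drops below ``tol``.  The topology is never changed.
    Returns a :class:`ModelFit` whose tree is a fitted copy of the input.
    """
    work_tree = tree.copy()
    if optimize_branch_lengths:
        np.clip(work_tree.branch_lengths, BRANCH_BOUNDS[0], BRANCH_BOUNDS[1],
                out=work_tree.branch_lengths)
        work_tree.branch_lengths[work_tree.root] = np.nan
    model = model.copy()
    if model.free_frequencies:
        model.frequencies = _observed_frequencies(aln)
    engine = PruningEngine(aln, work_tree, model)
    lnl = engine.log_likelihood()
    history = [lnl]
    has_params = len(_pack(model)) > 0
    converged = False
    n_rounds = 0
    param_gain = np.inf
    for n_rounds in range(1, max_rounds + 1):
        prev = lnl
        if optimize_branch_lengths:
            # coarse inner threshold: the outer loop polishes the tail
            inner_tol = tol if param_gain < tol else max(tol, 1e-2)
            for _ in range(max_sweeps_per_round):
                before = lnl
                prev_bl = work_tree.branch_lengths.copy()
                engine.sweep_branches()
                cur = engine.log_likelihood()
                if cur < before - 1e-9:
                    # stale-partial sweep worsened the likelihood: revert
                    work_tree.branch_lengths[:] = prev_bl
                    engine.set_model(model)
                    break
                lnl = cur
                if lnl - before < inner_tol:
                    break
        if has_params and param_gain >= tol:
            x0 = _pack(model)

            def negloglik(x: np.ndarray) -> float:
                engine.set_model(_unpack(model, x))
                return -engine.log_likelihood()

            res = minimize(negloglik, x0, method="L-BFGS-B",
                           options={"maxiter": param_steps_per_round,
                                    "maxfun": 40 * param_steps_per_round})
            param_gain = max(-res.fun - lnl, 0.0)
            if -res.fun >= lnl:
                model = _unpack(model, res.x)
                lnl = -res.fun
            engine.set_model(model)
        history.append(lnl)
        if verbose:
            print(f"round {n_rounds}: lnL = {lnl:.6f}")
        if lnl - prev < tol:
            converged = True
            break
    # 2*n-3 identifiable branch lengths; a two-leaf tree has one
    k = max(2 * aln.n_taxa - 3, 1) + model.n_free_parameters()
    return ModelFit(lnL=lnl, K=k, N=aln.n_columns, model=model,
                    tree=work_tree, n_rounds=n_rounds, converged=converged,
                    history=history)


def _observed_frequencies(aln: Alignment) -> np.ndarray:
    counts = np.bincount(aln.matrix[aln.matrix != GAP_CODE].ravel(),
                         minlength=N_STATES).astype(float)
    counts += 1.0  # avoid zero frequencies
    return counts / counts.sum()
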