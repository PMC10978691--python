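"""Reversible amino-acid substitution models.

A model is specified by a string of the form ``MATRIX[+F{Q,O}][+G12][+I]``
with ``MATRIX`` one of ``Poisson`` (all exchangeabilities equal), ``LG``
(the published Le-Gascuel matrix, shipped as package data) or ``GTR20``
(all 190 exchangeabilities free up to one fixed reference).  ``FQ`` fixes
the equilibrium frequencies at 1/20; ``FO`` makes them free parameters
optimized by maximum likelihood.  ``G12`` adds 12-category discrete-gamma
among-site rate variation (equal-probability bins, mean-of-bin rates);
``+I`` adds a proportion of invariant sites.

The instantaneous rate matrix is the standard general-time-reversible
construction Q_ij = s_ij * pi_j (i != j), with the diagonal set so rows sum
to zero and the whole matrix rescaled so the expected substitution rate at
equilibrium, -sum_i pi_i Q_ii, is one: branch lengths are then expected
substitutions per site.  Transition probabilities P(t) = exp(Qt) are
computed by symmetric eigendecomposition of diag(pi)^(1/2) Q diag(pi)^(-1/2),
which is numerically stable for reversible Q.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alphabet import N_STATES


class ModelSpecError(ValueError):
    """Unknown token in a model specification string."""


_MATRICES = ("Poisson", "LG", "GTR20")

# lower-triangle (i>j) index pairs in fixed order; 190 entries
_TRI = [(i, j) for i in range(1, N_STATES) for j in range(i)]


def _load_lg() -> tuple[np.ndarray, np.ndarray]:
    text = (resources.files("phyloesr") / "data" / "lg_model.txt").read_text()
    rows = [ln.split() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(rows[:19], start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = float(v)
    freqs = np.array([float(v) for v in rows[19]])
    return S, freqs / freqs.sum()


_LG_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def lg_matrix() -> tuple[np.ndarray, np.ndarray]:
    """The published LG exchangeabilities and equilibrium frequencies."""
    global _LG_CACHE
    if _LG_CACHE is None:
        _LG_CACHE = _load_lg()
    return _LG_CACHE[0].copy(), _LG_CACHE[1].copy()


@dataclass
class RateCategories:
    """Relative rates and probabilities of the among-site rate mixture."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("category weights must sum to 1")


def discretize_gamma(alpha: float, n_categories: int) -> RateCategories:
    """Equal-probability discrete-gamma rates (mean-of-bin), mean exactly 1.

    The gamma density has shape ``alpha`` and rate ``alpha`` (mean 1).  Each
    of the ``n_categories`` equal-probability bins is represented by its
    conditional mean, computed from the incomplete-gamma identity
    E[X; X in (a,b)] = F(b; alpha+1) - F(a; alpha+1) for rate alpha, then
    the rates are renormalized so the discrete mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return RateCategories(np.array([1.0]), np.array([1.0]))
    probs = np.arange(1, n_categories) / n_categories
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    upper = gamma_dist.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = n_categories * (upper - lower)
    rates /= rates.mean()
    weights = np.full(n_categories, 1.0 / n_categories)
    return RateCategories(rates, weights)


@dataclass
class EvoModel:
    """A concrete reversible substitution model with rate variation.

    ``exchangeabilities`` is the symmetric 20x20 matrix s with zero
    diagonal; ``frequencies`` the equilibrium distribution pi.  ``alpha``
    and ``n_rate_categories`` control the discrete-gamma mixture (``alpha``
    None means rate homogeneity); ``p_invariant`` adds an invariant-sites
    category at rate 0.
    """

    name: str
    matrix: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    free_frequencies: bool
    free_exchangeabilities: bool
    alpha: float | None = None
    n_rate_categories: int = 1
    p_invariant: float | None = None

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            self.frequencies = self.frequencies / self.frequencies.sum()

    # -- parameter structure ------------------------------------------
    @property
    def has_gamma(self) -> bool:
        return self.alpha is not None

    @property
    def has_invariant(self) -> bool:
        return self.p_invariant is not None

    def n_free_parameters(self) -> int:
        """Model parameters beyond branch lengths (FO:19, G:1, I:1, GTR20:189)."""
        k = 0
        if self.free_frequencies:
            k += N_STATES - 1
        if self.has_gamma:
            k += 1
        if self.has_invariant:
            k += 1
        if self.free_exchangeabilities:
            k += len(_TRI) - 1
        return k

    def copy(self) -> "EvoModel":
        return EvoModel(self.name, self.matrix, self.exchangeabilities.copy(),
                        self.frequencies.copy(), self.free_frequencies,
                        self.free_exchangeabilities, self.alpha,
                        self.n_rate_categories, self.p_invariant)

    # -- rate machinery ------------------------------------------------
    def rate_categories(self) -> RateCategories:
        """The full rate mixture including any invariant-sites category.

        With +I the gamma (or single) categories are rescaled by
        1/(1 - p_inv) so the mixture mean stays exactly 1.
        """
        if self.has_gamma:
            base = discretize_gamma(self.alpha, self.n_rate_categories)
        else:
            base = RateCategories(np.array([1.0]), np.array([1.0]))
        if not self.has_invariant:
            return base
        p = self.p_invariant
        scale = 1.0 / (1.0 - p) if p < 1.0 else 1.0
        rates = np.concatenate([[0.0], base.rates * scale])
        weights = np.concatenate([[p], base.weights * (1.0 - p)])
        return RateCategories(rates, weights)

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    def transition_calculator(self) -> "TransitionCalculator":
        return TransitionCalculator(self.rate_matrix(), self.frequencies)


def parse_model(spec: str) -> EvoModel:
    """Parse a model string such as ``"LG+FO+G12"`` into a template.

    GTR20 implies free (FO) frequencies.  When no frequency flag is given,
    FQ (uniform 1/20) is assumed for Poisson and LG.  The returned model is
    a template: free parameters carry starting values (uniform or published
    frequencies, alpha=1, p_inv=0.05) until fitted.
    """
    tokens = spec.strip().split("+")
    matrix = tokens[0]
    if matrix not in _MATRICES:
        raise ModelSpecError(f"unknown substitution matrix {matrix!r}")
    free_freq = matrix == "GTR20"
    alpha: float | None = None
    n_cat = 1
    p_inv: float | None = None
    for tok in tokens[1:]:
        if tok == "FQ":
            if matrix == "GTR20":
                raise ModelSpecError("GTR20 requires optimized (FO) frequencies")
            free_freq = False
        elif tok == "FO":
            free_freq = True
        elif m := re.fullmatch(r"G(\d+)", tok):
            alpha = 1.0
            n_cat = int(m.group(1))
            if n_cat < 1:
                raise ModelSpecError("gamma needs at least one category")
        elif tok == "I":
            p_inv = 0.05
        else:
            raise ModelSpecError(f"unknown model token {tok!r}")
    if matrix == "Poisson":
        S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
        freqs = np.full(N_STATES, 1.0 / N_STATES)
    elif matrix == "LG":
        S, lg_freqs = lg_matrix()
        freqs = lg_freqs if free_freq else np.full(N_STATES, 1.0 / N_STATES)
    else:  # GTR20: start from LG values
        S, freqs = lg_matrix()
    return EvoModel(name=spec.strip(), matrix=matrix, exchangeabilities=S,
                    frequencies=freqs, free_frequencies=free_freq,
                    free_exchangeabilities=(matrix == "GTR20"),
                    alpha=alpha, n_rate_categories=n_cat, p_invariant=p_inv)


def build_rate_matrix(model: EvoModel) -> np.ndarray:
    """The normalized GTR rate matrix Q_ij = s_ij pi_j, unit expected rate."""
    pi = model.frequencies
    if (pi <= 0).any():
        raise ValueError("equilibrium frequencies must be strictly positive")
    Q = model.exchangeabilities * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / rate


class TransitionCalculator:
    """Fast P(t)=exp(Qt) for a fixed reversible Q via symmetric eigendecomposition."""

    def __init__(self, Q: np.ndarray, frequencies: np.ndarray) -> None:
        self.Q = Q
        self.pi = np.asarray(frequencies, dtype=float)
        sqrt_pi = np.sqrt(self.pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        eigval, V = np.linalg.eigh((B + B.T) / 2.0)
        self.eigval = eigval
        self._U = V / sqrt_pi[:, None]      # diag(pi)^(-1/2) V
        self._W = V.T * sqrt_pi[None, :]    # V^T diag(pi)^(1/2)

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """P(t); ``t`` may be scalar or an array of times (stacked on axis 0)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if (t_arr < 0).any():
            raise ValueError("branch length times rate must be non-negative")
        expl = np.exp(self.eigval[None, :] * t_arr[:, None])
        P = np.einsum("ik,tk,kj->tij", self._U, expl, self._W)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        if np.isscalar(t) or np.ndim(t) == 0:
            return P[0]
        return P


def transition_matrix(model_or_Q, t: float, frequencies: np.ndarray | None = None
                      ) -> np.ndarray:
    """Transition probability matrix P(t) for a model or raw (Q, pi) pair."""
    if isinstance(model_or_Q, EvoModel):
        calc = model_or_Q.transition_calculator()
    else:
        if frequencies is None:
            raise ValueError("frequencies required with a raw rate matrix")
        calc = TransitionCalculator(np.asarray(model_or_Q), frequencies)
    return calc(t)
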