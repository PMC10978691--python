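"""Model/Results front end.

:class:`PhyloCTMC` bundles an alignment, a fixed tree topology, and a
substitution-model specification; ``.fit()`` maximizes the likelihood and
returns a :class:`PhyloCTMCResults` carrying the estimates, model-selection
scores and a ``summary()`` table, with reconstruction, cross-validation,
simulation and tree-annotation methods hanging off the results object.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evomodel import EvoModel, parse_model
from .phylolik import ModelFit, PruningEngine, log_likelihood, optimize
from .reconstruct import (ReconDistribution, esr_sequence_wise, esr_site_wise,
                          marginal_posterior, reconstruct_ancestors)
from .reconstats import sequence_stats
from .seqio import Alignment, PhyloTree, read_alignment, read_tree
from .simulate import SimulationResult, simulate
from .viz import annotate_tree_elnp


class PhyloCTMC:
    """A reversible amino-acid CTMC on a fixed tree topology.

    Parameters
    ----------
    alignment : :class:`~phyloesr.seqio.Alignment`
    tree : :class:`~phyloesr.seqio.PhyloTree`
        Topology is fixed; branch lengths are starting values for the fit.
    model : str or :class:`~phyloesr.evomodel.EvoModel`
        e.g. ``"LG+FO+G12"``.
    """

    def __init__(self, alignment: Alignment, tree: PhyloTree,
                 model: str | EvoModel = "LG+FO+G12") -> None:
        self.alignment = alignment
        self.tree = tree
        self.model = parse_model(model) if isinstance(model, str) else model
        missing = set(tree.leaf_labels) - set(alignment.ids)
        if missing:
            raise ValueError(f"tree leaves missing from alignment: {sorted(missing)[:5]}")

    @classmethod
    def from_files(cls, alignment_path: str | Path, tree_path: str | Path,
                   model: str = "LG+FO+G12") -> "PhyloCTMC":
        return cls(read_alignment(alignment_path), read_tree(tree_path), model)

    def loglike(self, model: EvoModel | None = None,
                tree: PhyloTree | None = None) -> float:
        lnl, _ = log_likelihood(self.alignment, tree or self.tree,
                                model or self.model)
        return lnl

    def fit(self, **kwargs) -> "PhyloCTMCResults":
        """Maximize the likelihood (branch lengths + free model parameters)."""
        fit = optimize(self.alignment, self.tree, self.model, **kwargs)
        return PhyloCTMCResults(self, fit)

    def results_at(self, model: EvoModel, tree: PhyloTree | None = None
                   ) -> "PhyloCTMCResults":
        """Results object at fixed (already-fitted) parameter values."""
        use_tree = (tree or self.tree).copy()
        lnl, _ = log_likelihood(self.alignment, use_tree, model)
        from .phylolik import count_parameters
        fit = ModelFit(lnL=lnl, K=count_parameters(model, self.alignment.n_taxa),
                       N=self.alignment.n_columns, model=model.copy(),
                       tree=use_tree)
        return PhyloCTMCResults(self, fit)


class PhyloCTMCResults:
    """Fitted-model results: estimates, AIC/BIC, reconstructions, simulation."""

    def __init__(self, model: PhyloCTMC, fit: ModelFit) -> None:
        self.model = model
        self.fit = fit

    # -- estimates -----------------------------------------------------
    @property
    def llf(self) -> float:
        return self.fit.lnL

    @property
    def K(self) -> int:
        return self.fit.K

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def bic(self) -> float:
        return self.fit.bic

    @property
    def tree(self) -> PhyloTree:
        return self.fit.tree

    @property
    def evomodel(self) -> EvoModel:
        return self.fit.model

    def summary(self) -> pd.DataFrame:
        m = self.fit.model
        rows = [
            ("model", m.name),
            ("n_taxa", self.model.alignment.n_taxa),
            ("n_columns (N)", self.fit.N),
            ("log-likelihood", round(self.fit.lnL, 4)),
            ("free parameters (K)", self.fit.K),
            ("AIC (lnL - K)", round(self.fit.aic, 4)),
            ("BIC (lnL - K lnN/2)", round(self.fit.bic, 4)),
            ("tree length", round(float(np.nansum(self.fit.tree.branch_lengths)), 4)),
            ("converged", self.fit.converged),
            ("optimization rounds", self.fit.n_rounds),
        ]
        if m.has_gamma:
            rows.append(("gamma shape alpha", round(m.alpha, 4)))
            rows.append(("rate categories", m.n_rate_categories))
        if m.has_invariant:
            rows.append(("p_invariant", round(m.p_invariant, 4)))
        if m.free_frequencies:
            rows.append(("frequencies", "ML-optimized (FO)"))
        return pd.DataFrame(rows, columns=["statistic", "value"])

    # -- reconstruction ------------------------------------------------
    def reconstruct(self, node: str | int, mask: np.ndarray | None = None
                    ) -> ReconDistribution:
        """Marginal reconstruction at one node (leaf label or node index)."""
        return marginal_posterior(self.model.alignment, self.fit.tree,
                                  self.fit.model, node, mask=mask)

    def reconstruct_ancestors(self) -> dict[int, ReconDistribution]:
        return reconstruct_ancestors(self.model.alignment, self.fit.tree,
                                     self.fit.model)

    def esr(self, leaves: Sequence[str] | None = None
            ) -> dict[str, ReconDistribution]:
        """Sequence-wise CV reconstruction of every (or selected) leaves."""
        return esr_sequence_wise(self.model.alignment, self.fit.tree,
                                 self.fit.model, refit=False, leaves=leaves)

    def esr_site_wise(self, leaf: str, sites: Sequence[int] | None = None,
                      **kwargs) -> ReconDistribution:
        return esr_site_wise(self.model.alignment, self.fit.tree,
                             self.fit.model, leaf, sites, **kwargs)

    def stats(self, recon: ReconDistribution, true_seq=None):
        return sequence_stats(recon, true_seq)

    # -- simulation and export ------------------------------------------
    def simulate(self, n_sites: int, seed: int | None = None) -> SimulationResult:
        """Simulate new data under the fitted model on the fitted tree."""
        return simulate(self.fit.tree, self.fit.model, n_sites, seed=seed)

    def annotated_tree(self) -> str:
        """Newick with min-max normalized eLnP node labels (0..100)."""
        from .reconstats import elnp as _elnp
        recons = self.reconstruct_ancestors()
        elnp_by_node = {node: _elnp(r) for node, r in recons.items()}
        for label, recon in self.esr().items():
            elnp_by_node[self.fit.tree.node_by_label(label)] = _elnp(recon)
        return annotate_tree_elnp(self.fit.tree, elnp_by_node)
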