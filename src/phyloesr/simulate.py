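"""Substitution-only sequence simulation along a tree.

The simulator draws the root sequence from the model's equilibrium
frequencies, assigns each site a rate category once (shared down the whole
tree, the standard discrete-gamma assumption), and propagates child states
from parent states with the transition matrices P(rate * branch length).
True sequences are recorded at every internal node so reconstructions can
be validated against them.  No indels are generated: alignments are fixed
length and gap-free, matching the role of fixed-length simulation studies.

``simulation_study`` drives the replicate experiment: simulate under a
generating model, then fit a ladder of (possibly misspecified) models with
the topology fixed to the generating tree and tabulate reconstruction
statistics for ancestral and extant nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import N_STATES
from .evomodel import EvoModel, TransitionCalculator, build_rate_matrix
from .phylolik import ModelFit, optimize
from .reconstruct import ReconDistribution, esr_sequence_wise, reconstruct_ancestors, smp
from .reconstats import (avg_probability, elnp, expected_fraction_correct,
                         fraction_correct, sequence_lnp)
from .seqio import Alignment, PhyloTree


@dataclass
class SimulationResult:
    """Extant alignment plus the recorded truth of a simulation run."""

    alignment: Alignment
    ancestors: dict[int, np.ndarray]   # internal node index -> codes
    site_categories: np.ndarray
    seed: int
    model: EvoModel
    tree: PhyloTree

    def ancestor_alignment(self) -> Alignment:
        ids = [self.tree.labels[i] or f"node{i}" for i in self.ancestors]
        return Alignment(ids, np.vstack(list(self.ancestors.values())))


def random_coalescent_tree(n_taxa: int, seed=None, *, scale: float = 1.0,
                           prefix: str = "t") -> PhyloTree:
    """A random coalescent-style rooted binary tree with exponential waiting times.

    Branch lengths are in expected substitutions per site; under the
    default ``scale`` the expected root height is about ``2 * scale`` in
    coalescent units, giving moderately informative terminal branches.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    children: list[list[int]] = [[] for _ in range(2 * n_taxa - 1)]
    parent = np.full(2 * n_taxa - 1, -1, dtype=np.int64)
    heights = np.zeros(2 * n_taxa - 1)
    labels: list[str | None] = [None] * (2 * n_taxa - 1)
    active = list(range(n_taxa))
    for i in range(n_taxa):
        labels[i] = f"{prefix}{i + 1}"
    t = 0.0
    nxt = n_taxa
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1))) * scale
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        children[nxt] = [a, b]
        parent[a] = parent[b] = nxt
        heights[nxt] = t
        active = [n for n in active if n not in (a, b)] + [nxt]
        nxt += 1
    lengths = np.full(2 * n_taxa - 1, np.nan)
    for node in range(2 * n_taxa - 1):
        if parent[node] >= 0:
            lengths[node] = heights[parent[node]] - heights[node]
    return PhyloTree(children, parent, lengths, labels)


def simulate(tree: PhyloTree, model: EvoModel, n_sites: int,
             seed: int | None = None) -> SimulationResult:
    """Simulate a gap-free alignment (and all ancestral sequences) on ``tree``."""
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    rng = np.random.default_rng(seed)
    cats = model.rate_categories()
    calc = TransitionCalculator(build_rate_matrix(model), model.frequencies)
    site_cat = rng.choice(len(cats.rates), size=n_sites, p=cats.weights)
    site_rates = cats.rates[site_cat]
    pi = model.frequencies
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    root = tree.root
    states[root] = rng.choice(N_STATES, size=n_sites, p=pi)
    unique_rates = np.unique(site_rates)
    for node in tree.preorder():
        if node == root:
            continue
        t = tree.branch_lengths[node]
        parent_states = states[int(tree.parent[node])]
        child = np.empty(n_sites, dtype=np.int8)
        for r in unique_rates:
            sel = site_rates == r
            if r * t <= 0:
                child[sel] = parent_states[sel]
                continue
            P = calc(r * t)
            cum = np.cumsum(P[parent_states[sel]], axis=1)
            u = rng.random(int(sel.sum()))
            child[sel] = (u[:, None] > cum).sum(axis=1)
        states[node] = child
    leaf_ids, leaf_rows = [], []
    ancestors: dict[int, np.ndarray] = {}
    for node in range(tree.n_nodes):
        if tree.is_leaf[node]:
            leaf_ids.append(tree.labels[node])
            leaf_rows.append(states[node])
        else:
            ancestors[node] = states[node]
    aln = Alignment(leaf_ids, np.vstack(leaf_rows))
    return SimulationResult(aln, ancestors, site_cat,
                            seed if seed is not None else -1, model.copy(),
                            tree.copy())


def simulation_study(tree: PhyloTree, generating_model: EvoModel,
                     fitted_models: Sequence[EvoModel], *,
                     n_sites: int = 1000, n_replicates: int = 10,
                     seed: int | None = None, do_esr: bool = False,
                     fit_kwargs: dict | None = None) -> pd.DataFrame:
    """Replicate simulate-fit-reconstruct experiment.

    For each replicate, data are simulated under ``generating_model``; each
    model of the ladder is then fitted with the topology fixed to the
    generating tree, ancestors (and optionally extant sequences) are
    reconstructed, and per-node statistics are tabulated against the
    recorded truth.
    """
    rng = np.random.default_rng(seed)
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        sim = simulate(tree, generating_model, n_sites, seed=rep_seed)
        for model in fitted_models:
            fit = optimize(sim.alignment, tree, model, **fit_kwargs)
            recons = reconstruct_ancestors(sim.alignment, fit.tree, fit.model)
            records: list[tuple[ReconDistribution, np.ndarray, str]] = [
                (recon, sim.ancestors[node], "asr")
                for node, recon in recons.items()]
            if do_esr:
                esr = esr_sequence_wise(sim.alignment, fit.tree, fit.model,
                                        refit=False)
                records += [(recon, sim.alignment.row(label), "esr")
                            for label, recon in esr.items()]
            for recon, truth, kind in records:
                smp_seq = smp(recon)
                rows.append({
                    "replicate": rep, "seed": rep_seed, "model": model.name,
                    "kind": kind, "node": recon.node, "lnL": fit.lnL,
                    "avg_probability": avg_probability(smp_seq, recon),
                    "fraction_correct": fraction_correct(smp_seq, truth, recon),
                    "expected_fraction_correct": expected_fraction_correct(recon),
                    "lnp_smp": sequence_lnp(smp_seq, recon),
                    "lnp_true": sequence_lnp(truth, recon),
                    "elnp": elnp(recon),
                })
    return pd.DataFrame(rows)
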