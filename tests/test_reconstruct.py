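"""Marginal reconstruction, CV drivers, SMP, sampling, taxon pruning."""

import numpy as np
import pytest

import phyloesr as pe
from phyloesr.alphabet import AA_INDEX, GAP_CODE
from .conftest import joint_tensor_posteriors, random_reversible_model


class TestMarginalPosterior:
    def test_zero_branch_identity(self):
        tree = pe.PhyloTree.from_newick("(A:0.0,B:0.0);")
        aln = pe.Alignment.from_sequences(["A", "B"], ["K", "K"])
        rec = pe.marginal_posterior(aln, tree, pe.parse_model("Poisson+FQ"), "A")
        assert rec.probabilities[0, AA_INDEX["K"]] == pytest.approx(1.0, abs=1e-9)

    def test_long_branch_returns_prior(self):
        tree = pe.PhyloTree.from_newick("((A:1000,B:0.2):0.1,C:0.3);")
        aln = pe.Alignment.from_sequences(["A", "B", "C"], ["K", "R", "R"])
        model = pe.parse_model("LG+FO")
        rec = pe.marginal_posterior(aln, tree, model, "A")
        assert np.abs(rec.probabilities[0] - model.frequencies).max() < 1e-6

    def test_internal_node_matches_bayes_oracle(self, four_leaf_tree,
                                                four_leaf_aln):
        model = pe.parse_model("Poisson+FQ")
        _, oracle = joint_tensor_posteriors(four_leaf_aln, four_leaf_tree, model)
        for node in oracle:
            if four_leaf_tree.is_leaf[node]:
                continue
            rec = pe.marginal_posterior(four_leaf_aln, four_leaf_tree, model, node)
            assert np.abs(rec.probabilities - oracle[node]).max() < 1e-10

    def test_masked_leaf_matches_bayes_oracle(self, four_leaf_tree,
                                              four_leaf_aln):
        model = random_reversible_model(np.random.default_rng(14), gamma=True)
        _, oracle = joint_tensor_posteriors(four_leaf_aln, four_leaf_tree, model,
                                            masked_leaves={"B"})
        node = four_leaf_tree.node_by_label("B")
        rec = pe.marginal_posterior(four_leaf_aln, four_leaf_tree, model, "B")
        assert np.abs(rec.probabilities - oracle[node]).max() < 1e-8

    def test_unknown_node_rejected(self, four_leaf_tree, four_leaf_aln):
        with pytest.raises(KeyError):
            pe.marginal_posterior(four_leaf_aln, four_leaf_tree,
                                  pe.parse_model("Poisson+FQ"), "Z")


class TestWorkaroundEquivalence:
    def test_masking_equals_long_branch_daughters(self):
        # grafting two daughters at branch length 1000 (one poly-Leu, one the
        # original sequence) onto the internalized tip reproduces the native
        # masked-leaf posterior
        rng = np.random.default_rng(3)
        model = pe.parse_model("LG+FO+G12")
        model.alpha = 1.2
        tree = pe.PhyloTree.from_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.4):0.25);")
        aln = pe.Alignment.from_sequences(["A", "B", "C", "D"],
                                          ["ARN", "RRC", "ARC", "AKC"])
        native = pe.marginal_posterior(aln, tree, model, "A")
        graft = pe.PhyloTree.from_newick(
            "(((X:1000,Y:1000)A2:0.2,B:0.3):0.1,(C:0.15,D:0.4):0.25);")
        graft_aln = pe.Alignment.from_sequences(
            ["X", "Y", "B", "C", "D"], ["ARN", "LLL", "RRC", "ARC", "AKC"])
        engine = pe.PruningEngine(graft_aln, graft, model)
        post = engine.posterior(graft.node_by_label("A2"))
        assert np.abs(native.probabilities - post).max() < 1e-6


class TestSequenceWiseCV:
    def test_all_gap_leaf_mask_is_noop(self):
        tree = pe.PhyloTree.from_newick("((A:0.2,B:0.3):0.1,C:0.3);")
        aln = pe.Alignment.from_sequences(["A", "B", "C"], ["---", "RRC", "ARC"])
        model = pe.parse_model("LG+FQ")
        masked = pe.marginal_posterior(aln, tree, model, "A")
        unmasked = pe.marginal_posterior(
            aln, tree, model, "A", mask=np.zeros(3, dtype=bool))
        assert masked.probabilities == pytest.approx(unmasked.probabilities)

    def test_posteriors_normalized(self):
        tree = pe.random_coalescent_tree(6, seed=41)
        sim = pe.simulate(tree, pe.parse_model("LG+FQ"), 30, seed=42)
        recons = pe.esr_sequence_wise(sim.alignment, tree,
                                      pe.parse_model("LG+FQ"), refit=False)
        for rec in recons.values():
            sums = rec.probabilities[rec.unmasked_sites].sum(axis=1)
            assert sums == pytest.approx(np.ones(len(sums)), abs=1e-10)


class TestSiteWiseCV:
    def test_fixed_parameters_reduce_to_sequence_wise(self):
        tree = pe.random_coalescent_tree(5, seed=51)
        sim = pe.simulate(tree, pe.parse_model("Poisson+FQ"), 12, seed=52)
        aln = sim.alignment
        leaf = aln.ids[0]
        model = pe.parse_model("Poisson+FQ")
        seqwise = pe.esr_sequence_wise(aln, tree, model, refit=False)[leaf]
        sitewise = pe.esr_site_wise(aln, tree, model, leaf, reoptimize=False)
        sites = sitewise.unmasked_sites
        assert np.abs(sitewise.probabilities[sites]
                      - seqwise.probabilities[sites]).max() < 1e-12

    def test_close_to_sequence_wise_with_reoptimization(self):
        tree = pe.random_coalescent_tree(8, seed=53)
        sim = pe.simulate(tree, pe.parse_model("Poisson+FQ"), 30, seed=54)
        aln = sim.alignment
        leaf = aln.ids[0]
        truth = aln.row(leaf)
        fit = pe.optimize(aln, tree, pe.parse_model("Poisson+FQ"))
        seqwise = pe.esr_sequence_wise(aln, fit.tree, fit.model,
                                       refit=False)[leaf]
        sites = list(range(10))
        sitewise = pe.esr_site_wise(aln, fit.tree, fit.model, leaf, sites,
                                    reoptimize=True)
        deltas = [abs(sitewise.probabilities[s, truth[s]]
                      - seqwise.probabilities[s, truth[s]])
                  for s in sitewise.unmasked_sites]
        assert np.mean(deltas) < 0.01

    def test_sequence_wise_lnp_dominates_site_wise(self):
        # withholding the whole sequence leaks strictly less information than
        # withholding one site, so the site-wise true-sequence LnP should be
        # lower for (nearly) every sequence
        tree = pe.random_coalescent_tree(6, seed=55)
        sim = pe.simulate(tree, pe.parse_model("Poisson+FQ"), 25, seed=56)
        aln = sim.alignment
        fit = pe.optimize(aln, tree, pe.parse_model("Poisson+FQ"))
        wins = 0
        for leaf in aln.ids:
            seqwise = pe.esr_sequence_wise(aln, fit.tree, fit.model,
                                           refit=False)[leaf]
            sitewise = pe.esr_site_wise(aln, fit.tree, fit.model, leaf,
                                        reoptimize=True)
            truth = aln.row(leaf)
            wins += (pe.sequence_lnp(truth, seqwise)
                     >= pe.sequence_lnp(truth, sitewise) - 1e-9)
        assert wins >= 0.95 * len(aln.ids)


class TestSmp:
    def _recon(self, probs):
        probs = np.asarray(probs, dtype=float)
        return pe.ReconDistribution("x", probs,
                                    np.zeros(len(probs), dtype=bool))

    def test_argmax_and_probability(self):
        site = np.zeros(20)
        site[AA_INDEX["A"]], site[AA_INDEX["C"]] = 0.7, 0.3
        s = pe.smp(self._recon([site]))
        assert s.sequence == "A"
        assert s.site_probabilities[0] == pytest.approx(0.7)

    def test_exact_tie_breaks_to_first_alphabet_index(self):
        site = np.zeros(20)
        site[AA_INDEX["R"]] = site[AA_INDEX["N"]] = 0.5
        s = pe.smp(self._recon([site]))
        assert s.sequence == "R"  # R precedes N in ARND... order
        assert s.ties == [0]

    def test_smp_lnp_bounds_sampled_lnp(self):
        rng = np.random.default_rng(61)
        recon = self._recon(rng.dirichlet(np.ones(20), size=40))
        smp_lnp = pe.sequence_lnp(pe.smp(recon), recon)
        samples = pe.sample_sequences(recon, 1000, seed=62)
        assert all(pe.sequence_lnp(s, recon) <= smp_lnp + 1e-12 for s in samples)


class TestSampling:
    def _recon(self, probs):
        probs = np.asarray(probs, dtype=float)
        return pe.ReconDistribution("x", probs,
                                    np.zeros(len(probs), dtype=bool))

    def test_degenerate_distribution_reproduces_smp(self):
        probs = np.zeros((8, 20))
        probs[np.arange(8), np.arange(8)] = 1.0
        recon = self._recon(probs)
        smp_codes = pe.smp(recon).codes
        for s in pe.sample_sequences(recon, 20, seed=1):
            assert (s.codes == smp_codes).all()

    def test_altall_picks_second_above_threshold(self):
        site = np.zeros(20)
        site[AA_INDEX["A"]], site[AA_INDEX["R"]] = 0.55, 0.45
        low = np.zeros(20)
        low[AA_INDEX["K"]], low[AA_INDEX["E"]] = 0.85, 0.15
        recon = self._recon([site, low])
        (alt,) = pe.sample_sequences(recon, mode="altall", threshold=0.2)
        assert alt.sequence == "RK"  # second residue where p>0.2, else SMP

    def test_biased_sampling_restricted_support(self):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(20) * 0.5, size=30)
        recon = self._recon(probs)
        for s in pe.sample_sequences(recon, 50, mode="biased",
                                     threshold=0.2, seed=8):
            drawn_p = probs[np.arange(30), s.codes]
            smp_codes = pe.smp(recon).codes
            ok = (drawn_p >= 0.2) | (s.codes == smp_codes)
            assert ok.all()

    def test_seeded_runs_reproducible(self):
        rng = np.random.default_rng(9)
        recon = self._recon(rng.dirichlet(np.ones(20), size=25))
        a = pe.sample_sequences(recon, 10, seed=123)
        b = pe.sample_sequences(recon, 10, seed=123)
        assert all((x.codes == y.codes).all() for x, y in zip(a, b))

    def test_unbiased_identity_matches_distribution_expectation(self):
        # mean fraction-identical-to-truth over unbiased samples converges to
        # the distribution-level expected fraction correct
        rng = np.random.default_rng(10)
        probs = rng.dirichlet(np.ones(20) * 0.3, size=60)
        recon = self._recon(probs)
        truth = pe.sample_sequences(recon, 1, seed=11)[0].codes
        expected = float(probs[np.arange(60), truth].mean())
        samples = pe.sample_sequences(recon, 4000, seed=12)
        fracs = [np.mean(s.codes == truth) for s in samples]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 4 * se + 1e-3

    def test_invalid_mode_rejected(self):
        rng = np.random.default_rng(13)
        recon = self._recon(rng.dirichlet(np.ones(20), size=5))
        with pytest.raises(ValueError):
            pe.sample_sequences(recon, 1, mode="magic")


class TestPruning:
    def test_splice_arithmetic(self):
        tree = pe.PhyloTree.from_newick("((A:1,B:1):1,(C:0.1,D:1):1);")
        aln = pe.Alignment.from_sequences(list("ABCD"), ["A", "R", "N", "D"])
        pruned, paln = pe.prune_leaves(tree, aln, ["C"])
        d = pruned.leaf_distances()
        assert d[("A", "D")] == pytest.approx(4.0)  # 1 + 1 + (1 + 1)
        assert sorted(paln.ids) == ["A", "B", "D"]

    def test_pairwise_distances_preserved(self):
        tree = pe.random_coalescent_tree(12, seed=71)
        aln = pe.Alignment(list(tree.leaf_labels),
                           np.zeros((12, 5), dtype=np.int8))
        before = tree.leaf_distances()
        series = pe.prune_short_branches(tree, aln, 4)
        pruned_tree, _, removed = series[-1]
        after = pruned_tree.leaf_distances()
        for pair, dist in after.items():
            assert dist == pytest.approx(before[pair], rel=1e-12)

    def test_shortest_terminal_branches_removed_first(self):
        tree = pe.random_coalescent_tree(10, seed=72)
        aln = pe.Alignment(list(tree.leaf_labels),
                           np.zeros((10, 5), dtype=np.int8))
        terminal = {tree.labels[i]: tree.branch_lengths[i]
                    for i in range(tree.n_nodes) if tree.is_leaf[i]}
        _, _, removed = pe.prune_short_branches(tree, aln, 1)[-1]
        assert terminal[removed[0]] == min(terminal.values())

    def test_over_pruning_rejected(self):
        tree = pe.random_coalescent_tree(6, seed=73)
        aln = pe.Alignment(list(tree.leaf_labels),
                           np.zeros((6, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            pe.prune_short_branches(tree, aln, 5)
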