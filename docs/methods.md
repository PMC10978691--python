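# Methods

## The problem

Ancestral sequence reconstruction (ASR) infers, for an internal node of a
phylogeny, a per-site posterior distribution over the 20 amino acids given a
multiple sequence alignment, a tree, and a probabilistic model of sequence
evolution. Its accuracy is hard to validate because true ancestral proteins
are unobservable. Extant sequence reconstruction (ESR) turns the same
machinery onto *terminal* nodes: a modern sequence is withheld, the model
predicts it from the remaining sequences, and the prediction can be compared
with the known truth. Under a time-reversible model there is no mathematical
distinction between ancestor and descendant, so extant reconstructions share
the statistical character of ancestral ones while being directly testable.

## Model

Sequence evolution is a reversible continuous-time Markov chain on the 20
amino acids, independent across sites, homogeneous across the tree. The rate
matrix is the general time-reversible construction

    Q_ij = s_ij * pi_j   (i != j),       Q_ii = -sum_{j != i} Q_ij,

rescaled so that the expected substitution rate at equilibrium,
`-sum_i pi_i Q_ii`, is 1; branch lengths are then expected substitutions per
site. Supported exchangeability matrices `s`: **Poisson** (all off-diagonal
entries equal), **LG** (the published Le–Gascuel matrix, shipped as
plain-text package data), and **GTR20** (all exchangeabilities free, one
fixed at 1 for identifiability, i.e. 189 free). Equilibrium frequencies are
either fixed uniform (`+FQ`) or free (`+FO`), optimized by maximum
likelihood through an unconstrained 19-dimensional log-ratio (softmax)
reparameterization — not set to observed counts, though observed counts are
the starting value. Among-site rate variation is a discrete-gamma mixture
(`+G12`: 12 equal-probability categories, each represented by its
conditional bin mean via the incomplete-gamma identity, renormalized so the
discrete mean is exactly 1), optionally with a proportion of invariant
sites (`+I`, a rate-0 category; the remaining categories are rescaled by
1/(1-p_inv) so the mixture mean stays 1 — with p_inv = 0 the likelihood
reduces exactly to the no-I model).

Transition probabilities P(t) = exp(Qt) are computed by symmetric
eigendecomposition of `diag(pi)^(1/2) Q diag(pi)^(-1/2)`, which is exact and
stable for reversible Q; round-off negatives are clamped to 0 and rows
renormalized.

## Likelihood and fitting

The alignment likelihood on a fixed topology is computed by Felsenstein
pruning with per-site, per-category conditional ("inside") partial vectors
and per-node rescaling with log accumulators (faster than full log-space
for 20-state vectors). Gaps are missing data: a gapped site contributes a
unit partial vector, so deleting a residue and gapping it are the same
operation. Rate categories are integrated with their mixture weights.

`optimize` fits branch lengths and free model parameters with the topology
fixed (topology search is delegated to external tools; all claims here
concern reconstruction *given* a topology). Each round:

1. **Branch sweeps.** Outside partial vectors are propagated root-to-tip
   once per sweep; each branch is then optimized by bounded scalar search
   against the cached inside/outside partials. The per-branch profile
   likelihood is unimodal but flattens into the equilibrium plateau at
   large t, so a coarse log-spaced scan brackets the optimum before the
   bounded refine; a result worse than the current value is never accepted,
   and a sweep that lowers the full likelihood (possible because partials
   above an updated branch are stale within a sweep) is reverted. Sweeps
   repeat until the gain falls below a coarse inner threshold (0.01 nats,
   dropping to the full tolerance once the model parameters have
   converged).
2. **Model parameters.** Frequencies, gamma shape, invariant fraction and
   GTR exchangeabilities are optimized jointly by L-BFGS-B on transformed
   coordinates (log-ratio frequencies, log alpha, logit p_inv, log
   exchangeability ratios) with numeric gradients, a bounded number of
   iterations per round, and acceptance only on improvement. Once a
   parameter block stops improving by the tolerance it is skipped.

Rounds repeat until the round-to-round improvement is below `tol`
(default 1e-4 nats; max 100 rounds; branch-length bounds [1e-8, 100]). The
log-likelihood history is non-decreasing by construction. Fits of a rooted
binary tree have one flat direction (only the sum of the two root-child
branch lengths is identified, by reversibility); this affects neither the
maximized likelihood nor any leaf reconstruction, and the parameter count
uses the identifiable 2n-3.

Model selection uses the penalized log-likelihood conventions
`AIC = lnL - K` and `BIC = lnL - K ln(N)/2` (larger is better), with
`K = (2 n_taxa - 3) + 19·[FO] + 1·[G] + 1·[I] + 189·[GTR20]` and N the
alignment column count. These K conventions are pinned deliberately —
tools differ in whether they count frequencies — because they are the ones
under which the published L/MDH and terpene synthase selection tables are
internally consistent.

## Reconstruction

The marginal reconstruction at a node is the per-site posterior over states
with all other hidden nodes integrated out, computed from the product of
inside and outside partials and normalized per site, with rate-category
uncertainty integrated under the mixture weights. For a terminal node the
leaf's own observations are masked (treated as missing), so the posterior
conditions only on the other sequences. This native masking is
mathematically equivalent to the workaround of grafting two daughter nodes
on branches of length 1000 onto the internalized tip (such branches
transmit no information) and is simpler, faster, and numerically cleaner;
the equivalence is kept as a test. One caveat, exercised deliberately in
the test-suite: a length-1000 branch only saturates when every rate
category is appreciably fast. With 12-category gamma the slowest category
has relative rate ~0.04 at alpha = 1 (saturated), but for alpha well below
1, or with an invariant-sites category (rate 0), the grafted daughters leak
information and the two constructions genuinely differ — another reason to
prefer native masking.

**Sequence-wise CV** fits the model once on the full alignment, then
reconstructs each leaf with its whole sequence masked, keeping the
full-data ML tree and parameters. **Site-wise CV** deletes one residue,
re-optimizes branch lengths and continuous model parameters on the reduced
alignment (topology fixed — a one-residue deletion is assumed not to change
the ML topology), and reconstructs that site alone; it is the stricter
protocol but costs one fit per residue. With parameters held at the
full-data ML values, site-wise reduces exactly to sequence-wise.

The **SMP** (single most probable) sequence takes the argmax residue per
unmasked site, breaking exact ties deterministically toward the lower
alphabet index (ties are recorded). Alternative sequences come from
unbiased per-site sampling, biased sampling (support restricted to residues
with probability >= a threshold, renormalized; sites with empty restricted
support fall back to the SMP residue), or the deterministic AltAll sequence
(second most probable residue wherever its probability exceeds the
threshold, default 0.2).

## Statistics

For a reconstruction with per-site distributions p(.)_j over unmasked
sites j (natural logs throughout):

- `LnP(seq) = sum_j ln p(a_j)_j` — log-probability of a specific sequence.
- `eLnP = sum_j sum_k p(a_k)_j ln p(a_k)_j` — the expected LnP of a
  sampled sequence; equals the negative Shannon entropy and estimates the
  true sequence's LnP without knowing the truth.
- Average probability of a sequence = `mean_j p(a_j)_j` — its expected
  fraction of correct residues.
- Distribution-level expected fraction correct = `sum_j sum_k p^2 / N_i`,
  the probability-weighted average over all sampleable sequences; site-wise
  `sum_k p^2 <= max_k p`, so it never exceeds the SMP's average
  probability. N_i counts unmasked (ungapped) sites only, the same
  convention used for every "fraction correct" denominator.
- The number of mistakes implied by per-site success probabilities follows
  a Poisson-binomial distribution, computed exactly by iterative
  convolution (mean `sum(1-p)`, variance `sum p(1-p)`).
- Chemical dissimilarity uses Grantham's distance, generated from the
  published formula `d = rho * sqrt(1.833 dc^2 + 0.1018 dp^2 +
  0.000399 dv^2)` over composition, polarity and volume with rho = 50.723
  (mean pairwise distance 100); the canonical rounded table serves as a
  checksum in the tests. Totals can be normalized per realized mistake or
  per expected mistake.
- Column entropy is the Shannon entropy of observed residue frequencies in
  an alignment column, gaps excluded.
- Calibration regressions (actual vs expected fraction correct; true LnP vs
  eLnP) are ordinary least squares, with an added equal-width binned
  reliability table (bins merged below 20 points) as a diagnostic the
  line fit alone does not give.

## Simulator

The simulator draws the root sequence from the equilibrium frequencies,
assigns each site one rate category for the whole tree (the standard
discrete-gamma assumption, and required for refitting consistency), and
propagates child states with P(rate × branch length). All ancestral
sequences and the category assignments are recorded. No indels are
generated — alignments are fixed-length and gap-free — so simulated data
never exercise the gap-handling path; gaps enter only through real
alignments. Substitution-only simulation also means tests on simulated data
say nothing about alignment error, a real-data complication that is out of
scope here. Random trees are coalescent-style (exponential waiting times),
giving realistic short-terminal-branch topology variation; a scale knob
multiplies all lengths.

Default study conditions mirror the replicate experiment this package is
built around: generating model LG+FO+G12 with the published LG frequencies
as the "optimized" truth and gamma shape alpha = 0.8 (a typical fitted
value for divergent protein families), 1000-residue alignments, 10
replicates. The calibration experiments in the tests and the acceptance
script use one replicate of 64 taxa × 300 sites (and 16 × 200 for the
replicated misspecification contrast), sizes chosen so the full
simulate–fit–reconstruct loop runs in minutes while leaving the qualitative
behaviour unchanged.

## Tree annotation and pruning

For visualization, the eLnP of every internal and terminal reconstruction
is min–max normalized to [0, 100] in one pooled scaling (constant input
degenerates to 50 for all nodes, with a warning) and written into the
Newick output — internal nodes in the label slot, leaves as a
FigTree-style `[&label=...]` comment. Branch lengths are emitted to 10
significant digits so read–write round-trips are stable.

The taxon-pruning experiment iteratively removes the leaf with the
shortest terminal branch; the resulting degree-2 node is spliced out with
its incident branch lengths summed, so all pairwise path lengths among
survivors are preserved exactly.

## Numerical choices and edge cases

- Per-site rescaling of partials uses one scalar per site shared across
  rate categories, so category mixing and posterior normalization remain
  exact.
- `0 ln 0 := 0` in entropies; LnP of a zero-probability residue is -inf
  (reported, not raised).
- Posterior rows at gap-masked sites carry no distribution and are zeroed.
- An all-gap alignment column contributes exactly zero log-likelihood.
- A two-leaf tree with identical sequences drives the joined branch length
  to its lower bound (1e-8).
- Biased sampling at a site where no residue reaches the threshold falls
  back to the SMP residue and logs the event.

## Known limitations

- Topology inference, alignment construction, indel models, and
  site-heterogeneous (CAT-style) or codon models are out of scope.
- Site-wise CV re-optimizes continuous parameters only; a per-deletion
  topology re-search is not attempted.
- GTR20 fitting (189 free exchangeabilities) uses the same numeric-gradient
  machinery as the small models; it is correct but slow, and intended for
  datasets large enough to inform that many parameters.
- The coordinate-descent fit guarantees a non-decreasing likelihood and
  matches enumeration oracles on small instances, but like all multimodal
  ML fits it can in principle stop at a local optimum on pathological
  data.
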