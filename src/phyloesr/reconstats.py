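"""Reconstruction-quality statistics.

Sequence-level statistics compare a specific sequence with a reconstruction
distribution: its log-probability LnP = sum_j ln p(a_j), its average
residue probability (the expected fraction of correct residues for that
sequence), and the Grantham chemical distance to another sequence.
Distribution-level statistics summarize the whole reconstruction: the
expected log-probability eLnP = sum_j sum_k p ln p (the negative Shannon
entropy, natural log), the expected fraction correct sum_j sum_k p^2 / N,
the expected Grantham distance to the true sequence, and the exact
Poisson-binomial distribution of the number of mistakes implied by per-site
success probabilities.

The Grantham dissimilarity matrix is generated from Grantham's published
formula and amino-acid property values (composition, polarity, molecular
volume) rather than transcribed; the canonical rounded table is used as a
checksum in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .alphabet import AMINO_ACIDS, GAP_CODE, N_STATES, encode
from .reconstruct import ReconDistribution, SmpSequence, smp
from .seqio import Alignment


class PairingError(ValueError):
    """Sequence/distribution length mismatch."""


# ---------------------------------------------------------------------------
# Grantham distance
# ---------------------------------------------------------------------------

# composition (atomic weight ratio of hetero elements), polarity, volume
_GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}
_GRANTHAM_WEIGHTS = (1.833, 0.1018, 0.000399)  # alpha, beta, gamma
_GRANTHAM_SCALE = 50.723  # sets the mean pairwise distance to 100


def grantham_matrix() -> np.ndarray:
    """The symmetric 20x20 Grantham dissimilarity in alphabet order."""
    c = np.array([_GRANTHAM_PROPERTIES[a][0] for a in AMINO_ACIDS])
    p = np.array([_GRANTHAM_PROPERTIES[a][1] for a in AMINO_ACIDS])
    v = np.array([_GRANTHAM_PROPERTIES[a][2] for a in AMINO_ACIDS])
    al, be, ga = _GRANTHAM_WEIGHTS
    D = np.sqrt(al * np.subtract.outer(c, c) ** 2
                + be * np.subtract.outer(p, p) ** 2
                + ga * np.subtract.outer(v, v) ** 2) * _GRANTHAM_SCALE
    np.fill_diagonal(D, 0.0)
    return D


_GD: np.ndarray | None = None


def _gd() -> np.ndarray:
    global _GD
    if _GD is None:
        _GD = grantham_matrix()
    return _GD


def _codes(seq: str | np.ndarray | SmpSequence) -> np.ndarray:
    if isinstance(seq, SmpSequence):
        return seq.codes
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.int8)


# ---------------------------------------------------------------------------
# Sequence statistics
# ---------------------------------------------------------------------------

def sequence_lnp(seq, recon: ReconDistribution) -> float:
    """Natural-log probability of a specific sequence under a reconstruction.

    Summed over unmasked sites; -inf if any chosen residue has probability
    zero.
    """
    codes = _codes(seq)
    if len(codes) != recon.n_sites:
        raise PairingError("sequence length does not match the distribution")
    sites = recon.unmasked_sites
    p = recon.probabilities[sites, codes[sites]]
    if (codes[sites] == GAP_CODE).any():
        raise PairingError("sequence is gapped at an unmasked site")
    with np.errstate(divide="ignore"):
        return float(np.log(p).sum())


def elnp(recon: ReconDistribution) -> float:
    """Expected log-probability: sum p ln p over unmasked sites (0 ln 0 = 0).

    Equals the negative Shannon entropy (natural log) of the reconstruction,
    and estimates the LnP of the true sequence.
    """
    P = recon.probabilities[recon.unmasked_sites]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return float(terms.sum())


def avg_probability(seq, recon: ReconDistribution) -> float:
    """Average residue probability of ``seq``: its expected fraction correct."""
    codes = _codes(seq)
    sites = recon.unmasked_sites
    if len(sites) == 0:
        raise ValueError("empty sequence: no unmasked sites")
    if len(codes) != recon.n_sites:
        raise PairingError("sequence length does not match the distribution")
    return float(recon.probabilities[sites, codes[sites]].mean())


def expected_fraction_correct(recon: ReconDistribution) -> float:
    """Distribution-level expected fraction correct: mean_j sum_k p_jk^2.

    The sequence-probability-weighted average, over all possible sampled
    sequences, of each sequence's expected fraction correct.
    """
    sites = recon.unmasked_sites
    if len(sites) == 0:
        raise ValueError("empty reconstruction: no unmasked sites")
    P = recon.probabilities[sites]
    return float((P ** 2).sum() / len(sites))


def fraction_correct(seq, true_seq, recon: ReconDistribution | None = None
                     ) -> float:
    """Fraction of residues of ``seq`` matching ``true_seq``.

    Compared over unmasked sites of ``recon`` when given, else over sites
    ungapped in both sequences.
    """
    a, b = _codes(seq), _codes(true_seq)
    if len(a) != len(b):
        raise PairingError("sequence length mismatch")
    if recon is not None:
        sites = recon.unmasked_sites
    else:
        sites = np.flatnonzero((a != GAP_CODE) & (b != GAP_CODE))
    if len(sites) == 0:
        raise ValueError("no comparable sites")
    return float((a[sites] == b[sites]).mean())


# ---------------------------------------------------------------------------
# Mistakes
# ---------------------------------------------------------------------------

def mistake_distribution(site_probabilities: np.ndarray) -> np.ndarray:
    """Exact Poisson-binomial pmf of the number of mistakes.

    ``site_probabilities`` are per-site probabilities of being *correct*;
    entry m of the returned vector is P(m mistakes).  Computed by iterative
    convolution; the mean is sum(1-p) and the variance sum p(1-p).
    """
    p = np.asarray(site_probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("site probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pj in p:
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * pj          # correct: mistake count unchanged
        nxt[1:] += pmf * (1.0 - pj)   # mistake
        pmf = nxt
    return pmf


def mistake_moments(site_probabilities: np.ndarray) -> tuple[float, float]:
    """Mean and standard deviation of the number of mistakes."""
    p = np.asarray(site_probabilities, dtype=float)
    return float((1 - p).sum()), float(np.sqrt((p * (1 - p)).sum()))


# ---------------------------------------------------------------------------
# Grantham statistics
# ---------------------------------------------------------------------------

def grantham_distance(seq_a, seq_b, *, per_mistake: bool = False) -> float:
    """Total Grantham distance between two sequences (gapped sites skipped).

    With ``per_mistake`` the total is divided by the number of differing
    sites (0 if the sequences agree everywhere).
    """
    a, b = _codes(seq_a), _codes(seq_b)
    if len(a) != len(b):
        raise PairingError("sequence length mismatch")
    sites = (a != GAP_CODE) & (b != GAP_CODE)
    total = float(_gd()[a[sites], b[sites]].sum())
    if per_mistake:
        n_mistakes = int((a[sites] != b[sites]).sum())
        return total / n_mistakes if n_mistakes else 0.0
    return total


def expected_grantham(recon: ReconDistribution, true_seq, *,
                      per_expected_mistake: bool = False) -> float:
    """Expected Grantham distance of the reconstruction to the true sequence.

    Weights d(true_j, k) by p(k)_j over all residues k and unmasked sites j.
    With ``per_expected_mistake`` the total is divided by the expected
    number of mistakes sum_j (1 - p(true_j)_j).
    """
    codes = _codes(true_seq)
    if len(codes) != recon.n_sites:
        raise PairingError("sequence length does not match the distribution")
    sites = recon.unmasked_sites
    P = recon.probabilities[sites]
    D = _gd()[codes[sites]]            # (n_sites, 20): row = d(true_j, .)
    total = float((P * D).sum())
    if per_expected_mistake:
        exp_mistakes = float((1.0 - P[np.arange(len(sites)), codes[sites]]).sum())
        return total / exp_mistakes if exp_mistakes > 0 else 0.0
    return total


def column_entropy(aln: Alignment, column: int) -> float:
    """Shannon entropy (nats) of the amino-acid frequencies in one column."""
    col = aln.matrix[:, column]
    col = col[col != GAP_CODE]
    if len(col) == 0:
        raise ValueError(f"column {column} is all gaps")
    counts = np.bincount(col, minlength=N_STATES).astype(float)
    f = counts[counts > 0] / counts.sum()
    return float(-(f * np.log(f)).sum())


# ---------------------------------------------------------------------------
# Aggregate statistics and calibration
# ---------------------------------------------------------------------------

@dataclass
class SequenceStats:
    """All per-reconstruction summary statistics in one record."""

    node: str
    lnp_smp: float
    lnp_true: float | None
    elnp: float
    avg_probability_smp: float
    expected_fraction_correct: float
    fraction_correct: float | None
    n_correct: int | None
    grantham_smp: float | None
    expected_grantham: float | None
    expected_mistakes_mean: float
    expected_mistakes_sd: float


def sequence_stats(recon: ReconDistribution,
                   true_seq=None) -> SequenceStats:
    """Compute the full statistics record for one reconstruction."""
    smp_seq = smp(recon)
    sites = recon.unmasked_sites
    mean_m, sd_m = mistake_moments(smp_seq.site_probabilities[sites])
    stats = SequenceStats(
        node=recon.node,
        lnp_smp=sequence_lnp(smp_seq, recon),
        lnp_true=None,
        elnp=elnp(recon),
        avg_probability_smp=avg_probability(smp_seq, recon),
        expected_fraction_correct=expected_fraction_correct(recon),
        fraction_correct=None,
        n_correct=None,
        grantham_smp=None,
        expected_grantham=None,
        expected_mistakes_mean=mean_m,
        expected_mistakes_sd=sd_m,
    )
    if true_seq is not None:
        codes = _codes(true_seq)
        stats.lnp_true = sequence_lnp(codes, recon)
        stats.fraction_correct = fraction_correct(smp_seq, codes, recon)
        stats.n_correct = int((smp_seq.codes[sites] == codes[sites]).sum())
        stats.grantham_smp = grantham_distance(smp_seq.codes, codes)
        stats.expected_grantham = expected_grantham(recon, codes)
    return stats


def calibration(expected: np.ndarray, actual: np.ndarray, *,
                n_bins: int = 10, min_per_bin: int = 20
                ) -> dict[str, object]:
    """OLS regression of actual on expected fraction correct + reliability bins.

    Returns slope, intercept, r-squared and a binned reliability table
    (equal-width probability bins, neighbours merged until each holds at
    least ``min_per_bin`` points).
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(actual, dtype=float)
    if len(x) < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.var(x) <= 1e-14:
        raise ValueError("degenerate regression: no variance in expected values")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    pending_mask = np.zeros(len(x), dtype=bool)
    for b in range(n_bins):
        pending_mask |= idx == b
        if pending_mask.sum() >= min_per_bin or b == n_bins - 1:
            if pending_mask.any():
                rows.append({"n": int(pending_mask.sum()),
                             "expected_mean": float(x[pending_mask].mean()),
                             "actual_mean": float(y[pending_mask].mean())})
            pending_mask = np.zeros(len(x), dtype=bool)
    return {"slope": float(res.params[1]), "intercept": float(res.params[0]),
            "r_squared": float(res.rsquared), "n": len(x),
            "reliability": pd.DataFrame(rows)}


def plot_tables(recon: ReconDistribution, true_seq, samples,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-cloud tables: LnP vs differences-from-SMP and vs mistakes.

    Returns two DataFrames with one row per sampled sequence plus rows for
    the SMP sequence, the true sequence, and the distribution expectation
    (LnP = eLnP; differences/mistakes = the appropriate expected counts).
    """
    smp_seq = smp(recon)
    sites = recon.unmasked_sites
    true_codes = _codes(true_seq)

    def diffs(codes: np.ndarray, ref: np.ndarray) -> int:
        return int((codes[sites] != ref[sites]).sum())

    rows_eick, rows_truth = [], []
    for i, s in enumerate(samples):
        lnp = sequence_lnp(s, recon)
        rows_eick.append({"sequence": f"sample{i}", "kind": "sample",
                          "lnp": lnp, "differences_from_smp": diffs(s.codes, smp_seq.codes)})
        rows_truth.append({"sequence": f"sample{i}", "kind": "sample",
                           "lnp": lnp, "mistakes": diffs(s.codes, true_codes)})
    lnp_smp = sequence_lnp(smp_seq, recon)
    lnp_true = sequence_lnp(true_codes, recon)
    exp_mistakes_smp, _ = mistake_moments(smp_seq.site_probabilities[sites])
    exp_mistakes_dist = len(sites) * (1.0 - expected_fraction_correct(recon))
    rows_eick += [
        {"sequence": "SMP", "kind": "smp", "lnp": lnp_smp, "differences_from_smp": 0},
        {"sequence": "true", "kind": "true", "lnp": lnp_true,
         "differences_from_smp": diffs(true_codes, smp_seq.codes)},
        {"sequence": "expectation", "kind": "expected", "lnp": elnp(recon),
         "differences_from_smp": exp_mistakes_smp},
    ]
    rows_truth += [
        {"sequence": "SMP", "kind": "smp", "lnp": lnp_smp,
         "mistakes": diffs(smp_seq.codes, true_codes)},
        {"sequence": "true", "kind": "true", "lnp": lnp_true, "mistakes": 0},
        {"sequence": "expectation", "kind": "expected", "lnp": elnp(recon),
         "mistakes": exp_mistakes_dist},
    ]
    return pd.DataFrame(rows_eick), pd.DataFrame(rows_truth)
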