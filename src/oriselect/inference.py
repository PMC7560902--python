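"""Motif inference from selection count data: enrichment ratio (ER) and
mutual-information maximization (IM).

ER inference is the standard log-odds estimator for massively parallel
selection experiments,

    theta_bl_ER = log2( f_bl_selected / f_bl_library ),

with base fractions f computed from read-count-weighted base occurrences
at each position, using a pseudocount of 1 (so theta is finite even for
bases absent from a sample).  ER is unbiased only when the selected read
count is a fixed exponential-like function of activity; any monotone
distortion of the selection scale (saturation, varying rounds of growth,
amplification bias) biases it.

IM inference instead seeks the matrix model theta that maximizes the
mutual information between a sequence's predicted activity and the
sample (library vs selected) it was observed in,

    I(theta) = sum_samples p(sample) sum_a p(a|sample) log2[ p(a|sample) / p(a) ],

where the activity distributions are estimated by replacing the combined
samples' activities by their ranks, binning the ranks into equipopulated
bins (default 1000), and smoothing each sample's read-count histogram
over bins with a Gaussian kernel (default sigma = 20 bins, truncated and
renormalized at the edges so probability mass is conserved).  Because
only activity *ranks* enter, I(theta) — and hence the IM estimate — is
exactly invariant under any strictly increasing distortion of the
activity scale, which is what removes systematic experiment-to-experiment
variation that confounds ER.

The optimum is found by Metropolis Monte Carlo: theta has relative
probability 2^(N I(theta)) with N the total read count of both samples,
chains start from i.i.d. standard-normal parameters and run for 25,000
steps by default, and the reported motif is the normalized, sign-aligned
average of the endpoints of five independent chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .motif import Motif, normalize_motif
from .mpos_io import VariantCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "MCConfig",
    "ActivityBinning",
    "er_motif",
    "equipopulated_bins",
    "bin_activities",
    "binning_from_activities",
    "mutual_information",
    "metropolis_run",
    "im_motif",
]


# ---------------------------------------------------------------------
# ER inference
# ---------------------------------------------------------------------


def er_motif(table: VariantCountTable, pseudocount: float = 1.0) -> Motif:
    """Enrichment-ratio motif: log2 of selected vs library base fractions.

    At each position l, the fraction of sample reads carrying base b is
    (weighted count + pseudocount) / (sample total + 4 * pseudocount);
    theta is the log2 ratio of the selected to the library fraction.
    """
    counts = table.counts
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        raise ValueError("both library and selected samples must be non-empty")
    idx = table.indices()
    n, L = idx.shape
    base_counts = np.zeros((2, 4, L))
    for s in range(2):
        w = counts[s]
        for l in range(L):
            base_counts[s, :, l] = np.bincount(idx[:, l], weights=w, minlength=4)
    totals = base_counts.sum(axis=1, keepdims=True)
    f = (base_counts + pseudocount) / (totals + 4 * pseudocount)
    theta = np.log2(f[1] / f[0])
    return Motif(theta=theta, label="ER")


# ---------------------------------------------------------------------
# activity binning and mutual information
# ---------------------------------------------------------------------


def equipopulated_bins(n: int, n_bins: int) -> np.ndarray:
    """Bin index for each rank 0..n-1, populations as equal as possible."""
    if n_bins < 1:
        raise ValueError("need at least one bin")
    return (np.arange(n, dtype=np.int64) * n_bins) // n


def gaussian_smoothing_matrix(n_bins: int, sigma: float) -> np.ndarray | None:
    """Column-normalized discrete Gaussian kernel matrix (mass-conserving).

    K[i, j] is the fraction of bin j's mass deposited in bin i; the
    kernel is truncated at the histogram edges and renormalized per
    source bin, so column sums are exactly 1.  ``None`` for sigma = 0
    (identity smoothing).
    """
    if sigma == 0:
        return None
    i = np.arange(n_bins)
    k = np.exp(-0.5 * ((i[:, None] - i[None, :]) / sigma) ** 2)
    return k / k.sum(axis=0, keepdims=True)


@dataclass
class ActivityBinning:
    """Rank-based activity distributions for the MI estimator.

    ``p_a_given_sample`` is (n_samples, n_bins) with each row summing to
    1; ``p_sample`` are the sample weights (read-count fractions);
    ``p_a`` is the marginal sum_s p(sample) p(a|sample).
    ``bin_of_variant`` records the bin each variant landed in.
    """

    p_a_given_sample: np.ndarray
    p_sample: np.ndarray
    bin_of_variant: np.ndarray
    n_bins: int
    sigma: float

    @property
    def p_a(self) -> np.ndarray:
        return self.p_sample @ self.p_a_given_sample

    def validate(self, tol: float = 1e-9) -> None:
        if np.abs(self.p_a_given_sample.sum(axis=1) - 1).max() > tol:
            raise ValueError("per-sample distributions do not sum to 1")
        if abs(self.p_sample.sum() - 1) > tol:
            raise ValueError("sample weights do not sum to 1")


def binning_from_activities(
    activities: np.ndarray,
    counts: np.ndarray,
    n_bins: int = 1000,
    sigma: float = 20.0,
    weight_by: str = "variants",
) -> ActivityBinning:
    """Bin pre-computed activities and build smoothed sample distributions.

    The combined activities are sorted (ties broken by stable input
    order), replaced by their ranks, and partitioned into ``n_bins``
    equipopulated bins; each sample's read counts are histogrammed over
    bins, Gaussian-smoothed (sigma in bins) and normalized.

    ``weight_by`` chooses what the bins equalize: ``"variants"`` (default)
    gives each distinct sequence equal rank weight; ``"reads"`` weights
    ranks by combined read count.
    """
    activities = np.asarray(activities, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n = activities.shape[0]
    if counts.shape[1] != n:
        raise ValueError("counts and activities disagree on variant number")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if n_bins > n:
        logger.warning(
            "requested %d bins for %d distinct variants; reducing to %d",
            n_bins, n, n,
        )
        n_bins = n
    order = np.argsort(activities, kind="stable")
    if weight_by == "variants":
        per_rank = equipopulated_bins(n, n_bins)
    elif weight_by == "reads":
        w = counts.sum(axis=0)[order]
        centers = np.cumsum(w) - w / 2
        per_rank = np.minimum(
            (centers / w.sum() * n_bins).astype(np.int64), n_bins - 1
        )
    else:
        raise ValueError(f"unknown weight_by {weight_by!r}")
    bin_of = np.empty(n, dtype=np.int64)
    bin_of[order] = per_rank

    hists = np.vstack(
        [np.bincount(bin_of, weights=counts[s], minlength=n_bins) for s in range(counts.shape[0])]
    )
    kernel = gaussian_smoothing_matrix(n_bins, sigma)
    if kernel is not None:
        hists = hists @ kernel.T
    totals = hists.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a sample has zero total reads")
    p_a_given_sample = hists / totals
    p_sample = counts.sum(axis=1) / counts.sum()
    return ActivityBinning(
        p_a_given_sample=p_a_given_sample,
        p_sample=p_sample,
        bin_of_variant=bin_of,
        n_bins=n_bins,
        sigma=sigma,
    )


def bin_activities(
    table: VariantCountTable,
    motif: Motif,
    n_bins: int = 1000,
    sigma: float = 20.0,
    weight_by: str = "variants",
) -> ActivityBinning:
    """Score the table's variants with ``motif`` and bin the activities."""
    activities = motif.activities(table.indices())
    return binning_from_activities(
        activities, table.counts, n_bins=n_bins, sigma=sigma, weight_by=weight_by
    )


def mutual_information(binning: ActivityBinning) -> float:
    """Mutual information (bits) between activity bin and sample identity.

    Terms with p(a|sample) = 0 contribute zero.  Bounded by the sample
    entropy: 0 <= I <= H(sample) <= 1 bit for two samples.
    """
    p_as = binning.p_a_given_sample
    p_a = binning.p_a
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_as > 0, p_as / p_a, 1.0)
        terms = np.where(p_as > 0, p_as * np.log2(ratio), 0.0)
    return float(binning.p_sample @ terms.sum(axis=1))


# ---------------------------------------------------------------------
# Metropolis Monte Carlo IM optimization
# ---------------------------------------------------------------------


@dataclass
class MCConfig:
    """Metropolis Monte Carlo settings for IM inference.

    ``n_eff`` is the N in the stationary weight 2^(N I(theta)); it
    defaults to the table's combined read count.  ``proposal_scale`` is
    the s.d. of the Gaussian single-parameter perturbation; the default
    0.3 is matched to the unit-scale standard-normal initialization so
    chains traverse the parameter scale within a few thousand steps.
    """

    steps: int = 25000
    runs: int = 5
    n_eff: float | None = None
    proposal_scale: float = 0.3
    n_bins: int = 1000
    sigma: float = 20.0
    weight_by: str = "variants"
    seed: int | None = None

    def __post_init__(self):
        if self.steps < 1 or self.runs < 1:
            raise ValueError("steps and runs must be >= 1")
        if self.n_eff is not None and self.n_eff < 0:
            raise ValueError("n_eff must be >= 0")


class _MIEvaluator:
    """Fast repeated evaluation of I(theta) for one count table."""

    def __init__(self, table: VariantCountTable, n_bins: int, sigma: float,
                 weight_by: str = "variants"):
        self.idx = table.indices()
        self.counts = table.counts
        self.n, self.L = self.idx.shape
        n_bins = min(n_bins, self.n)
        self.n_bins = n_bins
        self.weight_by = weight_by
        self.kernel = gaussian_smoothing_matrix(n_bins, sigma)
        self.per_rank = equipopulated_bins(self.n, n_bins)
        self.p_sample = self.counts.sum(axis=1) / self.counts.sum()
        self.sample_totals = self.counts.sum(axis=1, keepdims=True)
        self._col = np.arange(self.L)

    def activities(self, theta: np.ndarray) -> np.ndarray:
        return theta[self.idx, self._col].sum(axis=1)

    def information_from_activities(self, activities: np.ndarray) -> float:
        order = np.argsort(activities, kind="stable")
        bin_of = np.empty(self.n, dtype=np.int64)
        bin_of[order] = self.per_rank
        h0 = np.bincount(bin_of, weights=self.counts[0], minlength=self.n_bins)
        h1 = np.bincount(bin_of, weights=self.counts[1], minlength=self.n_bins)
        h = np.vstack([h0, h1])
        if self.kernel is not None:
            h = h @ self.kernel.T
        p_as = h / self.sample_totals
        p_a = self.p_sample @ p_as
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_as > 0, p_as / p_a, 1.0)
            terms = np.where(p_as > 0, p_as * np.log2(ratio), 0.0)
        return float(self.p_sample @ terms.sum(axis=1))

    def information(self, theta: np.ndarray) -> float:
        return self.information_from_activities(self.activities(theta))


def metropolis_run(
    table: VariantCountTable,
    config: MCConfig | None = None,
    seed: int | None = None,
    evaluator: _MIEvaluator | None = None,
):
    """One Metropolis chain maximizing I(theta).

    Starts from i.i.d. standard-normal parameters; each step perturbs one
    uniformly chosen theta entry by a centered Gaussian and accepts with
    probability min(1, 2^(N * delta_I)).  Returns the endpoint motif and
    the trace of the chain's I value at every step (length steps + 1,
    including the start).  Fully reproducible given the seed.
    """
    config = config or MCConfig()
    ev = evaluator or _MIEvaluator(table, config.n_bins, config.sigma, config.weight_by)
    n_eff = table.total_reads if config.n_eff is None else config.n_eff
    rng = np.random.default_rng(seed if seed is not None else config.seed)

    theta = rng.standard_normal((4, ev.L))
    act = ev.activities(theta)
    current = ev.information_from_activities(act)
    trace = np.empty(config.steps + 1)
    trace[0] = current
    for step in range(config.steps):
        b = int(rng.integers(4))
        l = int(rng.integers(ev.L))
        delta = rng.normal(0.0, config.proposal_scale)
        mask = ev.idx[:, l] == b
        new_act = act.copy()
        new_act[mask] += delta
        proposed = ev.information_from_activities(new_act)
        # accept with prob min(1, 2^(N dI)); log2(u) < N dI avoids overflow
        u = rng.uniform()
        log2u = -np.inf if u == 0.0 else math.log2(u)
        if log2u < n_eff * (proposed - current):
            theta[b, l] += delta
            act = new_act
            current = proposed
        trace[step + 1] = current
    return Motif(theta=theta, label="IM endpoint"), trace


def im_motif(
    table: VariantCountTable,
    config: MCConfig | None = None,
    return_details: bool = False,
):
    """IM motif: normalized, sign-aligned average of MC run endpoints.

    Each of ``config.runs`` independent chains contributes its endpoint;
    endpoints are gauge-fixed by :func:`normalize_motif`, sign-aligned to
    the ER motif of the same table (I(theta) is invariant under negation,
    so signs are arbitrary per run; if the ER inner product is zero, run
    1 is the reference), averaged entry-wise, and re-normalized.
    """
    config = config or MCConfig()
    ev = _MIEvaluator(table, config.n_bins, config.sigma, config.weight_by)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.runs)

    try:
        reference = normalize_motif(er_motif(table)).theta
    except Exception:
        reference = None

    endpoints = []
    traces = []
    for run in range(config.runs):
        endpoint, trace = metropolis_run(
            table, config, seed=int(seeds[run]), evaluator=ev
        )
        endpoints.append(normalize_motif(endpoint).theta)
        traces.append(trace)
    if reference is None:
        reference = endpoints[0]

    aligned = []
    for ep in endpoints:
        dot = float((ep * reference).sum())
        if dot == 0.0:
            dot = float((ep * endpoints[0]).sum()) or 1.0
        aligned.append(ep if dot > 0 else -ep)
    mean = np.mean(aligned, axis=0)
    result = normalize_motif(Motif(theta=mean, label="IM"))
    if return_details:
        return result, {
            "endpoints": [Motif(theta=a, normalized=True, label=f"IM run {i+1}")
                          for i, a in enumerate(aligned)],
            "traces": traces,
            "seeds": [int(s) for s in seeds],
        }
    return result
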