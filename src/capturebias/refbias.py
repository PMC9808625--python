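"""Heterozygote-ascertained reference-bias estimation.

Sites are called heterozygous when the reads show both alleles — at least
one read matching the reference allele and one matching the alternative.
With no bias, half of the reads at such a site should match the reference.
The observed spread of per-site reference fractions overstates the true
spread of the latent per-SNP reference-read probability ``p``, because
binomial sampling at finite depth adds variance of its own.  The estimator
here deconvolves that sampling noise: the latent ``p`` is modeled as a
discrete distribution on a fixed grid of interior points, and an
expectation–maximization (EM) algorithm estimates the grid weights by
maximum likelihood.  The likelihood is concave in the weights, so EM
converges to the global optimum from the uniform start.

Two treatments of the ascertainment are offered.  ``truncated`` (the
default) keeps all reads and conditions the binomial likelihood on having
seen both alleles:

    L(p; n, k) = C(n, k) p^k (1-p)^(n-k) / (1 - p^n - (1-p)^n)

``decrement`` instead removes one read of each allele (the reads that
established heterozygosity) and uses a plain binomial on the remaining
(n-2, k-1) — the residual is not exactly binomial, but the reading matches
a literal "count the additional reads" protocol, and the two modes agree
closely at moderate depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, softmax

from .counts import AlleleCounts
from .errors import EmptyInputError, NumericalError, ValidationError
from .simulate import LENGTH_BIN_LABELS

ASCERTAINMENT_MODES = ("truncated", "decrement")


@dataclass
class HetCounts:
    """Read totals and reference counts at ascertained heterozygous sites."""

    n: np.ndarray
    k: np.ndarray
    mode: str
    snp_id: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.n)


@dataclass
class BiasDistribution:
    """Estimated latent distribution of the reference-read probability."""

    grid: np.ndarray  # b_j = (j + 0.5) / K
    weights: np.ndarray  # sums to 1
    mean: float
    sd: float
    loglik: np.ndarray  # trace, non-decreasing
    converged: bool
    n_snps: int
    mode: str
    posterior_mean: np.ndarray | None = field(default=None, repr=False)


def ascertain(
    counts: AlleleCounts,
    mode: str = "truncated",
    dedup: str = "pre",
    length_bin: str | None = "pooled",
) -> HetCounts:
    """Retain sites where both alleles were observed.

    Each row of ``counts`` (one library x SNP observation) with at least
    one reference and one alternative read is kept.  ``truncated`` keeps the
    full (n = ref + alt, k = ref) for the ascertainment-corrected
    likelihood; ``decrement`` returns (n - 2, k - 1) and drops sites with no
    residual reads.  Reads matching neither allele are ignored.  When the
    table carries a ``dedup`` or ``length_bin`` column the requested stratum
    is selected first (pre-deduplication, pooled lengths by default).
    """
    if mode not in ASCERTAINMENT_MODES:
        raise ValidationError(f"mode must be one of {ASCERTAINMENT_MODES}")
    df = counts.select(dedup=dedup, length_bin=length_bin).df
    ref = df["ref_count"].to_numpy()
    alt = df["alt_count"].to_numpy()
    keep = (ref >= 1) & (alt >= 1)
    ref, alt = ref[keep], alt[keep]
    snp_id = df.loc[keep, "snp_id"].to_numpy()
    if mode == "truncated":
        n, k = ref + alt, ref
    else:
        n, k = ref + alt - 2, ref - 1
        nonzero = n > 0
        n, k, snp_id = n[nonzero], k[nonzero], snp_id[nonzero]
    return HetCounts(n=n, k=k, mode=mode, snp_id=snp_id)


def _log_likelihood_matrix(n, k, grid, mode) -> np.ndarray:
    """log L for each unique (n, k) row against each grid point."""
    n = n[:, None].astype(float)
    k = k[:, None].astype(float)
    b = grid[None, :]
    log_b, log_q = np.log(b), np.log1p(-b)
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    log_l = log_choose + k * log_b + (n - k) * log_q
    if mode == "truncated":
        denom = 1.0 - np.exp(n * log_b) - np.exp(n * log_q)
        with np.errstate(divide="ignore"):
            log_l = log_l - np.log(denom)
    return log_l


def em_bias(
    het: HetCounts,
    K: int = 100,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> BiasDistribution:
    """EM deconvolution of the latent per-SNP bias distribution.

    The latent reference-read probability takes values on the grid
    ``b_j = (j + 0.5) / K`` (interior midpoints, so the truncated likelihood
    is defined everywhere).  E-step: responsibilities
    ``r_ij ∝ w_j L(b_j; n_i, k_i)``; M-step: each weight becomes the mean
    responsibility over SNPs — every SNP contributes one likelihood term
    regardless of depth, because the target is the across-SNP bias
    distribution, not a read-weighted average.  The observed-data
    log-likelihood is checked to be non-decreasing at every iteration;
    convergence is a relative change below ``tol``.  Failure to converge
    within ``max_iter`` sets ``converged=False`` rather than raising.
    """
    if len(het) == 0:
        raise EmptyInputError("no ascertained sites")
    if K < 1:
        raise ValidationError("grid size K must be >= 1")
    grid = (np.arange(K) + 0.5) / K

    pairs, inverse, multiplicity = np.unique(
        np.column_stack([het.n, het.k]), axis=0, return_inverse=True,
        return_counts=True,
    )
    log_l = _log_likelihood_matrix(pairs[:, 0], pairs[:, 1], grid, het.mode)
    if not np.isfinite(log_l).all():
        bad = np.argwhere(~np.isfinite(log_l))[0, 0]
        raise NumericalError(
            f"non-finite likelihood for site with n={pairs[bad, 0]}, "
            f"k={pairs[bad, 1]}"
        )
    mult = multiplicity.astype(float)
    total = mult.sum()

    weights = np.full(K, 1.0 / K)
    trace: list[float] = []
    converged = K == 1
    for _ in range(max_iter if K > 1 else 1):
        with np.errstate(divide="ignore"):
            scores = log_l + np.log(weights)[None, :]
        ll = float(mult @ logsumexp(scores, axis=1))
        if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise NumericalError("EM log-likelihood decreased")
        if trace and abs(ll - trace[-1]) <= tol * max(1.0, abs(trace[-1])):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        resp = softmax(scores, axis=1)
        weights = (mult @ resp) / total
    with np.errstate(divide="ignore"):
        resp = softmax(log_l + np.log(weights)[None, :], axis=1)
    mean = float(weights @ grid)
    var = float(weights @ grid**2 - mean**2)
    posterior = (resp @ grid)[inverse]
    return BiasDistribution(
        grid=grid,
        weights=weights,
        mean=mean,
        sd=float(np.sqrt(max(var, 0.0))),
        loglik=np.asarray(trace),
        converged=converged,
        n_snps=len(het),
        mode=het.mode,
        posterior_mean=posterior,
    )


def bias_by_length(
    counts: AlleleCounts,
    bins: list[str] | None = None,
    mode: str = "truncated",
    K: int = 100,
    dedup: str = "pre",
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> dict[str, BiasDistribution | None]:
    """Bias distribution per fragment-length class.

    Runs the ascertainment and EM separately on each length bin (longer
    fragments align more reliably, so their bias is expected to be
    smaller).  Bins with no ascertained sites are reported as ``None``
    rather than raising.
    """
    bins = list(bins) if bins is not None else list(LENGTH_BIN_LABELS)
    out: dict[str, BiasDistribution | None] = {}
    for label in bins:
        het = ascertain(counts, mode=mode, dedup=dedup, length_bin=label)
        if len(het) == 0:
            out[label] = None
            continue
        out[label] = em_bias(het, K=K, max_iter=max_iter, tol=tol)
    return out


def raw_proportion_sd(het: HetCounts) -> float:
    """SD of the raw per-site reference fractions k/n (no correction)."""
    if len(het) == 0:
        raise EmptyInputError("no ascertained sites")
    return float(np.std(het.k / het.n))


def moment_bias_sd(het: HetCounts) -> float:
    """Method-of-moments check: raw variance minus binomial sampling variance.

    Ignores the ascertainment, so it is slightly biased at low depth; used
    as an independent cross-check of the EM, not as the estimator.
    """
    if len(het) == 0:
        raise EmptyInputError("no ascertained sites")
    p_hat = het.k / het.n
    sampling = np.mean(p_hat * (1 - p_hat) / np.maximum(het.n - 1, 1))
    return float(np.sqrt(max(np.var(p_hat) - sampling, 0.0)))
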