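"""Mutation-rate inference from Luria-Delbrück fluctuation assays.

Parallel cultures grown from a small inoculum accumulate mutants whose
count distribution is heavy-tailed (jackpot cultures): the Lea-Coulson
distribution with a single parameter ``m``, the expected number of
mutational events per culture.  The per-locus per-generation mutation
rate follows as ``mu = m / N_t`` where ``N_t`` is the final number of
cells per culture.

The probability mass function is computed by the Ma-Sandri-Sarkar (MSS)
recursion

    p_0 = exp(-m),    p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1)

and, for large supports where the O(k^2) recursion is impractical, by
numerical inversion of the probability generating function

    G(z) = exp(m * (1 - z) * log(1 - z) / z)

on the unit circle (FFT).  ``m`` is estimated by maximum likelihood with
counts at or above the support truncation pooled into a censored tail
class, and 95% confidence intervals come from the profile likelihood
(with the closed-form approximation of Stewart as a fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import irfft
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "FluctuationExperiment",
    "MutationRateEstimate",
    "MleResult",
    "lea_coulson_pmf",
    "lea_coulson_pmf_fft",
    "estimate_m_mle",
    "estimate_p0",
    "mutation_rate_with_ci",
    "rate_ratio",
]

#: default support truncation for the MSS recursion
DEFAULT_K_MAX = 1500

#: largest support used by the FFT backend (counts above are censored);
#: one below a power of two so the transform length stays at 2^20
_FFT_K_CAP = (1 << 19) - 1

#: recursion is used up to this support, FFT beyond
_RECURSION_LIMIT = 4096


@dataclass
class FluctuationExperiment:
    """Mutant counts from parallel cultures of a fluctuation assay.

    Parameters
    ----------
    mutant_counts
        One nonnegative mutant colony count per culture.
    nt
        Final number of cells per culture.
    n0
        Founding inoculum per culture (default 1000 cells, the assay's
        typical inoculum into 1 ml LB).
    phenotype
        Label of the selected phenotype (e.g. ``"gat-negative"``).
    """

    mutant_counts: Sequence[int]
    nt: float
    n0: float = 1000.0
    phenotype: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.mutant_counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("mutant_counts must be a 1-D sequence")
        if (counts < 0).any():
            raise ValueError("mutant counts must be nonnegative")
        if not (self.nt > self.n0 >= 1):
            raise ValueError("require nt > n0 >= 1")
        self.mutant_counts = counts

    @property
    def n_cultures(self) -> int:
        return int(len(self.mutant_counts))


@dataclass
class MleResult:
    m: float
    loglik: float
    boundary: bool = False
    k_max: int = DEFAULT_K_MAX


@dataclass
class MutationRateEstimate:
    """Point estimate and 95% CI for a per-locus per-generation rate."""

    m: float
    mu: float
    ci95: tuple[float, float]
    method: str
    boundary: bool = False
    experiment: FluctuationExperiment | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.mu <= hi) and not self.boundary:
            raise ValueError("CI must contain the point estimate")


def lea_coulson_pmf(m: float, k_max: int = DEFAULT_K_MAX) -> np.ndarray:
    """Lea-Coulson pmf ``p_0 .. p_{k_max}`` by the MSS recursion.

    The tail mass ``1 - p.sum()`` is the probability of counts above
    ``k_max``.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    if k_max < 0:
        raise ValueError("k_max must be nonnegative")
    p = np.zeros(k_max + 1)
    p[0] = np.exp(-m)
    if k_max == 0 or m == 0.0:
        if m == 0.0:
            p[0] = 1.0
        return p
    # convolution weights c_j = 1/(j+1) for lag j >= 1
    inv = np.empty(k_max + 2)
    inv[0] = 0.0  # unused
    inv[1:] = 1.0 / np.arange(1, k_max + 2, dtype=float)
    for k in range(1, k_max + 1):
        # p_k = (m/k) * sum_{j=1..k} p_{k-j} / (j+1)
        p[k] = (m / k) * np.dot(p[k - 1 :: -1], inv[2 : k + 2])
    return p


_pgf_kernel_cache: dict[int, np.ndarray] = {}


def _pgf_kernel(n: int) -> np.ndarray:
    """log G(z)/m evaluated at the first n//2+1 n-th roots of unity."""
    kern = _pgf_kernel_cache.get(n)
    if kern is None:
        j = np.arange(n // 2 + 1)
        # conjugate roots so that G matches numpy's rfft sign convention
        z = np.exp(-2j * np.pi * j / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            kern = (1.0 - z) * np.log1p(-z) / z
        kern[0] = 0.0  # z=1: (1-z)log(1-z) -> 0
        _pgf_kernel_cache[n] = kern
    return kern


def lea_coulson_pmf_fft(m: float, k_max: int) -> np.ndarray:
    """Lea-Coulson pmf ``p_0 .. p_{k_max}`` by pgf inversion (FFT).

    Aliasing adds O(m / n^2) per coefficient (the tail decays like
    m/k^2), negligible at the supports used here.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    n = 1
    while n < 2 * (k_max + 1):
        n <<= 1
    g = np.exp(m * _pgf_kernel(n))
    p = irfft(g, n)[: k_max + 1]
    return np.clip(p, 0.0, 1.0)


def _pmf(m: float, k_max: int) -> np.ndarray:
    if k_max <= _RECURSION_LIMIT:
        return lea_coulson_pmf(m, k_max)
    return lea_coulson_pmf_fft(m, k_max)


def _choose_k_max(counts: np.ndarray, k_max: int | None) -> int:
    """Support large enough to leave typical counts uncensored, capped so
    the pmf stays affordable (counts above are pooled into the tail)."""
    if k_max is not None:
        return int(k_max)
    hi = int(counts.max()) if counts.size else 0
    return int(min(max(64, 2 * hi), _FFT_K_CAP))


def _loglik(m: float, counts: np.ndarray, k_max: int) -> float:
    """Censored log-likelihood: counts >= k_max pooled into the tail."""
    if m <= 0:
        return -np.inf
    p = _pmf(m, k_max)
    below = counts[counts < k_max]
    n_tail = int((counts >= k_max).sum())
    ll = float(np.log(np.maximum(p[below], 1e-300)).sum())
    if n_tail:
        tail = max(1.0 - float(p.sum()) + float(p[k_max]), 1e-300)
        ll += n_tail * np.log(tail)
    return ll


def estimate_m_mle(
    experiment: FluctuationExperiment, k_max: int | None = None
) -> MleResult:
    """Maximum-likelihood estimate of m by bounded 1-D optimisation.

    All-zero counts put the MLE at the m = 0 boundary; the result is
    flagged and callers should report an upper bound instead of a point
    estimate (see :func:`mutation_rate_with_ci`).
    """
    counts = np.asarray(experiment.mutant_counts)
    if counts.size < 2:
        raise ValueError("need at least 2 cultures for MLE")
    k_max = _choose_k_max(counts, k_max)
    if (counts == 0).all():
        return MleResult(m=0.0, loglik=0.0, boundary=True, k_max=k_max)

    # initial guess from the Lea-Coulson median relation
    # r_med / m - ln m ~ 1.24, falling back to the p0 method
    r_med = float(np.median(counts))
    if r_med >= 1:
        m0 = max(r_med, 0.1)
        for _ in range(60):
            m0 = r_med / (np.log(max(m0, 1.05)) + 1.24)
    else:
        n_zero = int((counts == 0).sum())
        m0 = -np.log(max(n_zero, 1) / counts.size) if n_zero else 1.0
        m0 = max(m0, 0.05)

    # bounded search on log m around the init; widen if the optimum
    # lands on an edge (the pmf evaluation dominates the cost)
    half_width = np.log(6.0)
    for _ in range(4):
        lo, hi = np.log(m0) - half_width, np.log(m0) + half_width
        res = minimize_scalar(
            lambda lm: -_loglik(np.exp(lm), counts, k_max),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 2e-3},
        )
        if res.x - lo > 0.05 and hi - res.x > 0.05:
            break
        m0 = float(np.exp(res.x))
        half_width *= 2.0
    m_hat = float(np.exp(res.x))
    return MleResult(m=m_hat, loglik=-float(res.fun), k_max=k_max)


def estimate_p0(experiment: FluctuationExperiment) -> float:
    """Classical p0 estimate ``m = -ln(fraction of zero-count cultures)``."""
    counts = np.asarray(experiment.mutant_counts)
    n_zero = int((counts == 0).sum())
    if n_zero == 0:
        raise ValueError(
            "no zero-count cultures: the p0 method is undefined, use the MLE"
        )
    return float(-np.log(n_zero / counts.size))


def _stewart_ci(m_hat: float, n_cultures: int) -> tuple[float, float]:
    """Closed-form 95% CI on m (Stewart's approximation, as used by FALCOR)."""
    sigma = 1.225 * m_hat ** (-0.315) / np.sqrt(n_cultures)
    return (float(m_hat * np.exp(-1.96 * sigma)), float(m_hat * np.exp(1.96 * sigma)))


def _profile_ci(
    m_hat: float, ll_hat: float, counts: np.ndarray, k_max: int
) -> tuple[float, float] | None:
    """95% profile-likelihood CI on m (drop of 1.92 in log-likelihood)."""
    target = ll_hat - 1.92

    def drop(m: float) -> float:
        return _loglik(m, counts, k_max) - target

    try:
        lo_bracket = m_hat
        step = 0.5
        while drop(lo_bracket * step) > 0:
            lo_bracket *= step
            if lo_bracket < 1e-10:
                return None
        lo = brentq(drop, lo_bracket * step, lo_bracket, xtol=5e-3 * m_hat, rtol=1e-3)

        hi_bracket = m_hat
        while drop(hi_bracket / step) > 0:
            hi_bracket /= step
            if hi_bracket > 1e12:
                return None
        hi = brentq(drop, hi_bracket, hi_bracket / step, xtol=5e-3 * m_hat, rtol=1e-3)
    except ValueError:
        return None
    return (float(lo), float(hi))


def mutation_rate_with_ci(
    experiment: FluctuationExperiment,
    k_max: int | None = None,
    alpha: float = 0.05,
) -> MutationRateEstimate:
    """Per-locus per-generation mutation rate with a 95% CI.

    ``mu = m / nt`` (the FALCOR convention; divide by ``nt - n0`` by
    passing an adjusted ``nt`` if preferred).  The CI is the profile
    likelihood interval; Stewart's closed form is the fallback when the
    profile cannot be bracketed.  With all-zero counts the point
    estimate sits on the m = 0 boundary and a one-sided upper bound
    ``-ln(alpha) / (C * nt)`` is returned instead.
    """
    mle = estimate_m_mle(experiment, k_max=k_max)
    counts = np.asarray(experiment.mutant_counts)
    nt = float(experiment.nt)
    if mle.boundary:
        # P(all C cultures zero | m) = e^{-Cm} = alpha at the bound
        m_hi = -np.log(alpha) / experiment.n_cultures
        return MutationRateEstimate(
            m=0.0,
            mu=0.0,
            ci95=(0.0, m_hi / nt),
            method="p0-upper-bound",
            boundary=True,
            experiment=experiment,
        )
    ci = _profile_ci(mle.m, mle.loglik, counts, mle.k_max)
    method = "mss-mle-profile"
    if ci is None:
        ci = _stewart_ci(mle.m, experiment.n_cultures)
        method = "mss-mle-stewart"
    return MutationRateEstimate(
        m=mle.m,
        mu=mle.m / nt,
        ci95=(ci[0] / nt, ci[1] / nt),
        method=method,
        experiment=experiment,
    )


def rate_ratio(
    a: MutationRateEstimate, b: MutationRateEstimate
) -> tuple[float, tuple[float, float]]:
    """Fold difference ``a.mu / b.mu`` with a 95% CI assuming independence.

    The CI combines the two log-scale standard errors implied by the
    individual intervals.
    """
    if a.mu <= 0 or b.mu <= 0:
        raise ValueError("rate ratio undefined at a boundary estimate")
    ratio = a.mu / b.mu
    se_a = (np.log(a.ci95[1]) - np.log(a.ci95[0])) / (2 * 1.96)
    se_b = (np.log(b.ci95[1]) - np.log(b.ci95[0])) / (2 * 1.96)
    se = float(np.hypot(se_a, se_b))
    return float(ratio), (
        float(ratio * np.exp(-1.96 * se)),
        float(ratio * np.exp(1.96 * se)),
    )
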