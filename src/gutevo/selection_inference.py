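"""Selection-coefficient estimation from in vivo competition data.

Two competitors (an evolved clone and its ancestor, carrying opposite
fluorescent markers) are followed by daily colony counts.  Under haploid
selection the log ratio of the two types changes linearly with
generations, so the per-generation selection coefficient is

    s = ln(R_f / R_i) / (t * delta_days)

with R the focal/reference ratio at the window endpoints and t the
number of generations per day (18 by default, from an 80-minute
generation time in the streptomycin-treated mouse gut).

The same module fits the negative frequency-dependent-selection (FDS)
regression of the daily frequency change against frequency,
``delta_f = a + b * f``, whose stable internal equilibrium at
``f* = -a/b`` (for b < 0) maintains polymorphism, and classifies
epistasis between genetic backgrounds by a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DEFAULT_GENERATIONS_PER_DAY",
    "CompetitionTrajectory",
    "SelectionEstimate",
    "FDSFit",
    "EpistasisResult",
    "estimate_s_endpoint",
    "estimate_s_replicates",
    "estimate_s_logit",
    "fds_regression",
    "fds_equilibrium",
    "compare_epistasis",
]

DEFAULT_GENERATIONS_PER_DAY = 18


@dataclass
class CompetitionTrajectory:
    """Daily counts of a focal competitor against a reference.

    Counts may alternatively be frequencies (``is_frequency=True``); the
    ratio-based estimator is invariant to the common scale so both forms
    give identical estimates.
    """

    day: np.ndarray
    focal_count: np.ndarray
    reference_count: np.ndarray
    generations_per_day: int = DEFAULT_GENERATIONS_PER_DAY
    replicate_id: str | None = None
    host_id: str | None = None
    is_frequency: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.focal_count = np.asarray(self.focal_count, dtype=float)
        self.reference_count = np.asarray(self.reference_count, dtype=float)
        if not (len(self.day) == len(self.focal_count) == len(self.reference_count)):
            raise ValueError("day/focal/reference lengths differ")
        if len(self.day) < 2:
            raise ValueError("need at least 2 timepoints")
        if (np.diff(self.day) <= 0).any():
            raise ValueError("days must be strictly increasing")
        if (self.focal_count < 0).any() or (self.reference_count < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.generations_per_day < 1:
            raise ValueError("generations_per_day must be >= 1")

    def frequency(self) -> np.ndarray:
        tot = self.focal_count + self.reference_count
        return self.focal_count / tot

    def _value_at(self, day: float, which: str) -> float:
        idx = np.nonzero(self.day == day)[0]
        if idx.size == 0:
            raise ValueError(f"day {day} not present in trajectory")
        return float(getattr(self, which)[idx[0]])


@dataclass
class SelectionEstimate:
    """Per-generation selection coefficient with its uncertainty.

    ``se`` is a plain standard error; the reporting convention in this
    system is mean +/- 2SE, flagged by ``two_se_convention``.
    """

    s: float
    se: float
    window: tuple[float, float]
    n_replicates: int = 1
    two_se_convention: bool = True

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be nonnegative")
        if self.window[1] <= self.window[0]:
            raise ValueError("window must have positive span")


@dataclass
class FDSFit:
    """OLS fit of the daily frequency change against frequency."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    adj_r_squared: float
    p_value: float
    n_points: int

    @property
    def equilibrium(self) -> float | None:
        """Stable equilibrium -a/b, defined only for a negative slope."""
        if self.slope >= 0:
            return None
        return -self.intercept / self.slope


@dataclass
class EpistasisResult:
    verdict: str  # positive | negative | none
    p_value: float
    median_difference: float


def _default_window(traj: CompetitionTrajectory) -> tuple[float, float]:
    # the standard competition design scores a 3-day interval
    start = float(traj.day[0])
    end = start + 3.0
    if end > traj.day[-1]:
        end = float(traj.day[-1])
    return (start, end)


def estimate_s_endpoint(
    traj: CompetitionTrajectory, window: tuple[float, float] | None = None
) -> SelectionEstimate:
    """Endpoint log-ratio estimator ``s = ln(Rf/Ri) / (t * delta_days)``.

    A zero count at either endpoint makes the ratio undefined and raises
    (no pseudocounts are added; widen or shift the window instead).
    """
    if window is None:
        window = _default_window(traj)
    d_i, d_f = window
    for d in (d_i, d_f):
        foc = traj._value_at(d, "focal_count")
        ref = traj._value_at(d, "reference_count")
        if foc == 0 or ref == 0:
            raise ValueError(
                f"zero colony count at day {d}: log-ratio undefined; "
                "choose a window with both competitors observed"
            )
    r_i = traj._value_at(d_i, "focal_count") / traj._value_at(d_i, "reference_count")
    r_f = traj._value_at(d_f, "focal_count") / traj._value_at(d_f, "reference_count")
    gens = traj.generations_per_day * (d_f - d_i)
    s = float(np.log(r_f / r_i) / gens)
    return SelectionEstimate(s=s, se=0.0, window=(d_i, d_f), n_replicates=1)


def estimate_s_replicates(
    trajectories: Iterable[CompetitionTrajectory],
    window: tuple[float, float] | None = None,
) -> SelectionEstimate:
    """Mean selection coefficient across replicate competitions.

    Each replicate is estimated separately, then averaged; the reported
    ``se`` is the standard error of that mean (report +/- 2SE).
    """
    ss = []
    win = window
    for traj in trajectories:
        est = estimate_s_endpoint(traj, window)
        ss.append(est.s)
        win = est.window
    if not ss:
        raise ValueError("no trajectories supplied")
    ss_arr = np.asarray(ss)
    se = float(ss_arr.std(ddof=1) / np.sqrt(len(ss))) if len(ss) > 1 else 0.0
    return SelectionEstimate(
        s=float(ss_arr.mean()), se=se, window=win, n_replicates=len(ss)
    )


def estimate_s_logit(
    frequencies: Sequence[float],
    generations: Sequence[float],
) -> SelectionEstimate:
    """Selection coefficient from a frequency trajectory on the logit scale.

    ``s = [logit(f_end) - logit(f_start)] / delta_generations``; with the
    reference class defined as all non-focal cells this is algebraically
    identical to the endpoint log-ratio estimator.  Frequencies must be
    strictly inside (0, 1).
    """
    f = np.asarray(frequencies, dtype=float)
    g = np.asarray(generations, dtype=float)
    if f.size != g.size or f.size < 2:
        raise ValueError("need matching frequency/generation series of length >= 2")
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError(
            "frequencies must lie strictly in (0,1); shrink the window so the "
            "focal haplotype is segregating at both endpoints"
        )
    logit = np.log(f / (1 - f))
    s = float((logit[-1] - logit[0]) / (g[-1] - g[0]))
    return SelectionEstimate(
        s=s, se=0.0, window=(float(g[0]), float(g[-1])), n_replicates=1
    )


def fds_regression(
    frequency_series: Iterable[Sequence[float]] | Sequence[float],
) -> FDSFit:
    """Fit ``delta_f_{i->i+1} = a + b * f_i`` by OLS on pooled pairs.

    ``frequency_series`` is one daily frequency series or an iterable of
    replicate series; consecutive-day pairs from all replicates are
    pooled into a single regression (per-replicate fits can be obtained
    by calling this once per series).  A negative slope with positive
    intercept indicates negative frequency-dependent selection with a
    stable equilibrium at ``-a/b``.
    """
    seq = list(frequency_series)
    if not seq:
        raise ValueError("no frequency series supplied")
    if np.ndim(seq[0]) == 0:
        series_list = [np.asarray(seq, dtype=float)]
    else:
        series_list = [np.asarray(s, dtype=float) for s in seq]
    f_i, d_f = [], []
    for s in series_list:
        if s.size < 2:
            continue
        f_i.append(s[:-1])
        d_f.append(np.diff(s))
    if not f_i:
        raise ValueError("no consecutive frequency pairs available")
    x = np.concatenate(f_i)
    y = np.concatenate(d_f)
    if x.size < 3:
        raise ValueError("need at least 3 (f, delta_f) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: frequency has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return FDSFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        adj_r_squared=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
        n_points=int(x.size),
    )


def fds_equilibrium(fit: FDSFit) -> tuple[float, bool]:
    """Equilibrium frequency ``-a/b`` clipped to [0, 1].

    Returns ``(frequency, clipped)``; raises for a nonnegative slope
    (no stable internal equilibrium).
    """
    if fit.slope >= 0:
        raise ValueError("no stable equilibrium: slope must be negative")
    eq = -fit.intercept / fit.slope
    clipped = eq < 0 or eq > 1
    return float(np.clip(eq, 0.0, 1.0)), clipped


def compare_epistasis(
    s_ancestral_bg: Sequence[float],
    s_evolved_bg: Sequence[float],
    alpha: float = 0.05,
) -> EpistasisResult:
    """Classify epistasis of a mutation between two genetic backgrounds.

    Replicate selection-coefficient estimates on the ancestral and the
    evolved background are compared with a two-sided
    Mann-Whitney-Wilcoxon rank-sum test.  The verdict is ``positive``
    (larger effect on the more-adapted, evolved background), ``negative``
    or ``none``, gated at ``alpha``.
    """
    a = np.asarray(s_ancestral_bg, dtype=float)
    b = np.asarray(s_evolved_bg, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 replicate estimates per background")
    diff = float(np.median(b) - np.median(a))
    if np.array_equal(np.sort(a), np.sort(b)):
        return EpistasisResult(verdict="none", p_value=1.0, median_difference=0.0)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(b, a, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if p < alpha and diff != 0:
        verdict = "positive" if diff > 0 else "negative"
    else:
        verdict = "none"
    return EpistasisResult(verdict=verdict, p_value=p, median_difference=diff)
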