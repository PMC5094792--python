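"""Nested haplotype-frequency series (Muller plots) from clone typing.

During the colonization experiment, populations are dimorphic for a
neutral fluorescent marker (YFP/CFP) and accumulate beneficial
mutations on either background.  Haplotype frequencies are estimated by
typing a few dozen clones per timepoint for the known parallel
mutations and anchoring the within-marker composition to the daily
marker frequencies from plate counts:

    freq(haplotype) = (clone fraction within its marker class)
                      * (marker class frequency)

The genealogy is inferred from genotype subset relations (A is an
ancestor of B iff A's mutation set is a subset of B's), rooted at the
two marker backgrounds.  The central structural invariant is nesting:
a haplotype's inclusive frequency (itself plus all descendants) never
exceeds its parent's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .selection_inference import DEFAULT_GENERATIONS_PER_DAY

__all__ = [
    "Haplotype",
    "TypingSample",
    "MullerSeries",
    "reconstruct_muller",
    "classify_dynamics",
    "clean_window_for_s",
    "DynamicsClassification",
]


@dataclass(frozen=True)
class Haplotype:
    """A genotype class: a marker background plus a set of mutations."""

    marker: str
    mutations: frozenset[str] = frozenset()

    @property
    def label(self) -> str:
        if not self.mutations:
            return self.marker
        return f"{self.marker}:" + "+".join(sorted(self.mutations))

    @property
    def is_root(self) -> bool:
        return not self.mutations

    def __repr__(self) -> str:  # compact in error messages
        return f"Haplotype({self.label})"


@dataclass
class TypingSample:
    """Clone-typing counts at one timepoint."""

    day: float
    counts: dict[Haplotype, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("clone counts must be nonnegative")
        if sum(self.counts.values()) == 0:
            raise ValueError(f"no clones typed at day {self.day}")

    @property
    def clones_typed(self) -> int:
        return int(sum(self.counts.values()))

    def marker_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h, c in self.counts.items():
            out[h.marker] = out.get(h.marker, 0) + c
        return out


class MullerSeries:
    """Haplotype-frequency matrix with genealogy and a day/generation axis.

    Frequencies are stored *exclusively* (each cell belongs to exactly
    one haplotype, its full genotype); inclusive frequencies (a clade's
    total) are derived.  Roots are the marker backgrounds; their
    inclusive frequencies sum to 1 at every timepoint.
    """

    def __init__(
        self,
        days: Sequence[float],
        haplotypes: Sequence[Haplotype],
        frequencies: np.ndarray,
        parent: Mapping[Haplotype, Haplotype | None],
        generations_per_day: int = DEFAULT_GENERATIONS_PER_DAY,
        interpolated: Sequence[bool] | None = None,
    ) -> None:
        self.days = np.asarray(days, dtype=float)
        self.haplotypes = list(haplotypes)
        self.frequencies = np.asarray(frequencies, dtype=float)
        self.parent = dict(parent)
        self.generations_per_day = int(generations_per_day)
        self.interpolated = (
            np.zeros(len(self.days), dtype=bool)
            if interpolated is None
            else np.asarray(interpolated, dtype=bool)
        )
        if self.frequencies.shape != (len(self.haplotypes), len(self.days)):
            raise ValueError("frequency matrix shape mismatch")
        self._index = {h: i for i, h in enumerate(self.haplotypes)}
        sums = self.frequencies.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-timepoint frequencies must sum to 1")

    # -- axes ---------------------------------------------------------------
    @property
    def generations(self) -> np.ndarray:
        return self.days * self.generations_per_day

    # -- genealogy ----------------------------------------------------------
    def children(self, h: Haplotype) -> list[Haplotype]:
        return [c for c, p in self.parent.items() if p == h]

    def ancestors(self, h: Haplotype) -> list[Haplotype]:
        out = []
        p = self.parent.get(h)
        while p is not None:
            out.append(p)
            p = self.parent.get(p)
        return out

    def descendants(self, h: Haplotype) -> list[Haplotype]:
        out: list[Haplotype] = []
        stack = self.children(h)
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self.children(c))
        return out

    # -- frequencies --------------------------------------------------------
    def frequency(self, h: Haplotype) -> np.ndarray:
        return self.frequencies[self._index[h]]

    def inclusive_frequency(self, h: Haplotype) -> np.ndarray:
        idx = [self._index[h]] + [self._index[d] for d in self.descendants(h)]
        return self.frequencies[idx].sum(axis=0)

    def validate_nesting(self, atol: float = 1e-9) -> None:
        """Assert the nesting invariant: child clade <= parent clade."""
        for h, p in self.parent.items():
            if p is None:
                continue
            child = self.inclusive_frequency(h)
            par = self.inclusive_frequency(p)
            if (child > par + atol).any():
                raise AssertionError(
                    f"nesting violated: {h.label} exceeds its parent {p.label}"
                )

    # -- export -------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table consumable by standard Muller-plot renderers."""
        rows = []
        for h in self.haplotypes:
            p = self.parent.get(h)
            for j, d in enumerate(self.days):
                rows.append(
                    {
                        "day": d,
                        "generation": d * self.generations_per_day,
                        "haplotype": h.label,
                        "parent": p.label if p is not None else "",
                        "frequency": self.frequencies[self._index[h], j],
                        "interpolated": bool(self.interpolated[j]),
                    }
                )
        return pd.DataFrame(rows)


def _infer_parents(
    haplotypes: Iterable[Haplotype],
) -> dict[Haplotype, Haplotype | None]:
    """Genealogy from subset relations; ambiguities raise with the conflict."""
    haps = list(haplotypes)
    parent: dict[Haplotype, Haplotype | None] = {}
    for h in haps:
        if h.is_root:
            parent[h] = None
            continue
        candidates = [
            g
            for g in haps
            if g.marker == h.marker and g.mutations < h.mutations
        ]
        if not candidates:
            raise ValueError(
                f"no ancestor found for {h.label}: include the marker root"
            )
        maximal = [
            g
            for g in candidates
            if not any(g.mutations < c.mutations for c in candidates)
        ]
        if len(maximal) > 1:
            labels = ", ".join(g.label for g in maximal)
            raise ValueError(
                f"ambiguous genealogy for {h.label}: incomparable candidate "
                f"parents with overlapping mutations ({labels})"
            )
        parent[h] = maximal[0]
    return parent


def reconstruct_muller(
    typing: Sequence[TypingSample],
    marker_frequencies: Mapping[float, Mapping[str, float]],
    generations_per_day: int = DEFAULT_GENERATIONS_PER_DAY,
) -> MullerSeries:
    """Combine clone typing with daily marker frequencies into a Muller series.

    Days present in ``marker_frequencies`` but without a typing sample
    get their within-marker composition linearly interpolated between
    the nearest typed days (flagged ``interpolated``), then rescaled to
    that day's observed marker frequency.  Before the first (after the
    last) typed day the nearest composition is carried over.
    """
    if not typing:
        raise ValueError("no typing samples")
    typing = sorted(typing, key=lambda t: t.day)
    markers = sorted({m for mf in marker_frequencies.values() for m in mf})
    for t in typing:
        if t.day not in marker_frequencies:
            raise ValueError(f"no marker frequencies for typed day {t.day}")

    haps = sorted(
        {h for t in typing for h in t.counts}
        | {Haplotype(m) for m in markers},
        key=lambda h: (h.marker, len(h.mutations), h.label),
    )
    parent = _infer_parents(haps)

    # within-marker conditional composition at typed days
    typed_days = np.array([t.day for t in typing])
    comp = np.zeros((len(haps), len(typed_days)))
    for j, t in enumerate(typing):
        mc = t.marker_counts()
        for i, h in enumerate(haps):
            n_marker = mc.get(h.marker, 0)
            if n_marker == 0:
                # untyped marker class: attribute everything to its root
                comp[i, j] = 1.0 if h.is_root else 0.0
            else:
                comp[i, j] = t.counts.get(h, 0) / n_marker

    all_days = np.array(sorted(marker_frequencies))
    interp = np.array([d not in set(typed_days) for d in all_days])
    comp_all = np.empty((len(haps), len(all_days)))
    for i in range(len(haps)):
        comp_all[i] = np.interp(all_days, typed_days, comp[i])

    freqs = np.zeros_like(comp_all)
    for j, d in enumerate(all_days):
        mf = marker_frequencies[d]
        total = sum(mf.get(m, 0.0) for m in markers)
        if total <= 0:
            raise ValueError(f"marker frequencies at day {d} sum to 0")
        for i, h in enumerate(haps):
            freqs[i, j] = comp_all[i, j] * mf.get(h.marker, 0.0) / total

    series = MullerSeries(
        days=all_days,
        haplotypes=haps,
        frequencies=freqs,
        parent=parent,
        generations_per_day=generations_per_day,
        interpolated=interp,
    )
    series.validate_nesting()
    return series


@dataclass
class DynamicsClassification:
    """Per-timepoint selection-dynamics labels plus their overall set."""

    days: np.ndarray
    labels: list[str]
    summary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.summary = set(self.labels)


def classify_dynamics(
    series: MullerSeries,
    sweep_threshold: float = 0.95,
    interference_threshold: float = 0.10,
) -> DynamicsClassification:
    """Label each timepoint as sweep, clonal_interference or stasis.

    A sweep is a derived haplotype whose clade crosses ``sweep_threshold``
    (periodic selection: rapid replacement of the resident clone);
    clonal interference is two or more non-nested derived clades each
    above ``interference_threshold`` at the same timepoint.
    """
    if len(series.days) < 2:
        raise ValueError("need at least 2 timepoints")
    derived = [h for h in series.haplotypes if not h.is_root]
    incl = {h: series.inclusive_frequency(h) for h in derived}
    nested = {
        (a, b): (a in series.ancestors(b)) or (b in series.ancestors(a))
        for a in derived
        for b in derived
    }
    labels = []
    for j in range(len(series.days)):
        high = [h for h in derived if incl[h][j] >= interference_threshold]
        interfering = any(
            not nested[(a, b)] for k, a in enumerate(high) for b in high[k + 1 :]
        )
        if interfering:
            labels.append("clonal_interference")
        elif any(incl[h][j] >= sweep_threshold for h in derived):
            labels.append("sweep")
        else:
            labels.append("stasis")
    return DynamicsClassification(days=series.days.copy(), labels=labels)


def clean_window_for_s(
    series: MullerSeries,
    focal: Haplotype,
    purity_threshold: float = 0.05,
) -> tuple[float, float]:
    """Longest window where only the focal clade segregates appreciably.

    Trajectory-based selection estimates are only meaningful while no
    other derived haplotype is segregating; this returns the maximal
    contiguous day window where the focal clade frequency is strictly
    inside (0, 1) and every other derived clade (including the focal's
    own descendants, which would contaminate the estimate) stays below
    ``purity_threshold``.  Hand the window's frequencies to
    :func:`gutevo.selection_inference.estimate_s_logit`.
    """
    if focal not in series.haplotypes:
        raise ValueError(f"{focal.label} not present in series")
    f = series.inclusive_frequency(focal)
    excluded = set(series.ancestors(focal)) | {focal}
    others = [
        series.inclusive_frequency(h)
        for h in series.haplotypes
        if not h.is_root and h not in excluded
    ]
    contamination = np.max(others, axis=0) if others else np.zeros_like(f)
    ok = (f > 0) & (f < 1) & (contamination < purity_threshold)
    if not ok.any():
        raise ValueError(f"no clean window for {focal.label}")
    # longest run of consecutive valid timepoints (>= 2 points)
    best = (0, -1, -1)
    start = None
    for j, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            if j - start > best[0]:
                best = (j - start, start, j - 1)
            start = None
    if best[0] < 2:
        raise ValueError(f"no clean window with >= 2 timepoints for {focal.label}")
    return (float(series.days[best[1]]), float(series.days[best[2]]))
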