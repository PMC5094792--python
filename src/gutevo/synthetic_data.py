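"""Synthetic data generators with known ground truth.

Every tabular input the analysis modules consume can be generated here
with the statistical structure the estimators assume:

* a haploid Wright-Fisher simulation of gut colonization (daily cycles
  of 18 generations, per-locus Poisson mutation supply with hotspot vs
  background rates, constant or frequency-dependent fitness, optional
  epistasis overrides, multinomial colony/clone observation),
* two-competitor competition trajectories with binomial colony-count
  noise,
* Lea-Coulson fluctuation-assay mutant counts (exact compound-Poisson
  sampler),
* Poisson window coverage with a GC bias and embedded duplications or
  deletions, and
* random per-clone mutation tables.

Defaults mirror the colonization experiment this toolkit analyzes:
24 days at 18 generations/day, an effective population of 1e7 cells
(the gut census is larger but unparameterized; this is an explicit
knob, not a claim), ~1e-5 hotspot and ~4e-8 background inactivation
rates, and daily counts of a few hundred colonies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fluctuation_analysis import FluctuationExperiment
from .genome_analysis import CoverageProfile, MutationTable, CATEGORIES
from .muller_reconstruction import Haplotype, MullerSeries, TypingSample
from .selection_inference import (
    DEFAULT_GENERATIONS_PER_DAY,
    CompetitionTrajectory,
)

__all__ = [
    "LocusSpec",
    "SamplingSpec",
    "SimulationConfig",
    "PopulationExtinctError",
    "simulate_gut_population",
    "simulate_competition",
    "sample_lea_coulson",
    "simulate_fluctuation_assay",
    "simulate_coverage",
    "gaussian_gc_bias",
    "synth_mutation_table",
    "synthetic_population_series",
]


class PopulationExtinctError(RuntimeError):
    """The simulated population hit zero cells (never silent NaNs)."""


@dataclass
class LocusSpec:
    """One mutational target.

    ``fitness_effect`` is either a constant per-generation selection
    coefficient, or a frequency-dependent pair ``(a, b)`` on the
    per-day frequency scale (the scale on which the FDS regression is
    fitted); the implied per-generation coefficient is
    ``(a + b f) / generations_per_day``.  ``epistasis_overrides`` maps a
    set of background loci to a replacement coefficient.
    """

    name: str
    mutation_rate: float = 0.0
    fitness_effect: float | tuple[float, float] = 0.0
    epistasis_overrides: dict[frozenset, float] = field(default_factory=dict)
    initial_frequency: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if not (0.0 <= self.initial_frequency <= 1.0):
            raise ValueError("initial_frequency must be in [0, 1]")
        self.epistasis_overrides = {
            frozenset(k): v for k, v in self.epistasis_overrides.items()
        }
        if self.is_fds and self.fitness_effect[1] >= 0:
            warnings.warn(
                f"locus {self.name}: frequency-dependent slope >= 0 has no "
                "stable internal equilibrium",
                stacklevel=2,
            )

    @property
    def is_fds(self) -> bool:
        return isinstance(self.fitness_effect, tuple)

    def coefficient(
        self, background: frozenset, freq: float, generations_per_day: int
    ) -> float:
        """Per-generation coefficient given background loci and own frequency."""
        for key in sorted(self.epistasis_overrides, key=len, reverse=True):
            if key <= background:
                return self.epistasis_overrides[key]
        if self.is_fds:
            a, b = self.fitness_effect
            return (a + b * freq) / generations_per_day
        return float(self.fitness_effect)


@dataclass
class SamplingSpec:
    """Daily observation design: plate counts and clone typing."""

    colonies_per_day: int = 300
    clones_per_timepoint: int = 45
    typing_interval_days: int = 1

    def __post_init__(self) -> None:
        if self.colonies_per_day < 1 or self.clones_per_timepoint < 0:
            raise ValueError("invalid sampling spec")


@dataclass
class SimulationConfig:
    population_size: float = 1e7
    generations_per_day: int = DEFAULT_GENERATIONS_PER_DAY
    days: int = 24
    loci: list[LocusSpec] = field(default_factory=list)
    marker_split: float = 0.5
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    rng_seed: int = 0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.generations_per_day < 1:
            raise ValueError("generations_per_day must be >= 1")
        if not (0.0 <= self.marker_split <= 1.0):
            raise ValueError("marker_split must be in [0, 1]")
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            raise ValueError("locus names must be unique")


def _locus_frequency(counts: dict[Haplotype, float], locus: str, total: float) -> float:
    return sum(c for h, c in counts.items() if locus in h.mutations) / total


def simulate_gut_population(
    config: SimulationConfig,
) -> tuple[MullerSeries, list[TypingSample]]:
    """Wright-Fisher stand-in for the mouse-gut colonization experiment.

    Each generation resamples genotype counts multinomially with weights
    ``1 + sum of locus coefficients``, then seeds new mutants per locus
    with Poisson(count * mu) events (one derived allele class per locus).
    Once per day the population is observed: true haplotype frequencies
    are recorded into a :class:`MullerSeries` (genealogy tracked at
    mutation time, so nesting is exact) and a multinomial clone-typing
    sample is drawn.  ``deterministic=True`` replaces all sampling with
    expected values, reproducing the haploid-selection closed forms.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = float(config.population_size)
    t = config.generations_per_day
    loci = {l.name: l for l in config.loci}

    yfp, cfp = Haplotype("YFP"), Haplotype("CFP")
    counts: dict[Haplotype, float] = {
        yfp: n * config.marker_split,
        cfp: n * (1.0 - config.marker_split),
    }
    parent: dict[Haplotype, Haplotype | None] = {yfp: None, cfp: None}
    # standing variation: initial mutants split across markers
    for spec in config.loci:
        if spec.initial_frequency > 0:
            for root in (yfp, cfp):
                moved = counts[root] * spec.initial_frequency
                mut = Haplotype(root.marker, frozenset({spec.name}))
                counts[root] -= moved
                counts[mut] = counts.get(mut, 0.0) + moved
                parent.setdefault(mut, root)

    days_axis = [0]
    snapshots = [dict(counts)]
    typing: list[TypingSample] = []

    def observe(day: int) -> None:
        total = sum(counts.values())
        if total <= 0:
            raise PopulationExtinctError(f"population extinct at day {day}")
        if config.sampling.clones_per_timepoint > 0 and (
            day % config.sampling.typing_interval_days == 0
        ):
            haps = [h for h, c in counts.items() if c > 0]
            probs = np.array([counts[h] for h in haps]) / total
            if config.deterministic:
                typed = {
                    h: config.sampling.clones_per_timepoint * p
                    for h, p in zip(haps, probs)
                }
                typed = {h: int(round(v)) for h, v in typed.items() if v > 0}
            else:
                draws = rng.multinomial(config.sampling.clones_per_timepoint, probs)
                typed = {h: int(d) for h, d in zip(haps, draws) if d > 0}
            if typed:
                typing.append(TypingSample(day=float(day), counts=typed))

    observe(0)
    for day in range(1, config.days + 1):
        for _ in range(t):
            total = sum(counts.values())
            if total <= 0:
                raise PopulationExtinctError(f"population extinct at day {day}")
            # selection + drift
            haps = list(counts)
            freqs = {
                name: _locus_frequency(counts, name, total) for name in loci
            }
            # fitness weight e^s so that s is exactly the per-generation
            # log-ratio slope the endpoint estimator measures
            w = np.exp(
                [
                    sum(
                        loci[name].coefficient(
                            h.mutations - {name}, freqs[name], t
                        )
                        for name in h.mutations
                    )
                    for h in haps
                ]
            )
            p = np.array([counts[h] for h in haps]) * w
            p /= p.sum()
            if config.deterministic:
                new = {h: n * pi for h, pi in zip(haps, p)}
            else:
                draws = rng.multinomial(int(n), p)
                new = {h: float(d) for h, d in zip(haps, draws) if d > 0}
            counts = new
            if not counts:
                raise PopulationExtinctError(f"population extinct at day {day}")
            # mutation: one derived allele class per locus
            for name, spec in loci.items():
                if spec.mutation_rate == 0:
                    continue
                for h in list(counts):
                    if name in h.mutations or counts[h] <= 0:
                        continue
                    lam = counts[h] * spec.mutation_rate
                    n_mut = lam if config.deterministic else float(rng.poisson(lam))
                    n_mut = min(n_mut, counts[h])
                    if n_mut <= 0:
                        continue
                    child = Haplotype(h.marker, h.mutations | {name})
                    counts[h] -= n_mut
                    counts[child] = counts.get(child, 0.0) + n_mut
                    parent.setdefault(child, h)
        observe(day)
        days_axis.append(day)
        snapshots.append(dict(counts))

    haps_all = sorted(parent, key=lambda h: (h.marker, len(h.mutations), h.label))
    freq = np.zeros((len(haps_all), len(days_axis)))
    for j, snap in enumerate(snapshots):
        total = sum(snap.values())
        for i, h in enumerate(haps_all):
            freq[i, j] = snap.get(h, 0.0) / total
    series = MullerSeries(
        days=days_axis,
        haplotypes=haps_all,
        frequencies=freq,
        parent={h: parent[h] for h in haps_all},
        generations_per_day=t,
    )
    series.validate_nesting()
    return series, typing


def simulate_competition(
    s_true: float | tuple[float, float],
    days: int,
    replicates: int = 1,
    start_freq: float = 0.5,
    colonies_per_day: int | None = None,
    seed: int | None = None,
    generations_per_day: int = DEFAULT_GENERATIONS_PER_DAY,
) -> list[CompetitionTrajectory]:
    """Two-competitor competition with optional colony-count noise.

    With a constant coefficient the focal log-odds increase by
    ``s_true * generations_per_day`` per day (haploid selection); with a
    frequency-dependent pair ``(a, b)`` the daily frequency change is
    the linear map ``delta_f = a + b f`` (the model the FDS regression
    fits).  ``colonies_per_day=None`` gives noiseless trajectories
    recorded as exact frequencies; otherwise daily focal counts are
    binomial draws out of ``colonies_per_day`` colonies.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if not (0.0 < start_freq < 1.0):
        raise ValueError("start_freq must be strictly inside (0, 1)")
    if colonies_per_day is not None and colonies_per_day < 1:
        raise ValueError("colonies_per_day must be >= 1")
    rng = np.random.default_rng(seed)
    fds = isinstance(s_true, tuple)

    f = np.empty(days + 1)
    f[0] = start_freq
    for d in range(days):
        if fds:
            a, b = s_true
            f[d + 1] = np.clip(f[d] + a + b * f[d], 0.0, 1.0)
        else:
            logit = np.log(f[d] / (1 - f[d])) + s_true * generations_per_day
            f[d + 1] = 1.0 / (1.0 + np.exp(-logit))

    day_axis = np.arange(days + 1, dtype=float)
    out = []
    for r in range(replicates):
        meta = {"s_true": s_true, "start_freq": start_freq}
        if colonies_per_day is None:
            traj = CompetitionTrajectory(
                day=day_axis,
                focal_count=f,
                reference_count=1.0 - f,
                generations_per_day=generations_per_day,
                replicate_id=f"rep{r + 1}",
                is_frequency=True,
                meta=meta,
            )
        else:
            focal = rng.binomial(colonies_per_day, f)
            traj = CompetitionTrajectory(
                day=day_axis,
                focal_count=focal,
                reference_count=colonies_per_day - focal,
                generations_per_day=generations_per_day,
                replicate_id=f"rep{r + 1}",
                meta=meta,
            )
        out.append(traj)
    return out


def sample_lea_coulson(
    m: float,
    size: int,
    rng: np.random.Generator,
    fitness: float = 1.0,
    max_clone_size: float = 1e12,
) -> np.ndarray:
    """Exact Lea-Coulson mutant counts via the compound-Poisson form.

    The number of mutational events per culture is Poisson(m); each
    event founds a clone whose final size follows
    ``P(X >= x) = x^(-1/fitness)`` (for neutral mutants, fitness 1,
    ``P(X = j) = 1/(j(j+1))``, sampled as ``floor(1/U)``).  This is
    distributionally identical to the MSS-recursion pmf for any m,
    including values far beyond a feasible recursion support.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    if fitness <= 0:
        raise ValueError("fitness must be positive")
    counts = np.zeros(size, dtype=np.int64)
    n_events = rng.poisson(m, size=size)
    for i, k in enumerate(n_events):
        if k == 0:
            continue
        u = rng.random(k)
        sizes = np.minimum(np.floor(u ** (-fitness)), max_clone_size)
        counts[i] = int(sizes.sum())
    return counts


def simulate_fluctuation_assay(
    mu: float,
    n0: float = 1000.0,
    nt: float = 2e9,
    cultures: int = 10,
    seed: int | None = None,
    fitness: float = 1.0,
) -> FluctuationExperiment:
    """Fluctuation assay: parallel cultures with Lea-Coulson mutant counts.

    ``m = mu * nt`` expected mutational events per culture.  Clone sizes
    are capped at ``nt``.  ``fitness`` is the mutants' relative growth
    rate during the assay (1 = the neutral case the estimators assume).
    """
    if not (nt > n0 >= 1):
        raise ValueError("require nt > n0 >= 1")
    if cultures < 2:
        raise ValueError("need at least 2 cultures")
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    m = mu * nt
    if m > 1e7:
        raise ValueError(
            f"m = mu*nt = {m:.3g} is implausibly large; plate a diluted "
            "aliquot (reduce effective nt) or lower mu"
        )
    rng = np.random.default_rng(seed)
    counts = sample_lea_coulson(m, cultures, rng, fitness=fitness, max_clone_size=nt)
    return FluctuationExperiment(mutant_counts=counts, nt=nt, n0=n0)


def gaussian_gc_bias(optimum: float = 50.0, width: float = 30.0):
    """Bell-shaped coverage bias peaking at ``optimum`` GC%."""

    def bias(gc: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((np.asarray(gc, float) - optimum) / width) ** 2)

    return bias


def simulate_coverage(
    genome_length: int,
    window: int = 250,
    mean_depth: float = 100.0,
    gc_track: np.ndarray | None = None,
    gc_bias=None,
    cnv_regions: Sequence[tuple[int, int, float]] = (),
    seed: int | None = None,
) -> CoverageProfile:
    """Window read depth ~ Poisson(mean_depth * gc_bias(gc) * copy_ratio).

    A trailing partial window is dropped.  ``gc_track`` gives per-window
    integer GC%; by default a smooth sinusoidal track between ~35 and
    ~65% is generated.  ``cnv_regions`` are (start, end, copy_ratio)
    tuples, 0-based half-open; ratio 0 simulates a deletion.  Ground
    truth is recorded in ``profile.meta``.
    """
    n_windows = genome_length // window
    if n_windows < 1:
        raise ValueError("genome shorter than one window")
    rng = np.random.default_rng(seed)
    start = np.arange(n_windows, dtype=np.int64) * window
    end = start + window

    if gc_track is None:
        mid = (start + end) / 2
        gc = np.rint(50 + 15 * np.sin(2 * np.pi * mid / 2.0e5)).astype(int)
    else:
        gc = np.asarray(gc_track, dtype=int)
        if len(gc) != n_windows:
            raise ValueError("gc_track length must equal the window count")
    gc = np.clip(gc, 0, 100)

    bias = np.ones(n_windows) if gc_bias is None else np.asarray(gc_bias(gc), float)
    copy = np.ones(n_windows)
    for s, e, ratio in cnv_regions:
        if not (0 <= s < e <= genome_length):
            raise ValueError(f"CNV region ({s}, {e}) outside genome")
        if ratio < 0:
            raise ValueError("copy ratio must be >= 0")
        sel = (start >= s) & (end <= e)
        copy[sel] = ratio

    lam = mean_depth * bias * copy
    depth = rng.poisson(lam).astype(float)
    return CoverageProfile(
        start=start,
        end=end,
        depth=depth,
        gc_pct=gc,
        meta={
            "mean_depth": mean_depth,
            "cnv_regions": list(cnv_regions),
            "seed": seed,
        },
    )


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def synthetic_population_series(population: str = "2.10") -> MullerSeries:
    """Synthetic population time courses shaped like the study's two
    sequenced populations (a stand-in for the supplementary haplotype
    table, which is not redistributable here).

    ``"2.10"``: a hard sweep — a radA-dup haplotype rises logistically at
    0.14 per generation from day 2, reaching near-fixation, with an srlR
    mutant emerging on that background at day 7 and hovering at low
    frequency thereafter (balancing-selection-like).

    ``"2.7"``: clonal interference — an arcA haplotype rises at 0.09 per
    generation from day 7; from day 11 a pphB mutation appears on the
    arcA background and a focA haplotype rises on the opposite marker.

    Both series use 18 generations/day over 24 days, so the generating
    per-generation logit slopes (0.14 and 0.09) are exactly what
    trajectory-based estimation over the clean windows recovers.
    """
    t = DEFAULT_GENERATIONS_PER_DAY
    days = np.arange(25, dtype=float)
    if population == "2.10":
        yfp, cfp = Haplotype("YFP"), Haplotype("CFP")
        rad = Haplotype("YFP", frozenset({"radA-dup"}))
        srl = Haplotype("YFP", frozenset({"radA-dup", "srlR"}))
        # logit slope 0.14/gen * 18 gen/day = 2.52/day; f(day 2) = 0.04
        logit0 = np.log(0.04 / 0.96) - 2.52 * 2
        clade = np.where(days >= 2, _logistic(logit0 + 2.52 * days), 0.0)
        srl_f = np.where(days >= 7, 0.06 + (0.10 - 0.06) * (days - 7) / 17, 0.0)
        srl_f = np.minimum(srl_f, clade)
        rad_f = clade - srl_f
        root = (1.0 - clade) / 2.0
        haps = [cfp, yfp, rad, srl]
        freq = np.vstack([root, root, rad_f, srl_f])
        parent = {cfp: None, yfp: None, rad: yfp, srl: rad}
    elif population == "2.7":
        yfp, cfp = Haplotype("YFP"), Haplotype("CFP")
        arca = Haplotype("CFP", frozenset({"arcA"}))
        pphb = Haplotype("CFP", frozenset({"arcA", "pphB"}))
        foca = Haplotype("YFP", frozenset({"focA"}))
        # logit slope 0.09/gen * 18 = 1.62/day; f(day 7) = 0.10
        logit0 = np.log(0.10 / 0.90) - 1.62 * 7
        clade = np.where(
            days >= 7,
            np.where(
                days <= 10,
                _logistic(logit0 + 1.62 * days),
                # post-sweep plateau eroded by interference
                0.9347 - (0.9347 - 0.60) * (days - 11) / 13,
            ),
            0.0,
        )
        pphb_f = np.where(days >= 11, 0.06 + (0.20 - 0.06) * (days - 11) / 13, 0.0)
        pphb_f = np.minimum(pphb_f, clade)
        arca_f = clade - pphb_f
        foca_f = np.where(days >= 11, 0.02 + (0.30 - 0.02) * (days - 11) / 13, 0.0)
        root = (1.0 - clade - foca_f) / 2.0
        haps = [cfp, yfp, arca, pphb, foca]
        freq = np.vstack([root, root, arca_f, pphb_f, foca_f])
        parent = {cfp: None, yfp: None, arca: cfp, pphb: arca, foca: yfp}
    else:
        raise ValueError("population must be '2.10' or '2.7'")
    series = MullerSeries(
        days=days,
        haplotypes=haps,
        frequencies=freq,
        parent=parent,
        generations_per_day=t,
    )
    series.validate_nesting()
    return series


def synth_mutation_table(
    n_clones: int,
    mean_mutations_per_clone: float,
    locus_weights: dict[str, float],
    seed: int | None = None,
) -> MutationTable:
    """Random per-clone mutation table (Poisson counts, weighted loci).

    Each of ``n_clones`` clones (one per population, labelled 2.1,
    2.2, ...) receives Poisson(mean) mutations drawn over loci by
    weight; clones with zero mutations remain in the clone list so the
    spectrum denominator is correct.
    """
    weights = np.array(list(locus_weights.values()), dtype=float)
    names = list(locus_weights)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("locus weights must be nonnegative with positive sum")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    categories = sorted(CATEGORIES - {"large_duplication", "large_deletion"})
    rows = []
    clones = []
    positions = {name: 1 + 5000 * i for i, name in enumerate(names)}
    for i in range(n_clones):
        clone = f"clone{i + 1}"
        pop = f"2.{i + 1}"
        clones.append(clone)
        k = rng.poisson(mean_mutations_per_clone)
        for locus in rng.choice(names, size=k, p=probs):
            cat = str(rng.choice(categories))
            rows.append(
                {
                    "clone_id": clone,
                    "population_id": pop,
                    "host_id": f"mouse{i + 1}",
                    "position": positions[locus],
                    "locus": locus,
                    "category": cat,
                    "region": "coding" if cat.startswith("SNP") else "intergenic",
                    "allele": f"{locus}-allele",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "clone_id",
            "population_id",
            "host_id",
            "position",
            "locus",
            "category",
            "region",
            "allele",
        ],
    )
    return MutationTable(df, clones=clones)
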