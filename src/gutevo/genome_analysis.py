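"""Mutation-table analytics and the read-depth CNV screen.

Two independent concerns live here:

* tabular analysis of per-clone mutation calls (spectrum by category and
  region, and gene-level parallelism across independently evolving
  populations, the classical signature of adaptive targets), and
* a copy-number screen on fixed-width (250 bp) genome coverage windows:
  depth is normalized by the mean coverage of windows with the same GC%
  and runs of windows with normalized ratio above 1.4 are called as
  duplications, runs with essentially no coverage as deletions.

Coordinates are 0-based half-open internally and in BED-style coverage
TSVs; mutation positions follow the 1-based convention of the reference
genome annotation (converters: ``pos_1based = start_0based + 1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "REGIONS",
    "MutationTable",
    "load_mutation_fixture",
    "MutationSpectrum",
    "mutation_spectrum",
    "parallel_targets",
    "CoverageProfile",
    "gc_normalize",
    "CnvCall",
    "call_cnv",
    "cnv_to_bed",
]

CATEGORIES = frozenset(
    {
        "SNP_synonymous",
        "SNP_nonsynonymous",
        "SNP_nonsense",
        "small_indel",
        "IS_insertion",
        "large_duplication",
        "large_deletion",
    }
)

#: large structural events are tallied separately from the coding /
#: intergenic split, matching how clone-sequencing totals are reported
REGIONS = frozenset({"coding", "intergenic", "structural"})

_COLUMNS = [
    "clone_id",
    "population_id",
    "host_id",
    "position",
    "locus",
    "category",
    "region",
    "allele",
]


class MutationTable:
    """Per-clone mutation records (one row per mutation call).

    Wraps a DataFrame with columns clone_id, population_id, host_id,
    position (1-based), locus, category, region, allele.  ``clones`` may
    list sequenced clones with zero mutations so that per-clone means
    use the full denominator.
    """

    def __init__(self, df: pd.DataFrame, clones: Sequence[str] | None = None):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = set(df["category"]) - CATEGORIES
        if bad:
            raise ValueError(f"unknown mutation categories: {sorted(bad)}")
        bad_r = set(df["region"]) - REGIONS
        if bad_r:
            raise ValueError(f"unknown regions: {sorted(bad_r)}")
        if (df["position"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")
        self.df = df.reset_index(drop=True)
        self.clones = (
            list(clones) if clones is not None else sorted(df["clone_id"].unique())
        )

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path, clones: Sequence[str] | None = None) -> "MutationTable":
        df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "population_id": str})
        return cls(df, clones=clones)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def concat(self, other: "MutationTable") -> "MutationTable":
        return MutationTable(
            pd.concat([self.df, other.df], ignore_index=True),
            clones=self.clones + [c for c in other.clones if c not in self.clones],
        )


_FIXTURES = {
    "first_colonization": "mutations_first_colonization.tsv",
    "second_colonization": "mutations_second_colonization.tsv",
}


def load_mutation_fixture(name: str = "second_colonization") -> MutationTable:
    """Packaged synthetic clone-mutation tables.

    These are synthetic reconstructions shaped like the published
    clone-sequencing supplementary table: they reproduce its marginal
    totals (mutation counts per clone, category and region breakdown,
    and the set of parallel target loci) without being the original
    records.  ``"combined"`` concatenates both colonizations (29 clones).
    """
    if name == "combined":
        return load_mutation_fixture("first_colonization").concat(
            load_mutation_fixture("second_colonization")
        )
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; options: "
                         f"{sorted(_FIXTURES) + ['combined']}") from None
    path = resources.files("gutevo.data") / fname
    with resources.as_file(path) as p:
        return MutationTable.from_tsv(p)


@dataclass
class MutationSpectrum:
    total: int
    by_category: dict[str, int]
    by_region: dict[str, int]
    per_clone: pd.Series
    mean_per_clone: float


def mutation_spectrum(table: MutationTable) -> MutationSpectrum:
    """Counts by category and region plus per-clone mutation counts.

    The per-clone mean uses all sequenced clones as denominator,
    including clones with zero mutations (listed in ``table.clones``).
    """
    if len(table.clones) == 0:
        raise ValueError("empty clone list")
    df = table.df
    per_clone = (
        df.groupby("clone_id").size().reindex(table.clones, fill_value=0)
    )
    return MutationSpectrum(
        total=len(df),
        by_category=df["category"].value_counts().to_dict(),
        by_region=df["region"].value_counts().to_dict(),
        per_clone=per_clone,
        mean_per_clone=float(per_clone.mean()),
    )


def parallel_targets(table: MutationTable, min_independent: int = 2) -> pd.DataFrame:
    """Loci mutated in at least ``min_independent`` distinct populations.

    Independent recurrence across separately evolving populations (i.e.
    different hosts) is the parallelism signal used to flag adaptive
    targets; repeat hits within one population count once.  Returns a
    DataFrame (locus, n_populations, n_clones) ranked by population
    count.
    """
    df = table.df
    if df["population_id"].isna().any() or (df["population_id"] == "").any():
        raise ValueError("population_id labels are required for parallelism")
    grouped = df.groupby("locus").agg(
        n_populations=("population_id", "nunique"),
        n_clones=("clone_id", "nunique"),
    )
    out = grouped[grouped["n_populations"] >= min_independent]
    return (
        out.sort_values(["n_populations", "n_clones"], ascending=False)
        .reset_index()
    )


# ---------------------------------------------------------------------------
# coverage / CNV screen
# ---------------------------------------------------------------------------


@dataclass
class CoverageProfile:
    """Fixed-width window coverage with per-window GC%.

    ``start``/``end`` are 0-based half-open; all windows share the same
    width (250 bp by default in this system).
    """

    start: np.ndarray
    end: np.ndarray
    depth: np.ndarray
    gc_pct: np.ndarray
    chrom: str = "genome"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        self.gc_pct = np.asarray(self.gc_pct, dtype=np.int64)
        n = len(self.start)
        if not (len(self.end) == len(self.depth) == len(self.gc_pct) == n):
            raise ValueError("column lengths differ")
        widths = self.end - self.start
        if n and (widths != widths[0]).any():
            raise ValueError("windows must have uniform width")
        if (self.depth < 0).any():
            raise ValueError("depth must be nonnegative")
        if ((self.gc_pct < 0) | (self.gc_pct > 100)).any():
            raise ValueError("gc_pct must be in [0, 100]")

    @property
    def window(self) -> int:
        return int(self.end[0] - self.start[0]) if len(self.start) else 0

    def sort(self) -> "CoverageProfile":
        order = np.argsort(self.start)
        return CoverageProfile(
            self.start[order], self.end[order], self.depth[order],
            self.gc_pct[order], self.chrom, dict(self.meta),
        )

    @classmethod
    def from_tsv(cls, path) -> "CoverageProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["start"].to_numpy(), df["end"].to_numpy(),
            df["depth"].to_numpy(), df["gc_pct"].to_numpy(),
            chrom=str(df["chrom"].iloc[0]) if len(df) else "genome",
        ).sort()

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "depth": self.depth,
                "gc_pct": self.gc_pct,
            }
        ).to_csv(path, sep="\t", index=False)


def gc_normalize(profile: CoverageProfile, min_bin_count: int = 10) -> np.ndarray:
    """Normalize depth by the mean coverage of windows with the same GC%.

    GC bins are at 1% resolution; occupied bins with fewer than
    ``min_bin_count`` windows are merged into the nearest (by GC%)
    sufficiently populated bin, with a warning.  Returns the per-window
    normalized ratio (genome-average copy number ~ 1).
    """
    if len(profile.start) == 0:
        return np.array([])
    gc = profile.gc_pct
    occupied, counts = np.unique(gc, return_counts=True)
    big = occupied[counts >= min_bin_count]
    assignment = {}
    sparse = []
    for g, c in zip(occupied, counts):
        if c >= min_bin_count or big.size == 0:
            assignment[g] = g
        else:
            assignment[g] = int(big[np.argmin(np.abs(big - g))])
            sparse.append(int(g))
    if sparse:
        warnings.warn(
            f"GC bins {sparse} have < {min_bin_count} windows; merged into "
            "their nearest populated bin",
            stacklevel=2,
        )
    group = np.array([assignment[g] for g in gc])
    ratios = np.empty(len(gc))
    for g in np.unique(group):
        mask = group == g
        mean = profile.depth[mask].mean()
        if mean == 0:
            raise ValueError(f"GC bin {g}% has zero mean coverage after merging")
        ratios[mask] = profile.depth[mask] / mean
    return ratios


@dataclass
class CnvCall:
    """One called copy-number variant (0-based half-open interval)."""

    start: int
    end: int
    kind: str  # duplication | deletion
    mean_ratio: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.kind not in ("duplication", "deletion"):
            raise ValueError("kind must be duplication or deletion")


def _runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Index runs of True, merging runs separated by <= merge_gap False."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    runs = []
    s = p = idx[0]
    for i in idx[1:]:
        if i - p <= merge_gap + 1:
            p = i
        else:
            runs.append((s, p))
            s = p = i
    runs.append((s, p))
    return runs


def call_cnv(
    profile: CoverageProfile,
    ratios: np.ndarray | None = None,
    dup_threshold: float = 1.4,
    del_threshold: float = 0.05,
    min_windows: int = 4,
    merge_gap: int = 1,
) -> list[CnvCall]:
    """Call duplications and deletions from GC-normalized window ratios.

    Duplications are maximal runs of windows with ratio above
    ``dup_threshold``; deletions ("absence of coverage") are runs below
    ``del_threshold``.  Runs separated by at most ``merge_gap``
    sub-threshold windows are merged, and merged runs need at least
    ``min_windows`` qualifying windows (1 kb at 250 bp windows) to
    suppress single-window Poisson noise.
    """
    if ratios is None:
        ratios = gc_normalize(profile)
    calls: list[CnvCall] = []
    for kind, mask in (
        ("duplication", ratios > dup_threshold),
        ("deletion", ratios < del_threshold),
    ):
        for s, e in _runs(mask, merge_gap):
            n_qual = int(mask[s : e + 1].sum())
            if n_qual < min_windows:
                continue
            calls.append(
                CnvCall(
                    start=int(profile.start[s]),
                    end=int(profile.end[e]),
                    kind=kind,
                    mean_ratio=float(ratios[s : e + 1].mean()),
                    n_windows=n_qual,
                )
            )
    calls.sort(key=lambda c: c.start)
    return calls


def cnv_to_bed(calls: Sequence[CnvCall], chrom: str = "genome") -> pd.DataFrame:
    """CNV calls as a BED6(+ratio) table."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "name": [c.kind for c in calls],
            "score": [c.n_windows for c in calls],
            "strand": ".",
            "ratio": [round(c.mean_ratio, 4) for c in calls],
        }
    )
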