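"""Efficiency-corrected relative expression from qPCR Cq values.

Relative expression of a target gene in an evolved clone versus its
ancestor is quantified by the Pfaffl ratio

    ratio = E_target ** dCq_target / E_ref ** dCq_ref,

with ``dCq = Cq(ancestor) - Cq(evolved)`` and E the per-cycle
amplification factor (2 = perfect doubling).  Technical replicates are
averaged on the Cq scale, biological replicates on the log2-ratio
scale; a two-sided one-sample t-test on the log2 ratios against 0
flags genes whose expression changed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QpcrMeasurement", "pfaffl_ratio", "analyze_qpcr"]

DEFAULT_EFFICIENCY = 2.0


@dataclass
class QpcrMeasurement:
    """One qPCR well: sample role, gene, condition and its Cq value."""

    sample: str  # "evolved" | "ancestor"
    gene: str
    condition: str  # e.g. "aerobic" | "anaerobic"
    cq: float
    bio_rep: int = 1
    tech_rep: int = 1
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self) -> None:
        if self.sample not in ("evolved", "ancestor"):
            raise ValueError("sample must be 'evolved' or 'ancestor'")
        if self.cq <= 0:
            raise ValueError("Cq must be positive")
        if not (1.0 <= self.efficiency <= 2.0):
            raise ValueError("efficiency must be in [1, 2]")


def pfaffl_ratio(
    dcq_target: float,
    dcq_ref: float,
    e_target: float = DEFAULT_EFFICIENCY,
    e_ref: float = DEFAULT_EFFICIENCY,
) -> tuple[float, float]:
    """Expression ratio and its log2 for one target/reference pair.

    With E = 2 for both genes and ``dcq_ref = 0`` this reduces to the
    familiar ``2 ** dCq``.  An efficiency of exactly 1 cannot amplify a
    Cq difference, so it is rejected when the corresponding dCq is
    nonzero.
    """
    for e, dcq, name in ((e_target, dcq_target, "target"), (e_ref, dcq_ref, "reference")):
        if not (1.0 <= e <= 2.0):
            raise ValueError(f"{name} efficiency must be in [1, 2]")
        if e == 1.0 and dcq != 0:
            raise ValueError(
                f"{name} efficiency of 1 cannot explain a nonzero delta-Cq"
            )
    ratio = e_target**dcq_target / e_ref**dcq_ref
    return float(ratio), float(np.log2(ratio))


def analyze_qpcr(
    measurements: pd.DataFrame,
    reference_gene: str = "hfq",
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-condition relative expression with 2SE and a t-test.

    ``measurements`` needs columns sample (evolved/ancestor), gene,
    condition, bio_rep, tech_rep, cq.  Technical replicates are averaged
    on the Cq scale; each biological replicate yields one Pfaffl ratio
    (evolved vs ancestor, normalized by ``reference_gene``); log2 ratios
    are summarized as mean +/- 2SE with a two-sided one-sample t-test
    against 0.  Per-gene efficiencies default to 2.0.
    """
    required = {"sample", "gene", "condition", "bio_rep", "tech_rep", "cq"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    genes = set(measurements["gene"])
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent from data")
    eff = dict(efficiencies or {})

    # technical replicates -> one Cq per (sample, gene, condition, bio_rep)
    cq = (
        measurements.groupby(["condition", "gene", "sample", "bio_rep"])["cq"]
        .mean()
        .unstack("sample")
    )
    if cq.isna().any().any():
        raise ValueError("each bio_rep needs both evolved and ancestor Cq values")
    dcq = cq["ancestor"] - cq["evolved"]

    rows = []
    for condition in sorted(measurements["condition"].unique()):
        ref_dcq = dcq.loc[condition, reference_gene]
        for gene in sorted(g for g in genes if g != reference_gene):
            try:
                target_dcq = dcq.loc[condition, gene]
            except KeyError:
                continue
            common = target_dcq.index.intersection(ref_dcq.index)
            log2 = np.array(
                [
                    pfaffl_ratio(
                        target_dcq.loc[b],
                        ref_dcq.loc[b],
                        eff.get(gene, DEFAULT_EFFICIENCY),
                        eff.get(reference_gene, DEFAULT_EFFICIENCY),
                    )[1]
                    for b in common
                ]
            )
            n = len(log2)
            se = float(log2.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            if n <= 1:
                p = np.nan
            elif se == 0.0:
                # degenerate noiseless replicates: the t statistic diverges
                p = 1.0 if np.allclose(log2.mean(), 0.0) else 0.0
            else:
                p = float(stats.ttest_1samp(log2, 0.0).pvalue)
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "log2_ratio": float(log2.mean()),
                    "ratio": float(2.0 ** log2.mean()),
                    "se": se,
                    "two_se": 2 * se,
                    "n_bio_reps": n,
                    "p_value": p,
                    "significant": bool(p < 0.05) if n > 1 else False,
                }
            )
    return pd.DataFrame(rows)
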