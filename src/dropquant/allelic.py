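"""Allelic fractional abundance with propagated Poisson error.

Given duplex measurements of the two alleles, the WT fractional abundance is

    f_WT = C_WT / (C_WT + C_MUT)

(equivalently in λ, since both channels share the droplet volume).  The
standard error propagates first-order from the two λ estimates:

    SE(f) = f (1 − f) sqrt( (SE λ_WT / λ_WT)² + (SE λ_MUT / λ_MUT)² )

with SE(f) = 0 by convention when either λ is exactly 0 (the fraction is then
pinned to a boundary).  Fractions are reported as percentages to 0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .quantify import TargetMeasurement, Z95


@dataclass(frozen=True)
class AllelicResult:
    """WT/MUT fractional abundances for one sample × assay (one replicate)."""

    sample_id: str
    assay_id: str
    f_wt: float
    se_f: float
    ci_low: float
    ci_high: float
    n_droplets: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_wt <= 1.0:
            raise DataError("f_wt must be in [0, 1]")

    @property
    def f_mut(self) -> float:
        return 1.0 - self.f_wt


@dataclass(frozen=True)
class GroupSummary:
    """Replicate summary for one group: per-assay and pooled mean WT fraction."""

    group: str
    per_assay_mean: Mapping[str, float]
    per_assay_sd: Mapping[str, float]
    per_assay_n: Mapping[str, int]
    pooled_mean_f_wt: float
    pooled_sd: float
    n_replicates: int


def allelic_fraction(
    m_wt: TargetMeasurement,
    m_mut: TargetMeasurement,
    sample_id: str = "",
    assay_id: str = "",
) -> AllelicResult:
    """Fractional abundance of the WT allele from paired WT/MUT measurements."""
    lam_w, lam_m = m_wt.lambda_hat, m_mut.lambda_hat
    if lam_w + lam_m <= 0.0:
        raise DataError("no template detected: both allele concentrations are zero")
    f = lam_w / (lam_w + lam_m)
    if lam_w == 0.0 or lam_m == 0.0:
        se = 0.0
    else:
        se = f * (1.0 - f) * math.hypot(m_wt.lambda_se / lam_w, m_mut.lambda_se / lam_m)
    return AllelicResult(
        sample_id=sample_id,
        assay_id=assay_id,
        f_wt=f,
        se_f=se,
        ci_low=max(0.0, f - Z95 * se),
        ci_high=min(1.0, f + Z95 * se),
        n_droplets=m_wt.n_total,
    )


def summarize_replicates(
    results: Iterable[AllelicResult],
    groups: Mapping[str, str] | None = None,
) -> list[GroupSummary]:
    """Summarize replicate allelic fractions per group.

    ``groups`` maps sample_id → group label; samples not listed form their
    own group.  Within a group, the per-assay mean and SD (sample SD, ddof=1;
    0 for a single replicate) are computed over replicates, and the pooled
    cross-assay value is the unweighted mean of the per-assay means — assays
    are independent views of the same allele ratio and count equally
    regardless of how many replicate wells each had.  The pooled SD is the
    sample SD over all replicate values of all assays.
    """
    results = list(results)
    if not results:
        raise DataError("summarize_replicates needs at least one result")
    groups = dict(groups or {})
    frame = pd.DataFrame(
        {
            "group": [groups.get(r.sample_id, r.sample_id) for r in results],
            "assay_id": [r.assay_id for r in results],
            "f_wt": [r.f_wt for r in results],
        }
    )
    out: list[GroupSummary] = []
    for group, sub in frame.groupby("group", sort=True):
        per_assay = sub.groupby("assay_id")["f_wt"].agg(["mean", "std", "count"])
        per_assay["std"] = per_assay["std"].fillna(0.0)
        values = sub["f_wt"].to_numpy()
        out.append(
            GroupSummary(
                group=str(group),
                per_assay_mean=per_assay["mean"].to_dict(),
                per_assay_sd=per_assay["std"].to_dict(),
                per_assay_n={k: int(v) for k, v in per_assay["count"].to_dict().items()},
                pooled_mean_f_wt=float(per_assay["mean"].mean()),
                pooled_sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                n_replicates=int(len(sub)),
            )
        )
    return out


def results_table(results: Iterable[AllelicResult]) -> pd.DataFrame:
    """Flatten allelic results into the documented percentage-scale schema."""
    rows = [
        {
            "sample_id": r.sample_id,
            "assay_id": r.assay_id,
            "f_wt_pct": round(100.0 * r.f_wt, 1),
            "f_mut_pct": round(100.0 * r.f_mut, 1),
            "se_pct": round(100.0 * r.se_f, 3),
            "ci_low_pct": round(100.0 * r.ci_low, 1),
            "ci_high_pct": round(100.0 * r.ci_high, 1),
            "n_droplets": r.n_droplets,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "assay_id", "f_wt_pct", "f_mut_pct", "se_pct",
                 "ci_low_pct", "ci_high_pct", "n_droplets"],
    )
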