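"""Allele-specific expression from per-SNP RNA-seq read counts.

A heterozygous transcribed SNP lets read pile-ups measure the same WT/MUT
ratio a ddPCR duplex assay does: f = wt / (wt + mut) per SNP, with a Wilson
score interval on the binomial proportion.  Per-sample aggregates are either
the unweighted mean over SNP regions (default — each SNP is an independent
view of the ratio) or the fraction of pooled read counts (which weights SNPs
by depth); the across-SNP SD quantifies the extra dispersion read counting
shows relative to droplet counting.
"""

from __future__ import annotations

import warnings

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .droplet_io import validate_snp_counts
from .errors import DataError

AGGREGATION_METHODS = ("mean_of_snps", "pooled_counts")


def per_snp_fraction(table: pd.DataFrame) -> pd.DataFrame:
    """WT fraction with Wilson 95% CI per (snp_id, sample_id) row.

    Zero-depth rows are excluded with a warning rather than failing the
    whole table.
    """
    df = validate_snp_counts(table)
    depth = df["wt_count"] + df["mut_count"]
    zero = depth == 0
    if zero.any():
        dropped = df.loc[zero, ["snp_id", "sample_id"]].itertuples(index=False, name=None)
        warnings.warn(f"excluding zero-depth rows: {sorted(dropped)}", stacklevel=2)
        df, depth = df[~zero].reset_index(drop=True), depth[~zero].reset_index(drop=True)
    if df.empty:
        raise DataError("no SNP rows with positive depth")
    lo, hi = proportion_confint(df["wt_count"], depth, alpha=0.05, method="wilson")
    out = df.copy()
    out["depth"] = depth
    out["f_wt"] = df["wt_count"] / depth
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out


def aggregate_fraction(table: pd.DataFrame, method: str = "mean_of_snps") -> pd.DataFrame:
    """Per-sample WT fraction aggregated over SNPs, plus across-SNP SD.

    ``mean_of_snps`` averages per-SNP fractions without depth weighting;
    ``pooled_counts`` sums reads first.  The two differ whenever depths are
    unequal across SNPs.
    """
    if method not in AGGREGATION_METHODS:
        raise DataError(f"unknown aggregation method {method!r}; expected {AGGREGATION_METHODS}")
    per_snp = per_snp_fraction(table)
    rows = []
    for sample, sub in per_snp.groupby("sample_id", sort=True):
        if method == "mean_of_snps":
            f = float(sub["f_wt"].mean())
        else:
            f = float(sub["wt_count"].sum() / sub["depth"].sum())
        sd = float(sub["f_wt"].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(
            {
                "sample_id": sample,
                "f_wt": f,
                "f_mut": 1.0 - f,
                "sd_across_snps": sd,
                "n_snps": int(len(sub)),
                "total_depth": int(sub["depth"].sum()),
                "method": method,
            }
        )
    return pd.DataFrame(rows)
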