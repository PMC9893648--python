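"""Biological read-outs built on concentration ratios.

Three estimators, all ratios of Poisson-corrected concentrations:

* transcripts per diploid genome — total (WT + MUT) cDNA concentration over
  the matched gDNA amplicon concentration from a split-tube isolation, times
  a diploid factor (default 2: a heterozygous SNP assay counts two genomic
  amplicons per diploid genome);
* copy number — target over reference-gene concentration times the reference
  copy number (default 2), optionally partitioned into WT/MUT copies by the
  genomic allelic fraction;
* knockdown — treated-over-control ratio of reference-normalized expression.

Ratio CIs use the first-order delta method on independent numerator and
denominator estimates: SE(R)/R = sqrt((SE_A/A)² + (SE_B/B)²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .allelic import AllelicResult
from .errors import DataError
from .quantify import TargetMeasurement, Z95, as_measurement


def _round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (so 10.5 → 11, −10.5 → −11)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _ratio_with_se(a: TargetMeasurement, b: TargetMeasurement) -> tuple[float, float]:
    if b.concentration <= 0:
        raise DataError("denominator concentration must be positive")
    r = a.concentration / b.concentration
    if a.concentration == 0:
        return r, 0.0
    rel = math.hypot(
        a.concentration_se / a.concentration, b.concentration_se / b.concentration
    )
    return r, r * rel


@dataclass(frozen=True)
class PerGenomeResult:
    """Transcripts per diploid genome from a paired cDNA/gDNA measurement."""

    transcripts_per_diploid_genome: float
    ci_low: float
    ci_high: float
    cdna_conc: float
    gdna_conc: float
    diploid_factor: float
    scaling: float


@dataclass(frozen=True)
class CopyNumberResult:
    """Total (and optionally allele-partitioned) copies per genome."""

    cn_total: float
    ci_low: float
    ci_high: float
    reference_copies: int
    cn_wt: float | None = None
    cn_mut: float | None = None

    @property
    def cn_total_int(self) -> int:
        return _round_half_away(self.cn_total)

    @property
    def cn_wt_int(self) -> int | None:
        return None if self.cn_wt is None else _round_half_away(self.cn_wt)

    @property
    def cn_mut_int(self) -> int | None:
        return None if self.cn_mut is None else _round_half_away(self.cn_mut)


@dataclass(frozen=True)
class KnockdownResult:
    """Treated expression relative to control, per target, plus knockdown %."""

    relative_total: float
    relative_wt: float
    relative_mut: float

    @property
    def knockdown_total_pct(self) -> float:
        return 100.0 * (1.0 - self.relative_total)

    @property
    def knockdown_wt_pct(self) -> float:
        return 100.0 * (1.0 - self.relative_wt)

    @property
    def knockdown_mut_pct(self) -> float:
        return 100.0 * (1.0 - self.relative_mut)


def copies_per_diploid_genome(
    cdna: TargetMeasurement | float,
    gdna: TargetMeasurement | float,
    diploid_factor: float = 2.0,
    scaling: float = 1.0,
) -> PerGenomeResult:
    """Estimate transcripts per diploid genome from paired cDNA/gDNA wells.

    ``scaling`` is a user-supplied cDNA/gDNA recovery ratio (default 1,
    i.e. the split-tube isolations are assumed to sample the same number of
    cells per µL of reaction).
    """
    cdna = as_measurement(cdna, "total")
    gdna = as_measurement(gdna, "total")
    if gdna.concentration <= 0:
        raise DataError("gDNA concentration must be positive")
    if diploid_factor <= 0 or scaling <= 0:
        raise DataError("diploid_factor and scaling must be positive")
    r, se = _ratio_with_se(cdna, gdna)
    value = diploid_factor * scaling * r
    half = Z95 * diploid_factor * scaling * se
    return PerGenomeResult(
        transcripts_per_diploid_genome=value,
        ci_low=max(0.0, value - half),
        ci_high=value + half,
        cdna_conc=cdna.concentration,
        gdna_conc=gdna.concentration,
        diploid_factor=diploid_factor,
        scaling=scaling,
    )


def cnv(
    target: TargetMeasurement | float,
    reference: TargetMeasurement | float,
    reference_copies: int = 2,
) -> CopyNumberResult:
    """Copy-number estimate: reference_copies × C_target / C_reference."""
    target = as_measurement(target, "total")
    reference = as_measurement(reference, "reference")
    if reference.concentration <= 0:
        raise DataError("reference concentration must be positive")
    if reference_copies <= 0:
        raise DataError("reference_copies must be positive")
    r, se = _ratio_with_se(target, reference)
    cn = reference_copies * r
    half = Z95 * reference_copies * se
    return CopyNumberResult(
        cn_total=cn,
        ci_low=max(0.0, cn - half),
        ci_high=cn + half,
        reference_copies=reference_copies,
    )


def partition_cn(
    cn: CopyNumberResult, fractions: AllelicResult | float
) -> CopyNumberResult:
    """Split a total copy number into WT/MUT copies by the genomic WT fraction.

    Continuous partitions always sum to the total; the integer report rounds
    each partition to the nearest whole copy (ties away from zero).
    """
    f_wt = fractions.f_wt if isinstance(fractions, AllelicResult) else float(fractions)
    if not 0.0 <= f_wt <= 1.0:
        raise DataError("WT fraction must be in [0, 1]")
    return replace(cn, cn_wt=cn.cn_total * f_wt, cn_mut=cn.cn_total * (1.0 - f_wt))


def knockdown(
    control_wt: TargetMeasurement | float,
    control_mut: TargetMeasurement | float,
    treated_wt: TargetMeasurement | float,
    treated_mut: TargetMeasurement | float,
    control_reference: TargetMeasurement | float,
    treated_reference: TargetMeasurement | float,
) -> KnockdownResult:
    """Silencing efficiency relative to a control-treated group.

    Within each group the target concentration is normalized to the
    reference-gene assay, then treated/control ratios are formed for the
    total (WT + MUT), WT and MUT targets.  Knockdown % = 100 × (1 − ratio).
    """
    cw = as_measurement(control_wt, "WT").concentration
    cm = as_measurement(control_mut, "MUT").concentration
    tw = as_measurement(treated_wt, "WT").concentration
    tm = as_measurement(treated_mut, "MUT").concentration
    cr = as_measurement(control_reference, "reference").concentration
    tr = as_measurement(treated_reference, "reference").concentration
    if cr <= 0 or tr <= 0:
        raise DataError("reference-gene concentration must be positive in both groups")
    if cw + cm <= 0:
        raise DataError("zero control expression: knockdown undefined")

    def rel(c_treated: float, c_control: float) -> float:
        if c_control <= 0:
            return float("nan")
        return (c_treated / tr) / (c_control / cr)

    return KnockdownResult(
        relative_total=rel(tw + tm, cw + cm),
        relative_wt=rel(tw, cw),
        relative_mut=rel(tm, cm),
    )
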