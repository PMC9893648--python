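"""Droplet classification and Poisson concentration estimation.

ddPCR partitions a reaction into ~20,000 nanoliter droplets.  A droplet is
scored positive on a channel when its fluorescence exceeds a threshold; the
positive fraction p estimates the probability that a droplet received at least
one template copy.  Under Poisson partitioning with mean occupancy λ,
p = 1 − e^−λ, so

    λ̂ = −ln(1 − k/n),        concentration = λ̂ / V_d  (copies/µL)

with V_d the droplet volume.  The standard error of λ̂ follows from the delta
method on the binomial count: SE(λ̂) = sqrt(p̂ / (n (1 − p̂))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .droplet_io import DropletWell
from .errors import DataError, NoClusterStructureError, SaturatedWellError

#: Droplet volume of the QX200 generation chemistry, µL (0.85 nL).
DEFAULT_DROPLET_VOLUME_UL = 0.00085

#: Wells with fewer accepted droplets are flagged (never dropped).
DEFAULT_MIN_DROPLETS = 10_000

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ClassifiedWell:
    """Four-quadrant droplet counts for a duplex well."""

    n_total: int
    k_ch1_pos: int
    k_ch2_pos: int
    k_double_pos: int
    k_double_neg: int
    threshold_ch1: float
    threshold_ch2: float
    low_droplet_flag: bool = False

    def __post_init__(self) -> None:
        only1 = self.k_ch1_pos - self.k_double_pos
        only2 = self.k_ch2_pos - self.k_double_pos
        if only1 < 0 or only2 < 0:
            raise DataError("double-positive count exceeds a channel's positive count")
        if only1 + only2 + self.k_double_pos + self.k_double_neg != self.n_total:
            raise DataError("quadrant counts do not sum to n_total")


@dataclass(frozen=True)
class TargetMeasurement:
    """Poisson-corrected concentration for one target in one sample.

    ``lambda_hat`` is copies per droplet; ``concentration`` and the 95% CI are
    copies/µL.  ``k_pos``/``n_total`` retain the counts the estimate came
    from so replicate wells can be pooled before correction.
    """

    target: str
    lambda_hat: float
    lambda_se: float
    concentration: float
    ci_low: float
    ci_high: float
    n_total: int
    k_pos: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL

    @classmethod
    def from_concentration(
        cls,
        concentration: float,
        target: str = "total",
        droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    ) -> "TargetMeasurement":
        """Wrap a known concentration (no count data, zero uncertainty).

        Used for desk arithmetic on published concentration ratios.
        """
        if concentration < 0:
            raise DataError("concentration must be non-negative")
        lam = concentration * droplet_volume
        return cls(
            target=target,
            lambda_hat=lam,
            lambda_se=0.0,
            concentration=concentration,
            ci_low=concentration,
            ci_high=concentration,
            n_total=0,
            k_pos=0,
            droplet_volume=droplet_volume,
        )

    @property
    def concentration_se(self) -> float:
        return self.lambda_se / self.droplet_volume


def as_measurement(value: "TargetMeasurement | float", target: str = "total") -> TargetMeasurement:
    """Coerce a bare concentration (copies/µL) into a TargetMeasurement."""
    if isinstance(value, TargetMeasurement):
        return value
    return TargetMeasurement.from_concentration(float(value), target=target)


def auto_threshold(amplitudes: Sequence[float] | np.ndarray) -> float:
    """Split 1-D amplitudes into two clusters and return the midpoint threshold.

    Deterministic two-means: centers initialised at the 5th/95th percentiles,
    at most 100 iterations, convergence tolerance 1e-6 on the centers.  The
    split is rejected (``NoClusterStructureError``) when the final centers are
    closer than twice the summed within-cluster spreads — the signature of a
    single cluster split in half.
    """
    x = np.asarray(amplitudes, dtype=float).ravel()
    if x.size < 100:
        raise DataError(f"auto_threshold needs at least 100 droplets, got {x.size}")
    if np.ptp(x) == 0.0:
        raise NoClusterStructureError("no cluster structure: all amplitudes identical")
    lo, hi = np.percentile(x, [5.0, 95.0])
    if hi <= lo:
        raise NoClusterStructureError("no cluster structure: degenerate percentile init")
    for _ in range(100):
        assign_hi = np.abs(x - hi) < np.abs(x - lo)
        if not assign_hi.any() or assign_hi.all():
            raise NoClusterStructureError("no cluster structure: a cluster emptied")
        new_lo, new_hi = x[~assign_hi].mean(), x[assign_hi].mean()
        shift = max(abs(new_lo - lo), abs(new_hi - hi))
        lo, hi = new_lo, new_hi
        if shift < 1e-6:
            break
    sd_lo = float(x[~assign_hi].std())
    sd_hi = float(x[assign_hi].std())
    if (hi - lo) < 2.0 * (sd_lo + sd_hi):
        raise NoClusterStructureError(
            "no cluster structure: cluster separation "
            f"{hi - lo:.1f} below 2x within-cluster spread {sd_lo + sd_hi:.1f}"
        )
    return float((lo + hi) / 2.0)


def classify(
    well: DropletWell,
    thresholds: str | Sequence[float | str] = "auto",
    min_droplets: int = DEFAULT_MIN_DROPLETS,
) -> ClassifiedWell:
    """Score droplets positive/negative per channel and tally quadrants.

    ``thresholds`` is "auto" (both channels), or a (ch1, ch2) pair where each
    entry is a fluorescence cutoff or "auto".  A droplet exactly at the
    threshold counts as negative (strictly greater is positive).
    """
    amp = well.amplitudes
    if thresholds == "auto":
        thresholds = ("auto", "auto")
    if len(thresholds) != 2:
        raise DataError("thresholds must be 'auto' or a (ch1, ch2) pair")
    resolved: list[float] = []
    for ch, t in enumerate(thresholds):
        if isinstance(t, str):
            if t != "auto":
                raise DataError(f"unknown threshold mode {t!r}")
            resolved.append(auto_threshold(amp[:, ch]))
        else:
            resolved.append(float(t))
    pos1 = amp[:, 0] > resolved[0]
    pos2 = amp[:, 1] > resolved[1]
    n = amp.shape[0]
    k_double = int(np.count_nonzero(pos1 & pos2))
    return ClassifiedWell(
        n_total=n,
        k_ch1_pos=int(np.count_nonzero(pos1)),
        k_ch2_pos=int(np.count_nonzero(pos2)),
        k_double_pos=k_double,
        k_double_neg=int(np.count_nonzero(~pos1 & ~pos2)),
        threshold_ch1=resolved[0],
        threshold_ch2=resolved[1],
        low_droplet_flag=n < min_droplets,
    )


def estimate_concentration(
    k_pos: int,
    n_total: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    target: str = "total",
    exact_ci: bool = False,
) -> TargetMeasurement:
    """Poisson-correct a positive-droplet count into copies/µL with a 95% CI.

    The default CI is the delta-method normal interval on λ̂, floored at 0;
    ``exact_ci=True`` switches to a Clopper–Pearson binomial interval on p
    mapped through −ln(1 − p).  When k = 0 the delta SE collapses to zero, so
    the upper bound falls back to the SE evaluated at one positive droplet.
    """
    if n_total <= 0:
        raise DataError("n_total must be positive")
    if not 0 <= k_pos <= n_total:
        raise DataError(f"k_pos={k_pos} outside [0, n_total={n_total}]")
    if droplet_volume <= 0:
        raise DataError("droplet_volume must be positive")
    if k_pos == n_total:
        raise SaturatedWellError(
            f"saturated well: all {n_total} droplets positive, concentration not estimable"
        )
    p = k_pos / n_total
    lam = -math.log1p(-p)
    se = math.sqrt(p / (n_total * (1.0 - p)))
    if exact_ci:
        p_lo = 0.0 if k_pos == 0 else float(stats.beta.ppf(0.025, k_pos, n_total - k_pos + 1))
        p_hi = float(stats.beta.ppf(0.975, k_pos + 1, n_total - k_pos))
        lam_lo, lam_hi = -math.log1p(-p_lo), -math.log1p(-p_hi)
    else:
        se_hi = se
        if k_pos == 0:
            p1 = 1.0 / n_total
            se_hi = math.sqrt(p1 / (n_total * (1.0 - p1)))
        lam_lo = max(0.0, lam - Z95 * se)
        lam_hi = lam + Z95 * se_hi
    return TargetMeasurement(
        target=target,
        lambda_hat=lam,
        lambda_se=se,
        concentration=lam / droplet_volume,
        ci_low=lam_lo / droplet_volume,
        ci_high=lam_hi / droplet_volume,
        n_total=n_total,
        k_pos=k_pos,
        droplet_volume=droplet_volume,
    )


def merge_wells(measurements: Iterable[TargetMeasurement], exact_ci: bool = False) -> TargetMeasurement:
    """Pool replicate wells of one target by summing counts before correction.

    Pooling raw counts (the digital-PCR convention) is not the same as
    averaging per-well concentrations when droplet counts differ.
    """
    ms = list(measurements)
    if not ms:
        raise DataError("merge_wells needs at least one measurement")
    targets = {m.target for m in ms}
    if len(targets) != 1:
        raise DataError(f"cannot merge measurements of different targets: {sorted(targets)}")
    volumes = {m.droplet_volume for m in ms}
    if len(volumes) != 1:
        raise DataError("cannot merge measurements with different droplet volumes")
    if any(m.n_total == 0 for m in ms):
        raise DataError("cannot merge measurements lacking count data")
    return estimate_concentration(
        k_pos=sum(m.k_pos for m in ms),
        n_total=sum(m.n_total for m in ms),
        droplet_volume=ms[0].droplet_volume,
        target=ms[0].target,
        exact_ci=exact_ci,
    )


def total_measurement(m_a: TargetMeasurement, m_b: TargetMeasurement) -> TargetMeasurement:
    """Sum two targets measured in the same well(s) into a 'total' measurement.

    Poisson means add, so λ_total = λ_a + λ_b; the SEs combine in quadrature
    (the two channels' occupancies are independent draws).
    """
    if m_a.droplet_volume != m_b.droplet_volume:
        raise DataError("cannot sum measurements with different droplet volumes")
    lam = m_a.lambda_hat + m_b.lambda_hat
    se = math.hypot(m_a.lambda_se, m_b.lambda_se)
    v = m_a.droplet_volume
    return TargetMeasurement(
        target="total",
        lambda_hat=lam,
        lambda_se=se,
        concentration=lam / v,
        ci_low=max(0.0, lam - Z95 * se) / v,
        ci_high=(lam + Z95 * se) / v,
        n_total=m_a.n_total,
        k_pos=m_a.k_pos + m_b.k_pos,
        droplet_volume=v,
    )


def measure_well(
    well: DropletWell,
    ch1_target: str = "WT",
    ch2_target: str | None = "MUT",
    thresholds: str | Sequence[float | str] = "auto",
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    exact_ci: bool = False,
) -> tuple[ClassifiedWell, dict[str, TargetMeasurement]]:
    """Classify one well and estimate a concentration per mapped channel."""
    cw = classify(well, thresholds=thresholds, min_droplets=min_droplets)
    out = {
        ch1_target: estimate_concentration(
            cw.k_ch1_pos, cw.n_total, droplet_volume, target=ch1_target, exact_ci=exact_ci
        )
    }
    if ch2_target is not None:
        out[ch2_target] = estimate_concentration(
            cw.k_ch2_pos, cw.n_total, droplet_volume, target=ch2_target, exact_ci=exact_ci
        )
    return cw, out
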