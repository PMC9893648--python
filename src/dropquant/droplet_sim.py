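"""Seeded generator of synthetic droplet-level ddPCR data.

The generator inverts the quantification model: each droplet independently
receives WT and MUT template copies from Poisson distributions with means
conc × droplet_volume, occupancy > 0 on a target places the droplet in that
channel's positive fluorescence cluster, and amplitudes are drawn from normal
clusters with optional uniform "rain" between the cluster means.  Ground-truth
occupancy labels ride along on every simulated well so downstream estimates
can be checked against what the droplets actually contained.

Amplitude units are synthetic (arbitrary fluorescence units); the defaults —
negative cluster at 2,000 a.u., positive at 8,000 a.u., SD 300 — are chosen
only to be well separated, since real instrument scales vary by assay and dye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .droplet_io import AssayDefinition, DropletWell, PlateMetadata
from .errors import ConfigError, DataError
from .quantify import DEFAULT_DROPLET_VOLUME_UL

DEFAULT_N_DROPLETS = 20_000

#: Per-channel expected positive fraction above which a well is flagged saturated.
SATURATION_FRACTION = 0.999


@dataclass(frozen=True)
class AmplitudeModel:
    """Two-cluster fluorescence model for a duplex ddPCR well.

    ``rain_fraction`` of droplets lose their cluster amplitude and instead
    draw uniformly between the negative and positive cluster means on both
    channels — the intermediate-fluorescence droplets that stress
    thresholding.  ``crosstalk_shift`` is added to the *off* channel of a
    positive droplet to emulate spectral bleed-through.
    """

    neg_mean_ch1: float = 2000.0
    neg_mean_ch2: float = 2000.0
    pos_mean_ch1: float = 8000.0
    pos_mean_ch2: float = 8000.0
    neg_sd: float = 300.0
    pos_sd: float = 300.0
    rain_fraction: float = 0.01
    crosstalk_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.pos_mean_ch1 <= self.neg_mean_ch1 or self.pos_mean_ch2 <= self.neg_mean_ch2:
            raise DataError("positive cluster mean must exceed negative cluster mean")
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise DataError("cluster SDs must be positive")
        if not 0.0 <= self.rain_fraction < 0.5:
            raise DataError("rain_fraction must be in [0, 0.5)")

    def midpoints(self) -> tuple[float, float]:
        """Midpoint between cluster means per channel — the natural threshold."""
        return (
            (self.neg_mean_ch1 + self.pos_mean_ch1) / 2.0,
            (self.neg_mean_ch2 + self.pos_mean_ch2) / 2.0,
        )

    def rain_robust_thresholds(self, n_sd: float = 3.0) -> tuple[float, float]:
        """Thresholds just below each positive cluster (mean − n_sd·SD).

        A midpoint threshold scores half of the uniform rain band positive,
        an additive false-positive rate of rain_fraction/2 per channel that
        dominates low-occupancy wells.  Sitting n_sd SDs below the positive
        cluster keeps essentially all true positives (99.87% at 3 SD) while
        only the top sliver of the rain band crosses — the usual manual
        practice of thresholding tight under the positive cloud.
        """
        return (
            self.pos_mean_ch1 - n_sd * self.pos_sd,
            self.pos_mean_ch2 - n_sd * self.pos_sd,
        )


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for one simulated well: concentrations, noise model, seed."""

    conc_wt: float
    conc_mut: float
    n_droplets: int = DEFAULT_N_DROPLETS
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    amplitude_model: AmplitudeModel = field(default_factory=AmplitudeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_wt < 0 or self.conc_mut < 0:
            raise DataError("concentrations must be non-negative")
        if self.n_droplets <= 0:
            raise DataError("n_droplets must be positive")
        if self.droplet_volume <= 0:
            raise DataError("droplet_volume must be positive")


@dataclass(frozen=True)
class WellTruth:
    """Per-droplet occupancy labels attached to simulated wells."""

    spec: SimulationSpec
    wt_copies: np.ndarray
    mut_copies: np.ndarray
    rain: np.ndarray  # boolean mask of rain-reassigned droplets

    @property
    def lambda_wt(self) -> float:
        return self.spec.conc_wt * self.spec.droplet_volume

    @property
    def lambda_mut(self) -> float:
        return self.spec.conc_mut * self.spec.droplet_volume


def simulate_well(
    spec: SimulationSpec,
    well_id: str = "A01",
    sample_id: str = "sim",
    assay_id: str = "sim",
) -> DropletWell:
    """Simulate one duplex well; fully reproducible from ``spec.seed``.

    Wells whose expected positive fraction exceeds 99.9% on a channel carry a
    ``saturated_ch1``/``saturated_ch2`` flag (quantification will refuse only
    if *every* droplet actually came up positive).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_droplets
    m = spec.amplitude_model
    lam_wt = spec.conc_wt * spec.droplet_volume
    lam_mut = spec.conc_mut * spec.droplet_volume

    wt = rng.poisson(lam_wt, size=n)
    mut = rng.poisson(lam_mut, size=n)
    pos1 = wt > 0
    pos2 = mut > 0

    ch1 = np.where(
        pos1,
        rng.normal(m.pos_mean_ch1, m.pos_sd, size=n),
        rng.normal(m.neg_mean_ch1, m.neg_sd, size=n),
    )
    ch2 = np.where(
        pos2,
        rng.normal(m.pos_mean_ch2, m.pos_sd, size=n),
        rng.normal(m.neg_mean_ch2, m.neg_sd, size=n),
    )
    if m.crosstalk_shift:
        ch2 = ch2 + np.where(pos1 & ~pos2, m.crosstalk_shift, 0.0)
        ch1 = ch1 + np.where(pos2 & ~pos1, m.crosstalk_shift, 0.0)

    rain = rng.random(n) < m.rain_fraction
    n_rain = int(rain.sum())
    if n_rain:
        ch1[rain] = rng.uniform(m.neg_mean_ch1, m.pos_mean_ch1, size=n_rain)
        ch2[rain] = rng.uniform(m.neg_mean_ch2, m.pos_mean_ch2, size=n_rain)

    flags = []
    if 1.0 - np.exp(-lam_wt) > SATURATION_FRACTION:
        flags.append("saturated_ch1")
    if 1.0 - np.exp(-lam_mut) > SATURATION_FRACTION:
        flags.append("saturated_ch2")

    return DropletWell(
        well_id=well_id,
        sample_id=sample_id,
        assay_id=assay_id,
        amplitudes=np.column_stack([ch1, ch2]),
        flags=tuple(flags),
        truth=WellTruth(spec=spec, wt_copies=wt, mut_copies=mut, rain=rain),
    )


# ---------------------------------------------------------------------------
# Experiment designs

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")

#: WT fractions of the seven-sample plasmid mixture validation series.
MIXTURE_SERIES_FRACTIONS = (1.0, 0.9, 0.75, 0.5, 0.25, 0.1, 0.0)


def _well_ids(n: int):
    return [f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}" for i in range(n)]


def _amplitude_model(design: Mapping[str, Any], **overrides: Any) -> AmplitudeModel:
    given = design.get("amplitude_model")
    if isinstance(given, AmplitudeModel):
        return given
    params = dict(overrides)
    params.update(given or {})
    return AmplitudeModel(**params)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def simulate_experiment(
    design: Mapping[str, Any],
) -> tuple[list[DropletWell], PlateMetadata, dict[str, AssayDefinition]]:
    """Build the wells of a named experiment design.

    Supported designs (``design["name"]``):

    ``mixture_series``
        Seven plasmid mixtures at a fixed total concentration (default 400
        copies/µL) spanning WT fractions 100%…0% — the assay-specificity
        validation series.
    ``het_gdna``
        Heterozygous genomic DNA: equal WT and MUT concentrations (default
        100 copies/µL each), 3 replicate wells — the 50:50 control.
    ``paired_cdna_gdna``
        Split-tube cDNA/gDNA pairs for the transcripts-per-diploid-genome
        estimator; rain-free by default (see docs on rain bias at low
        template concentrations).
    ``knockdown``
        Control vs treated duplex wells plus a single-channel reference-gene
        assay in both groups, for silencing-efficiency read-outs.
    ``cnv``
        Single-channel target (homozygous assay, no allele discrimination)
        plus reference-gene wells for copy-number estimation.

    Returns the wells, plate metadata rows, and assay definitions keyed by id.
    Unknown design names raise ``ConfigError``.
    """
    name = design.get("name")
    builders = {
        "mixture_series": _build_mixture_series,
        "het_gdna": _build_het_gdna,
        "paired_cdna_gdna": _build_paired_cdna_gdna,
        "knockdown": _build_knockdown,
        "cnv": _build_cnv,
    }
    if name not in builders:
        raise ConfigError(
            f"unknown design name {name!r}; expected one of {sorted(builders)}"
        )
    return builders[name](design)


def _common(design: Mapping[str, Any]):
    return (
        int(design.get("n_droplets", DEFAULT_N_DROPLETS)),
        float(design.get("droplet_volume", DEFAULT_DROPLET_VOLUME_UL)),
        int(design.get("seed", 0)),
    )


def _assemble(rows, specs, assays):
    wells = []
    meta = []
    ids = _well_ids(len(rows))
    for wid, row, spec in zip(ids, rows, specs):
        wells.append(
            simulate_well(spec, well_id=wid, sample_id=row["sample_id"], assay_id=row["assay_id"])
        )
        meta.append({"well_id": wid, **row, "amplitude_file": f"{wid}.csv"})
    return wells, PlateMetadata(pd.DataFrame(meta)), assays


def _build_mixture_series(design):
    n, vol, seed = _common(design)
    total = float(design.get("total_conc", 400.0))
    fractions = tuple(design.get("wt_fractions", MIXTURE_SERIES_FRACTIONS))
    replicates = int(design.get("replicates", 1))
    model = _amplitude_model(design)
    assay = AssayDefinition("SNPdup", gene="SNP-linked", ch1_allele="WT", ch2_allele="MUT")
    rows, specs = [], []
    seeds = iter(_spawn_seeds(seed, len(fractions) * replicates))
    for i, f in enumerate(fractions):
        label = ROMAN[i] if i < len(ROMAN) else f"S{i + 1}"
        for r in range(1, replicates + 1):
            rows.append(
                dict(sample_id=label, assay_id=assay.assay_id, material="plasmid",
                     group="mixture_series", replicate=r)
            )
            specs.append(
                SimulationSpec(conc_wt=total * f, conc_mut=total * (1.0 - f),
                               n_droplets=n, droplet_volume=vol,
                               amplitude_model=model, seed=next(seeds))
            )
    return _assemble(rows, specs, {assay.assay_id: assay})


def _build_het_gdna(design):
    n, vol, seed = _common(design)
    conc = float(design.get("conc", 100.0))
    replicates = int(design.get("replicates", 3))
    model = _amplitude_model(design)
    assay = AssayDefinition("SNPdup", gene="SNP-linked", ch1_allele="WT", ch2_allele="MUT")
    rows, specs = [], []
    for r, s in zip(range(1, replicates + 1), _spawn_seeds(seed, replicates)):
        rows.append(dict(sample_id="het_gdna", assay_id=assay.assay_id, material="gDNA",
                         group="het_gdna", replicate=r))
        specs.append(SimulationSpec(conc_wt=conc, conc_mut=conc, n_droplets=n,
                                    droplet_volume=vol, amplitude_model=model, seed=s))
    return _assemble(rows, specs, {assay.assay_id: assay})


def _build_paired_cdna_gdna(design):
    n, vol, seed = _common(design)
    cdna_total = float(design.get("cdna_total_conc", 540.0))
    gdna_total = float(design.get("gdna_total_conc", 20.0))
    wt_fraction = float(design.get("wt_fraction", 0.5))
    replicates = int(design.get("replicates", 3))
    # Rain-free by default: uniform rain crossing the threshold adds a
    # constant false-positive rate that swamps low-template gDNA wells.
    model = _amplitude_model(design, rain_fraction=0.0)
    assay = AssayDefinition("SNPdup", gene="SNP-linked", ch1_allele="WT", ch2_allele="MUT")
    rows, specs = [], []
    seeds = iter(_spawn_seeds(seed, 2 * replicates))
    for material, total in (("cDNA", cdna_total), ("gDNA", gdna_total)):
        for r in range(1, replicates + 1):
            rows.append(dict(sample_id=f"paired_{material}", assay_id=assay.assay_id,
                             material=material, group="paired", replicate=r))
            specs.append(SimulationSpec(conc_wt=total * wt_fraction,
                                        conc_mut=total * (1.0 - wt_fraction),
                                        n_droplets=n, droplet_volume=vol,
                                        amplitude_model=model, seed=next(seeds)))
    return _assemble(rows, specs, {assay.assay_id: assay})


def _build_knockdown(design):
    n, vol, seed = _common(design)
    control = tuple(design.get("control_conc", (200.0, 110.0)))
    treated = tuple(design.get("treated_conc", (100.0, 55.0)))
    ref_conc = float(design.get("reference_conc", 200.0))
    replicates = int(design.get("replicates", 3))
    model = _amplitude_model(design)
    target = AssayDefinition("SNPdup", gene="target", ch1_allele="WT", ch2_allele="MUT")
    ref = AssayDefinition("REF", gene="reference", ch1_allele="reference", ch2_allele=None)
    rows, specs = [], []
    seeds = iter(_spawn_seeds(seed, 4 * replicates))
    for group, (cwt, cmut) in (("control", control), ("treated", treated)):
        for r in range(1, replicates + 1):
            rows.append(dict(sample_id=f"{group}", assay_id=target.assay_id,
                             material="cDNA", group=group, replicate=r))
            specs.append(SimulationSpec(conc_wt=cwt, conc_mut=cmut, n_droplets=n,
                                        droplet_volume=vol, amplitude_model=model,
                                        seed=next(seeds)))
        for r in range(1, replicates + 1):
            rows.append(dict(sample_id=f"{group}", assay_id=ref.assay_id,
                             material="cDNA", group=group, replicate=r))
            specs.append(SimulationSpec(conc_wt=ref_conc, conc_mut=0.0, n_droplets=n,
                                        droplet_volume=vol, amplitude_model=model,
                                        seed=next(seeds)))
    return _assemble(rows, specs, {target.assay_id: target, ref.assay_id: ref})


def _build_cnv(design):
    n, vol, seed = _common(design)
    target_conc = float(design.get("target_conc", 340.0))
    ref_conc = float(design.get("reference_conc", 40.0))
    replicates = int(design.get("replicates", 3))
    model = _amplitude_model(design)
    # The copy-number assay uses a SNP homozygous on the transgene: one
    # channel, total template only, no allele discrimination.
    target = AssayDefinition("CNVTARGET", gene="target", ch1_allele="total", ch2_allele=None)
    ref = AssayDefinition("RPP30", gene="reference", ch1_allele="reference", ch2_allele=None)
    rows, specs = [], []
    seeds = iter(_spawn_seeds(seed, 2 * replicates))
    for assay, conc in ((target, target_conc), (ref, ref_conc)):
        for r in range(1, replicates + 1):
            rows.append(dict(sample_id="cnv_sample", assay_id=assay.assay_id,
                             material="gDNA", group="cnv", replicate=r))
            specs.append(SimulationSpec(conc_wt=conc, conc_mut=0.0, n_droplets=n,
                                        droplet_volume=vol, amplitude_model=model,
                                        seed=next(seeds)))
    return _assemble(rows, specs, {target.assay_id: target, ref.assay_id: ref})


# ---------------------------------------------------------------------------
# RNA-seq style SNP allele counts


def simulate_snp_counts(
    true_fraction: float,
    depth_per_snp: int,
    n_snps: int,
    seed: int,
    sample_id: str = "sample1",
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate per-SNP allele read counts: WT ~ Binomial(depth, true_fraction).

    Emulates the read pile-ups at assay SNPs used to cross-check ddPCR
    allelic fractions against RNA-seq.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise DataError("true_fraction must be in [0, 1]")
    if depth_per_snp <= 0 or n_snps <= 0:
        raise DataError("depth_per_snp and n_snps must be positive")
    rng = np.random.default_rng(seed)
    if snp_ids is None:
        snp_ids = [f"SNP{i + 1}" for i in range(n_snps)]
    if len(snp_ids) != n_snps:
        raise DataError("snp_ids length must equal n_snps")
    wt = rng.binomial(depth_per_snp, true_fraction, size=n_snps)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "sample_id": sample_id,
            "wt_count": wt.astype(int),
            "mut_count": (depth_per_snp - wt).astype(int),
        }
    )
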