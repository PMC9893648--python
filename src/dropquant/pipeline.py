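"""End-to-end runs: configuration handling and the orchestration behind the CLI.

Every ``run_*`` function is a plain library call — the CLI only parses
arguments and maps exceptions to exit codes — so command-line results are
identical to direct library composition on the same inputs.  Each run writes
its result tables plus a ``resolved_config.yaml`` next to them for
provenance.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import cnv, copies_per_diploid_genome, knockdown, partition_cn
from .allelic import allelic_fraction, summarize_replicates
from .ase_counts import aggregate_fraction, per_snp_fraction
from .droplet_io import (
    read_amplitude_csv,
    read_plate_config,
    read_snp_counts,
    write_amplitude_csv,
    write_plate_config,
    write_results,
)
from .droplet_sim import simulate_experiment
from .errors import ConfigError, SaturatedWellError
from .quantify import (
    DEFAULT_DROPLET_VOLUME_UL,
    DEFAULT_MIN_DROPLETS,
    TargetMeasurement,
    measure_well,
    merge_wells,
    total_measurement,
)

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return dict(doc)


def _require(cfg: Mapping[str, Any], keys: list[str], context: str) -> None:
    """Validate a config section, reporting every problem at once."""
    problems = [f"{context}: missing required key '{k}'" for k in keys if k not in cfg]
    for k in ("droplet_volume", "diploid_factor", "scaling"):
        if k in cfg and not (isinstance(cfg[k], (int, float)) and cfg[k] > 0):
            problems.append(f"{context}: '{k}' must be a positive number")
    if "min_droplets" in cfg and not (isinstance(cfg["min_droplets"], int) and cfg["min_droplets"] >= 0):
        problems.append(f"{context}: 'min_droplets' must be a non-negative integer")
    if problems:
        raise ConfigError(problems)


def _write_resolved(cfg: Mapping[str, Any], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    text = yaml.safe_dump(dict(cfg), sort_keys=True)
    (outdir / "resolved_config.yaml").write_text(text)
    digest = hashlib.sha256(text.encode()).hexdigest()[:12]
    logger.info("dropquant %s; config sha256 %s", __version__, digest)


def _thresholds(cfg: Mapping[str, Any]):
    t = cfg.get("thresholds", "auto")
    if t == "auto":
        return "auto"
    if isinstance(t, Mapping):
        missing = [k for k in ("ch1", "ch2") if k not in t]
        if missing:
            raise ConfigError([f"thresholds: missing {k}" for k in missing])
        return (t["ch1"], t["ch2"])
    raise ConfigError("thresholds must be 'auto' or a {ch1, ch2} mapping")


# ---------------------------------------------------------------------------


def run_simulate(cfg: Mapping[str, Any], outdir: str | Path, seed: int | None = None) -> Path:
    """Simulate an experiment design into amplitude CSVs + plate metadata."""
    _require(cfg, ["design"], "simulate")
    design = dict(cfg["design"])
    if seed is not None:
        design["seed"] = int(seed)
    outdir = Path(outdir)
    wells, plate, assays = simulate_experiment(design)
    welldir = outdir / "wells"
    welldir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for w in wells:
        write_amplitude_csv(w, welldir / f"{w.well_id}.csv")
        t = w.truth
        truth_rows.append(
            {
                "well_id": w.well_id,
                "sample_id": w.sample_id,
                "conc_wt": t.spec.conc_wt,
                "conc_mut": t.spec.conc_mut,
                "lambda_wt": t.lambda_wt,
                "lambda_mut": t.lambda_mut,
                "n_rain": int(t.rain.sum()),
                "flags": ";".join(w.flags),
            }
        )
        if w.flags:
            logger.warning("well %s flagged: %s", w.well_id, ",".join(w.flags))
    write_plate_config(plate, assays, outdir / "plate.yaml")
    write_results(pd.DataFrame(truth_rows), outdir / "truth.tsv")
    _write_resolved({**cfg, "design": design}, outdir)
    logger.info("simulated %d wells into %s", len(wells), outdir)
    return outdir


def run_quantify(cfg: Mapping[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Classify every plate well and write per-target measurements."""
    _require(cfg, ["plate", "amplitude_dir"], "quantify")
    outdir = Path(outdir)
    plate, assays = read_plate_config(cfg["plate"])
    ampdir = Path(cfg["amplitude_dir"])
    volume = float(cfg.get("droplet_volume", DEFAULT_DROPLET_VOLUME_UL))
    min_droplets = int(cfg.get("min_droplets", DEFAULT_MIN_DROPLETS))
    thresholds = _thresholds(cfg)
    exact_ci = bool(cfg.get("exact_ci", False))

    rows = []
    for meta in plate.rows.itertuples(index=False):
        fname = getattr(meta, "amplitude_file", None) or f"{meta.well_id}.csv"
        well = read_amplitude_csv(
            ampdir / fname, well_id=meta.well_id,
            sample_id=meta.sample_id, assay_id=meta.assay_id,
        )
        assay = assays.get(meta.assay_id)
        if assay is None:
            raise ConfigError(f"well {meta.well_id}: assay {meta.assay_id!r} not defined")
        ch_targets = [(0, assay.ch1_allele)]
        if assay.ch2_allele is not None:
            ch_targets.append((1, assay.ch2_allele))
        try:
            cw, measurements = measure_well(
                well,
                ch1_target=assay.ch1_allele,
                ch2_target=assay.ch2_allele,
                thresholds=thresholds,
                droplet_volume=volume,
                min_droplets=min_droplets,
                exact_ci=exact_ci,
            )
        except SaturatedWellError as exc:
            logger.warning("well %s: %s", meta.well_id, exc)
            rows.append({**meta._asdict(), "target": "total", "k_pos": np.nan,
                         "n_total": well.accepted_count, "lambda": np.nan,
                         "lambda_se": np.nan, "concentration": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "droplet_volume": volume, "qc_flags": "saturated"})
            continue
        flags = []
        if cw.low_droplet_flag:
            flags.append("low_droplets")
            logger.warning("well %s: only %d accepted droplets", meta.well_id, cw.n_total)
        for target, m in measurements.items():
            rows.append(
                {
                    **meta._asdict(),
                    "target": target,
                    "k_pos": m.k_pos,
                    "n_total": m.n_total,
                    "lambda": m.lambda_hat,
                    "lambda_se": m.lambda_se,
                    "concentration": m.concentration,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "droplet_volume": volume,
                    "qc_flags": ";".join(flags),
                }
            )
    df = pd.DataFrame(rows)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(df, outdir / "measurements.tsv")
    _write_resolved(cfg, outdir)
    return df


def load_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _row_measurement(row: pd.Series, target: str) -> TargetMeasurement:
    return TargetMeasurement(
        target=target,
        lambda_hat=row["lambda"],
        lambda_se=row["lambda_se"],
        concentration=row["concentration"],
        ci_low=row["ci_low"],
        ci_high=row["ci_high"],
        n_total=int(row["n_total"]),
        k_pos=int(row["k_pos"]),
        droplet_volume=row["droplet_volume"],
    )


def merged_target(df: pd.DataFrame, target: str, **selector: Any) -> TargetMeasurement:
    """Pool all measurement rows matching ``selector`` for one target."""
    sub = df[df["target"] == target]
    for key, value in selector.items():
        sub = sub[sub[key] == value]
    if sub.empty:
        raise ConfigError(f"no measurement rows for target={target!r}, {selector}")
    return merge_wells(_row_measurement(r, target) for _, r in sub.iterrows())


def run_allelic(cfg: Mapping[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Per-well allelic fractions plus per-group replicate summaries."""
    _require(cfg, ["measurements"], "allelic")
    outdir = Path(outdir)
    df = load_measurements(cfg["measurements"])
    results, rows = [], []
    groups: dict[str, str] = {}
    duplex = df[df["target"].isin(["WT", "MUT"])]
    for (sample, assay, well_id), sub in duplex.groupby(["sample_id", "assay_id", "well_id"]):
        by_target = {r["target"]: r for _, r in sub.iterrows()}
        if "WT" not in by_target or "MUT" not in by_target:
            continue
        res = allelic_fraction(
            _row_measurement(by_target["WT"], "WT"),
            _row_measurement(by_target["MUT"], "MUT"),
            sample_id=sample,
            assay_id=assay,
        )
        groups[sample] = str(sub["group"].iloc[0])
        results.append(res)
        rows.append(
            {
                "sample_id": sample, "assay_id": assay, "well_id": well_id,
                "f_wt_pct": round(100 * res.f_wt, 1),
                "f_mut_pct": round(100 * res.f_mut, 1),
                "se_pct": round(100 * res.se_f, 3),
                "ci_low_pct": round(100 * res.ci_low, 1),
                "ci_high_pct": round(100 * res.ci_high, 1),
                "n_droplets": res.n_droplets,
            }
        )
    if not results:
        raise ConfigError("allelic: no wells with both WT and MUT measurements")
    table = pd.DataFrame(rows)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(table, outdir / "allelic.tsv")
    summary_rows = []
    for s in summarize_replicates(results, groups):
        for assay, mean in s.per_assay_mean.items():
            summary_rows.append({"group": s.group, "assay_id": assay,
                                 "mean_f_wt_pct": round(100 * mean, 1),
                                 "sd_pct": round(100 * s.per_assay_sd[assay], 2),
                                 "n": s.per_assay_n[assay]})
        summary_rows.append({"group": s.group, "assay_id": "pooled",
                             "mean_f_wt_pct": round(100 * s.pooled_mean_f_wt, 1),
                             "sd_pct": round(100 * s.pooled_sd, 2),
                             "n": s.n_replicates})
    write_results(pd.DataFrame(summary_rows), outdir / "allelic_summary.tsv")
    _write_resolved(cfg, outdir)
    return table


def run_pergenome(cfg: Mapping[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Transcripts per diploid genome from paired cDNA/gDNA measurements."""
    _require(cfg, ["measurements", "cdna_sample", "gdna_sample"], "pergenome")
    outdir = Path(outdir)
    df = load_measurements(cfg["measurements"])
    factor = float(cfg.get("diploid_factor", 2.0))
    scaling = float(cfg.get("scaling", 1.0))

    def total_for(sample: str) -> TargetMeasurement:
        wt = merged_target(df, "WT", sample_id=sample)
        mut = merged_target(df, "MUT", sample_id=sample)
        return total_measurement(wt, mut)

    res = copies_per_diploid_genome(
        total_for(cfg["cdna_sample"]), total_for(cfg["gdna_sample"]),
        diploid_factor=factor, scaling=scaling,
    )
    table = pd.DataFrame(
        [{
            "cdna_sample": cfg["cdna_sample"], "gdna_sample": cfg["gdna_sample"],
            "cdna_conc": res.cdna_conc, "gdna_conc": res.gdna_conc,
            "diploid_factor": res.diploid_factor, "scaling": res.scaling,
            "transcripts_per_diploid_genome": res.transcripts_per_diploid_genome,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
        }]
    )
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(table, outdir / "pergenome.tsv")
    _write_resolved(cfg, outdir)
    return table


def run_cnv(cfg: Mapping[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Copy number vs a reference gene, optionally allele-partitioned."""
    _require(cfg, ["measurements", "target_assay", "reference_assay"], "cnv")
    outdir = Path(outdir)
    df = load_measurements(cfg["measurements"])
    target = merged_target(df, "total", assay_id=cfg["target_assay"])
    reference = merged_target(df, "reference", assay_id=cfg["reference_assay"])
    result = cnv(target, reference, reference_copies=int(cfg.get("reference_copies", 2)))
    row = {
        "target_assay": cfg["target_assay"], "reference_assay": cfg["reference_assay"],
        "reference_copies": result.reference_copies,
        "cn_total": result.cn_total, "cn_total_int": result.cn_total_int,
        "ci_low": result.ci_low, "ci_high": result.ci_high,
    }
    if "wt_fraction" in cfg:
        part = partition_cn(result, float(cfg["wt_fraction"]))
        row.update(cn_wt=part.cn_wt, cn_mut=part.cn_mut,
                   cn_wt_int=part.cn_wt_int, cn_mut_int=part.cn_mut_int)
    table = pd.DataFrame([row])
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(table, outdir / "cnv.tsv")
    _write_resolved(cfg, outdir)
    return table


def run_knockdown(cfg: Mapping[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Silencing efficiency: treated vs control, reference-normalized."""
    _require(
        cfg,
        ["measurements", "control_group", "treated_group", "target_assay", "reference_assay"],
        "knockdown",
    )
    outdir = Path(outdir)
    df = load_measurements(cfg["measurements"])
    ctrl, trt = cfg["control_group"], cfg["treated_group"]
    res = knockdown(
        control_wt=merged_target(df, "WT", group=ctrl, assay_id=cfg["target_assay"]),
        control_mut=merged_target(df, "MUT", group=ctrl, assay_id=cfg["target_assay"]),
        treated_wt=merged_target(df, "WT", group=trt, assay_id=cfg["target_assay"]),
        treated_mut=merged_target(df, "MUT", group=trt, assay_id=cfg["target_assay"]),
        control_reference=merged_target(df, "reference", group=ctrl, assay_id=cfg["reference_assay"]),
        treated_reference=merged_target(df, "reference", group=trt, assay_id=cfg["reference_assay"]),
    )
    table = pd.DataFrame(
        [{
            "control_group": ctrl, "treated_group": trt,
            "relative_total": res.relative_total,
            "relative_wt": res.relative_wt, "relative_mut": res.relative_mut,
            "knockdown_total_pct": res.knockdown_total_pct,
            "knockdown_wt_pct": res.knockdown_wt_pct,
            "knockdown_mut_pct": res.knockdown_mut_pct,
        }]
    )
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(table, outdir / "knockdown.tsv")
    _write_resolved(cfg, outdir)
    return table


def run_ase(cfg: Mapping[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Allele-specific expression from an RNA-seq SNP count table."""
    _require(cfg, ["counts"], "ase")
    outdir = Path(outdir)
    counts = read_snp_counts(cfg["counts"])
    method = cfg.get("method", "mean_of_snps")
    per_snp = per_snp_fraction(counts)
    agg = aggregate_fraction(counts, method=method)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(per_snp, outdir / "ase_per_snp.tsv")
    write_results(agg, outdir / "ase_aggregate.tsv")
    _write_resolved(cfg, outdir)
    return agg
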