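"""Readers and writers for droplet amplitude files, plate metadata and result tables.

The instrument-export dialect accepted here is deliberately permissive: a CSV
with a header row naming "Ch1 Amplitude" and "Ch2 Amplitude" (case-insensitive,
surrounding whitespace ignored); extra columns are ignored with a logged
warning.  One file holds one well.  All readers reject malformed input with an
error naming the offending line rather than coercing silently.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError

logger = logging.getLogger(__name__)

#: Channel/allele roles an assay channel may report.
ALLELE_ROLES = ("WT", "MUT", "total", "reference")
MATERIALS = ("cDNA", "gDNA", "plasmid")

AMPLITUDE_COLUMNS = ("ch1 amplitude", "ch2 amplitude")

RESULT_FLOAT_FORMAT = "%.6g"


@dataclass
class DropletWell:
    """Raw two-channel fluorescence amplitudes for one well.

    ``amplitudes`` is an (n, 2) float array; column 0 is channel 1 (typically
    the FAM/WT probe), column 1 is channel 2 (HEX/MUT probe).  ``truth`` is
    populated by the simulator only and carries per-droplet occupancy labels
    for oracle tests; it is never read from instrument files.
    """

    well_id: str
    sample_id: str
    assay_id: str
    amplitudes: np.ndarray
    flags: tuple[str, ...] = ()
    truth: Any = None

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        if amp.ndim != 2 or amp.shape[1] != 2:
            raise DataError(f"well {self.well_id}: amplitudes must be an (n, 2) array")
        if not np.isfinite(amp).all():
            raise DataError(f"well {self.well_id}: non-finite amplitude values")
        self.amplitudes = amp

    @property
    def accepted_count(self) -> int:
        return int(self.amplitudes.shape[0])


@dataclass(frozen=True)
class AssayDefinition:
    """A duplex (or single-channel) ddPCR assay and its channel→allele mapping.

    rsIDs are opaque labels for provenance; no variant-database lookup happens.
    """

    assay_id: str
    gene: str = ""
    rsid: str = ""
    ch1_allele: str = "WT"
    ch2_allele: str | None = "MUT"

    def __post_init__(self) -> None:
        if self.ch1_allele not in ALLELE_ROLES:
            raise DataError(f"assay {self.assay_id}: ch1_allele must be one of {ALLELE_ROLES}")
        if self.ch2_allele is not None:
            if self.ch2_allele not in ALLELE_ROLES:
                raise DataError(f"assay {self.assay_id}: ch2_allele must be one of {ALLELE_ROLES}")
            if self.ch2_allele == self.ch1_allele:
                raise DataError(
                    f"assay {self.assay_id}: duplex channels must report different targets"
                )


@dataclass
class PlateMetadata:
    """Per-well sample annotations for one plate.

    ``rows`` has columns well_id, sample_id, assay_id, material, group,
    replicate and optionally amplitude_file.  Well ids must be unique.
    """

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("well_id", "sample_id", "assay_id", "material", "group", "replicate")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DataError(f"plate metadata missing columns: {missing}")
        if df["well_id"].duplicated().any():
            dups = sorted(df.loc[df["well_id"].duplicated(), "well_id"])
            raise DataError(f"duplicate well_ids in plate metadata: {dups}")
        bad = set(df["material"]) - set(MATERIALS)
        if bad:
            raise DataError(f"unknown material values {sorted(bad)}; expected one of {MATERIALS}")
        self.rows = df.reset_index(drop=True)

    def well(self, well_id: str) -> pd.Series:
        hit = self.rows[self.rows["well_id"] == well_id]
        if hit.empty:
            raise DataError(f"well {well_id} not present in plate metadata")
        return hit.iloc[0]


def read_amplitude_csv(
    path: str | Path,
    well_id: str | None = None,
    sample_id: str = "",
    assay_id: str = "",
) -> DropletWell:
    """Read one well's droplet amplitudes from an instrument-style CSV.

    The header must contain "Ch1 Amplitude" and "Ch2 Amplitude"
    (case-insensitive).  Malformed cells are reported with their 1-based file
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"amplitude file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty amplitude file") from None
        names = [h.strip().lower() for h in header]
        try:
            idx = [names.index(c) for c in AMPLITUDE_COLUMNS]
        except ValueError:
            raise DataError(
                f"{path}: header must contain columns 'Ch1 Amplitude' and "
                f"'Ch2 Amplitude' (case-insensitive); got {header}"
            ) from None
        extra = [header[i] for i in range(len(names)) if i not in idx]
        if extra:
            logger.warning("%s: ignoring extra columns %s", path, extra)
        values: list[tuple[float, float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue  # blank trailing lines are tolerated
            try:
                values.append((float(row[idx[0]]), float(row[idx[1]])))
            except (ValueError, IndexError):
                raise DataError(f"{path}: malformed amplitude row at line {lineno}: {row}") from None
    if not values:
        raise DataError(f"{path}: no droplet rows")
    return DropletWell(
        well_id=well_id if well_id is not None else path.stem,
        sample_id=sample_id,
        assay_id=assay_id,
        amplitudes=np.array(values, dtype=float),
    )


def write_amplitude_csv(well: DropletWell, path: str | Path) -> None:
    """Write a well in the same dialect ``read_amplitude_csv`` accepts.

    Floats are written with ``repr`` (shortest round-tripping form) so a
    write-then-read cycle is bit-exact.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Ch1 Amplitude", "Ch2 Amplitude"])
        for a, b in well.amplitudes:
            writer.writerow([repr(float(a)), repr(float(b))])


def read_plate_config(path: str | Path) -> tuple[PlateMetadata, dict[str, AssayDefinition]]:
    """Read a plate-layout YAML: well metadata plus assay definitions."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"plate config not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "wells" not in doc:
        raise DataError(f"{path}: expected a mapping with a 'wells' list")
    plate = PlateMetadata(pd.DataFrame(list(doc["wells"])))
    assays: dict[str, AssayDefinition] = {}
    for assay_id, spec in (doc.get("assays") or {}).items():
        assays[assay_id] = AssayDefinition(assay_id=assay_id, **(spec or {}))
    return plate, assays


def write_plate_config(
    plate: PlateMetadata, assays: Mapping[str, AssayDefinition], path: str | Path
) -> None:
    doc = {
        "wells": plate.rows.to_dict(orient="records"),
        "assays": {
            a.assay_id: {
                "gene": a.gene,
                "rsid": a.rsid,
                "ch1_allele": a.ch1_allele,
                "ch2_allele": a.ch2_allele,
            }
            for a in assays.values()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


SNP_COUNT_COLUMNS = ("snp_id", "sample_id", "wt_count", "mut_count")


def read_snp_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-SNP allele read-count TSV (snp_id, sample_id, wt_count, mut_count)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"SNP count file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SNP_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return validate_snp_counts(df[list(SNP_COUNT_COLUMNS)])


def validate_snp_counts(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("wt_count", "mut_count"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            raise DataError(f"SNP counts: non-numeric values in {col}")
        if (df[col] < 0).any():
            raise DataError(f"SNP counts: negative values in {col}")
    dup = df.duplicated(subset=["snp_id", "sample_id"])
    if dup.any():
        pairs = df.loc[dup, ["snp_id", "sample_id"]].itertuples(index=False, name=None)
        raise DataError(f"SNP counts: duplicated (snp_id, sample_id) rows: {sorted(set(pairs))}")
    return df.reset_index(drop=True)


def write_snp_counts(df: pd.DataFrame, path: str | Path) -> None:
    validate_snp_counts(df).to_csv(path, sep="\t", index=False)


def write_results(
    results: pd.DataFrame | Iterable[Mapping[str, Any]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a result table as a deterministic TSV.

    Rows are sorted on (sample_id, assay_id, target) — whichever of those
    columns exist — then on all remaining columns, and floats are rendered at
    6 significant digits, so identical inputs give byte-identical files.
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results), columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    if len(df):
        keys = [c for c in ("sample_id", "assay_id", "target") if c in df.columns]
        keys += [c for c in df.columns if c not in keys and df[c].dtype == object]
        if keys:
            df = df.sort_values(keys, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=RESULT_FLOAT_FORMAT)
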