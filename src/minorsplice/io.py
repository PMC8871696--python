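"""Readers, writers and sample bookkeeping for the pipeline's external formats.

Formats handled here:

* **Intron annotation** — BED6+2 (``chrom start end name score strand
  gene_id minor|major``), 0-based half-open coordinates. Any 1-based
  inclusive source must be converted before it reaches this module; a
  single internal convention prevents off-by-one joins.
* **Coverage containers** — per-(event, sample) intron alignment counts and
  spanning-junction counts, either as a long TSV (portable interchange) or
  as an HDF5 events x samples layout mirroring splice-graph tool output.
* **Sample sheets** — TSV mapping samples to patient, tissue and cohort,
  either with explicit columns or with TCGA-style barcodes to parse.
* **Gene counts** — TSV of raw counts, genes x samples, plus a gene-set
  membership table (gene_id, set label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IntronRecord",
    "BarcodeError",
    "read_intron_annotation",
    "write_intron_annotation",
    "read_coverage_container",
    "write_coverage_tsv",
    "write_coverage_hdf5",
    "parse_sample_barcode",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_counts",
    "read_gene_sets",
    "match_events_to_minor_introns",
    "select_matched_pairs",
]

COVERAGE_COLUMNS = ["intron_id", "sample_id", "intron_alignment_count", "junction_count"]
EVENT_COLUMNS = ["event_id", "chrom", "start", "end", "strand"]
ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "intron_id", "score", "strand", "gene_id", "label",
]


@dataclass(frozen=True)
class IntronRecord:
    """A genomic intron in 0-based half-open coordinates."""

    intron_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    is_minor: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"intron {self.intron_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"intron {self.intron_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"intron {self.intron_id}: bad strand {self.strand!r}")


class BarcodeError(ValueError):
    """Raised for a sample barcode that cannot be interpreted."""


def read_intron_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED6+2 intron annotation into a validated DataFrame.

    Columns of the result: ``intron_id, chrom, start, end, strand, length,
    gene_id, is_minor``. ``length`` is computed from the coordinates, never
    read from the file. Malformed coordinates raise with the offending
    line number; an empty file yields an empty frame with a warning.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None, names=ANNOTATION_COLUMNS,
                          dtype={"chrom": str, "intron_id": str, "gene_id": str,
                                 "label": str, "strand": str}, comment="#")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=ANNOTATION_COLUMNS)
    if raw.empty:
        logger.warning("annotation %s is empty", path)
        return pd.DataFrame(
            columns=["intron_id", "chrom", "start", "end", "strand", "length",
                     "gene_id", "is_minor"])
    records = []
    for lineno, row in enumerate(raw.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
        if end <= start or start < 0:
            raise ValueError(
                f"{path} line {lineno}: invalid interval [{start}, {end}) "
                f"for intron {row.intron_id}")
        label = str(row.label).lower()
        if label not in {"minor", "major"}:
            raise ValueError(
                f"{path} line {lineno}: intron class must be 'minor' or 'major', "
                f"got {row.label!r}")
        records.append((str(row.intron_id), str(row.chrom), start, end,
                        str(row.strand), end - start, str(row.gene_id),
                        label == "minor"))
    out = pd.DataFrame(records, columns=["intron_id", "chrom", "start", "end",
                                         "strand", "length", "gene_id", "is_minor"])
    dup = out["intron_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate intron_id(s): {sorted(out.loc[dup, 'intron_id'])[:5]}")
    bad_strand = ~out["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError(f"{path}: invalid strand values present")
    return out


def write_intron_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation frame back to BED6+2."""
    label = np.where(annotation["is_minor"], "minor", "major")
    bed = pd.DataFrame({
        "chrom": annotation["chrom"], "start": annotation["start"],
        "end": annotation["end"], "intron_id": annotation["intron_id"],
        "score": ".", "strand": annotation["strand"],
        "gene_id": annotation["gene_id"], "label": label,
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def _validate_coverage(coverage: pd.DataFrame, source: str) -> pd.DataFrame:
    coverage = coverage.copy()
    for col in ("intron_alignment_count", "junction_count"):
        vals = pd.to_numeric(coverage[col], errors="raise")
        if (vals < 0).any():
            raise ValueError(f"{source}: negative {col} encountered")
        coverage[col] = vals.astype(np.int64)
    coverage["intron_id"] = coverage["intron_id"].astype(str)
    coverage["sample_id"] = coverage["sample_id"].astype(str)
    return coverage[COVERAGE_COLUMNS]


def read_coverage_container(
    path: str | Path, dialect: str = "tsv_long"
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a coverage container.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"tsv_long"`` — TSV with columns ``intron_id, sample_id,
        intron_alignment_count, junction_count``; returns ``(coverage,
        None)`` (event coordinates, if any, travel in a separate table).
        ``"hdf5_hierarchical"`` — HDF5 with datasets ``samples``,
        ``events/{event_id,chrom,start,end,strand}``, ``intron_counts`` and
        ``junction_counts`` (events x samples); returns ``(coverage,
        events)`` with one coverage row per (event, sample).
    """
    path = Path(path)
    if dialect == "tsv_long":
        cov = pd.read_csv(path, sep="\t")
        missing = set(COVERAGE_COLUMNS) - set(cov.columns)
        if missing:
            raise ValueError(f"{path}: missing coverage columns {sorted(missing)}")
        return _validate_coverage(cov, str(path)), None
    if dialect == "hdf5_hierarchical":
        with h5py.File(path, "r") as h5:
            samples = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in h5["samples"][:]]
            events = pd.DataFrame({
                "event_id": [e.decode() if isinstance(e, bytes) else str(e)
                             for e in h5["events/event_id"][:]],
                "chrom": [c.decode() if isinstance(c, bytes) else str(c)
                          for c in h5["events/chrom"][:]],
                "start": h5["events/start"][:].astype(np.int64),
                "end": h5["events/end"][:].astype(np.int64),
                "strand": [s.decode() if isinstance(s, bytes) else str(s)
                           for s in h5["events/strand"][:]],
            })
            intron_counts = h5["intron_counts"][:]
            junction_counts = h5["junction_counts"][:]
        n_events, n_samples = intron_counts.shape
        if junction_counts.shape != (n_events, n_samples):
            raise ValueError(f"{path}: count matrix shapes disagree")
        if len(samples) != n_samples:
            raise ValueError(
                f"{path}: sample vector length {len(samples)} does not match "
                f"count matrix width {n_samples}")
        if len(events) != n_events:
            raise ValueError(f"{path}: event table length mismatch")
        cov = pd.DataFrame({
            "intron_id": np.repeat(events["event_id"].to_numpy(), n_samples),
            "sample_id": np.tile(np.asarray(samples, dtype=object), n_events),
            "intron_alignment_count": intron_counts.ravel(),
            "junction_count": junction_counts.ravel(),
        })
        return _validate_coverage(cov, str(path)), events
    raise ValueError(f"unknown coverage dialect {dialect!r}")


def write_coverage_tsv(coverage: pd.DataFrame, path: str | Path) -> None:
    _validate_coverage(coverage, "coverage").to_csv(path, sep="\t", index=False)


def write_coverage_hdf5(
    coverage: pd.DataFrame, events: pd.DataFrame, path: str | Path
) -> None:
    """Write coverage to the HDF5 events x samples dialect.

    Missing (event, sample) combinations are stored as zeros, which the
    per-sample read filter later treats as absent observations.
    """
    coverage = _validate_coverage(coverage, "coverage")
    event_ids = events["event_id"].astype(str).tolist()
    samples = sorted(coverage["sample_id"].unique())
    e_index = {e: i for i, e in enumerate(event_ids)}
    s_index = {s: j for j, s in enumerate(samples)}
    unknown = set(coverage["intron_id"]) - set(e_index)
    if unknown:
        raise ValueError(f"coverage refers to events absent from the event table: "
                         f"{sorted(unknown)[:5]}")
    shape = (len(event_ids), len(samples))
    intron_counts = np.zeros(shape, dtype=np.int64)
    junction_counts = np.zeros(shape, dtype=np.int64)
    rows = coverage["intron_id"].map(e_index).to_numpy()
    cols = coverage["sample_id"].map(s_index).to_numpy()
    intron_counts[rows, cols] = coverage["intron_alignment_count"].to_numpy()
    junction_counts[rows, cols] = coverage["junction_count"].to_numpy()
    with h5py.File(path, "w") as h5:
        str_dt = h5py.string_dtype()
        h5.create_dataset("samples", data=np.asarray(samples, dtype=object), dtype=str_dt)
        grp = h5.create_group("events")
        grp.create_dataset("event_id", data=np.asarray(event_ids, dtype=object), dtype=str_dt)
        grp.create_dataset("chrom", data=events["chrom"].astype(str).to_numpy(dtype=object),
                           dtype=str_dt)
        grp.create_dataset("start", data=events["start"].to_numpy(np.int64))
        grp.create_dataset("end", data=events["end"].to_numpy(np.int64))
        grp.create_dataset("strand", data=events["strand"].astype(str).to_numpy(dtype=object),
                           dtype=str_dt)
        h5.create_dataset("intron_counts", data=intron_counts)
        h5.create_dataset("junction_counts", data=junction_counts)


def parse_sample_barcode(barcode: str) -> tuple[str, str]:
    """Split a TCGA-style sample barcode into (patient_id, tissue).

    The patient is the first 12 characters; the two-digit sample-type code
    at positions 14-15 maps 01-09 to tumor and 10-19 to normal. Anything
    else (control codes, malformed barcodes) raises :class:`BarcodeError`.
    """
    if not isinstance(barcode, str) or len(barcode) < 15:
        raise BarcodeError(f"barcode too short: {barcode!r}")
    if barcode[4] != "-" or barcode[7] != "-" or barcode[12] != "-":
        raise BarcodeError(f"barcode not in TCGA style: {barcode!r}")
    code_txt = barcode[13:15]
    if not code_txt.isdigit():
        raise BarcodeError(f"non-numeric sample-type code in {barcode!r}")
    code = int(code_txt)
    if 1 <= code <= 9:
        tissue = "tumor"
    elif 10 <= code <= 19:
        tissue = "normal"
    else:
        raise BarcodeError(f"sample-type code {code:02d} out of range in {barcode!r}")
    return barcode[:12], tissue


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet into columns sample_id/patient_id/tissue/cohort.

    Accepts either explicit ``patient_id`` and ``tissue`` columns or raw
    barcodes in ``sample_id`` plus a ``cohort`` column, in which case
    patient and tissue are derived with :func:`parse_sample_barcode`.
    Unparseable samples are excluded with a log entry.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns or "cohort" not in sheet.columns:
        raise ValueError(f"{path}: sample sheet needs sample_id and cohort columns")
    if {"patient_id", "tissue"} <= set(sheet.columns):
        bad = ~sheet["tissue"].isin(["tumor", "normal"])
        if bad.any():
            raise ValueError(f"{path}: tissue must be 'tumor' or 'normal'")
        return sheet[["sample_id", "patient_id", "tissue", "cohort"]].copy()
    parsed, dropped = [], 0
    for row in sheet.itertuples(index=False):
        try:
            patient, tissue = parse_sample_barcode(row.sample_id)
        except BarcodeError as exc:
            logger.info("excluding sample: %s", exc)
            dropped += 1
            continue
        parsed.append((row.sample_id, patient, tissue, row.cohort))
    if dropped:
        logger.warning("%d sample(s) excluded for unparseable barcodes", dropped)
    return pd.DataFrame(parsed, columns=["sample_id", "patient_id", "tissue", "cohort"])


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[["sample_id", "patient_id", "tissue", "cohort"]].to_csv(
        path, sep="\t", index=False)


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples raw count TSV (first column gene_id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    if counts.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene_ids")
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return counts


def read_gene_sets(path: str | Path) -> pd.DataFrame:
    """Read a gene-set membership TSV with columns gene_id, set."""
    sets = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "set"} <= set(sets.columns):
        raise ValueError(f"{path}: gene-set table needs gene_id and set columns")
    return sets[["gene_id", "set"]].copy()


def match_events_to_minor_introns(
    events: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, str]:
    """Map detected retention events to annotated minor introns.

    An event maps to a minor intron iff chrom, start, end and strand all
    match exactly (both sides in the internal 0-based half-open
    convention). Unmatched events are dropped from the mapping, with the
    count logged; duplicate coordinates in the annotation make the join
    ambiguous and are fatal.
    """
    minor = annotation.loc[annotation["is_minor"]]
    keys = list(zip(minor["chrom"], minor["start"], minor["end"], minor["strand"]))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate minor-intron coordinates in annotation; "
                         "join would be ambiguous")
    lookup = dict(zip(keys, minor["intron_id"]))
    mapping: dict[str, str] = {}
    unmatched = 0
    for row in events.itertuples(index=False):
        key = (row.chrom, int(row.start), int(row.end), row.strand)
        intron = lookup.get(key)
        if intron is None:
            unmatched += 1
        else:
            mapping[str(row.event_id)] = str(intron)
    logger.info("matched %d/%d events to minor introns (%d unmatched)",
                len(mapping), len(events), unmatched)
    return mapping


def select_matched_pairs(
    samples: pd.DataFrame, min_patients: int = 5
) -> pd.DataFrame:
    """Select one matched tumor/normal sample pair per patient per cohort.

    A patient with multiple tumor (or normal) aliquots keeps the
    lexicographically smallest sample_id — a deterministic convention.
    Cohorts with fewer than ``min_patients`` retained pairs are flagged
    ineligible rather than dropped, so callers can report the funnel.

    Returns a frame with columns ``cohort, patient_id, tumor_sample,
    normal_sample, cohort_eligible`` sorted by (cohort, patient_id).
    """
    rows = []
    for (cohort, patient), grp in samples.groupby(["cohort", "patient_id"], sort=True):
        tumors = sorted(grp.loc[grp["tissue"] == "tumor", "sample_id"])
        normals = sorted(grp.loc[grp["tissue"] == "normal", "sample_id"])
        if tumors and normals:
            rows.append((cohort, patient, tumors[0], normals[0]))
    pairs = pd.DataFrame(rows, columns=["cohort", "patient_id", "tumor_sample",
                                        "normal_sample"])
    if pairs.empty:
        pairs["cohort_eligible"] = pd.Series(dtype=bool)
        return pairs
    counts = pairs.groupby("cohort")["patient_id"].transform("size")
    pairs["cohort_eligible"] = counts >= min_patients
    for cohort, n in pairs.groupby("cohort").size().items():
        if n < min_patients:
            logger.info("cohort %s ineligible: %d matched pairs < %d",
                        cohort, n, min_patients)
    return pairs.reset_index(drop=True)
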