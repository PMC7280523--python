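"""Readers and writers for the interchange formats.

Plain-text formats only: FASTA for references (via Biopython), BED (0-based
half-open) for islands/fragments/TSS, TSV for beta matrices (columns: chrom,
pos, then one column per sample), binary call matrices (locus column then
samples, values M/U/NA), sample sheets and lane readings, and a versioned
JSON report. Betas round-trip to 6 decimal places; binary calls bit-exactly.
All validation errors name the offending line or record.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay import CALL_LABELS, LaneReading
from .simulate import INVALID, ReferenceSequence, SampleAnnotation, TssSite

_CALL_CODES = {v: k for k, v in CALL_LABELS.items()}
REPORT_SCHEMA_VERSION = "1.0"


class FormatError(ValueError):
    """A malformed interchange file; the message names the line/record."""


# ---------------------------------------------------------------- matrices

def write_beta_matrix(betas: pd.DataFrame, path: str | Path) -> None:
    out = betas.reset_index()
    out.columns = ["chrom", "pos"] + list(betas.columns)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    rows = []
    index = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 3 or header[:2] != ["chrom", "pos"]:
            raise FormatError(f"{path}: line 1: expected header 'chrom\\tpos\\t<samples>'")
        samples = header[2:]
        if len(set(samples)) != len(samples):
            raise FormatError(f"{path}: line 1: duplicate sample ids")
        for ln, rec in enumerate(reader, start=2):
            if len(rec) != len(header):
                raise FormatError(f"{path}: line {ln}: expected {len(header)} fields, got {len(rec)}")
            try:
                pos = int(rec[1])
            except ValueError:
                raise FormatError(f"{path}: line {ln}: position {rec[1]!r} is not an integer") from None
            vals = []
            for v in rec[2:]:
                if v == "NA":
                    vals.append(np.nan)
                    continue
                try:
                    b = float(v)
                except ValueError:
                    raise FormatError(f"{path}: line {ln}: beta {v!r} is not numeric") from None
                if not 0.0 <= b <= 1.0:
                    raise FormatError(f"{path}: line {ln}: beta {b} outside [0, 1]")
                vals.append(b)
            index.append((rec[0], pos))
            rows.append(vals)
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["chrom", "pos"]),
        columns=samples,
        dtype=float,
    )


def write_call_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.map(lambda c: CALL_LABELS[int(c)])
    out.index.name = "locus"
    out.to_csv(path, sep="\t")


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    rows = []
    loci = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2 or header[0] != "locus":
            raise FormatError(f"{path}: line 1: expected header 'locus\\t<samples>'")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise FormatError(f"{path}: line 1: duplicate sample ids")
        for ln, rec in enumerate(reader, start=2):
            if len(rec) != len(header):
                raise FormatError(f"{path}: line {ln}: expected {len(header)} fields, got {len(rec)}")
            try:
                rows.append([_CALL_CODES[v] for v in rec[1:]])
            except KeyError as e:
                raise FormatError(f"{path}: line {ln}: unknown call {e.args[0]!r} (use M/U/NA)") from None
            loci.append(rec[0])
    return pd.DataFrame(rows, index=pd.Index(loci, name="locus"), columns=samples, dtype="int8")


# ------------------------------------------------------------ sample sheet

_SHEET_COLUMNS = ["sample_id", "response", "age", "tumor_size", "node_status", "regimen"]


def write_sample_sheet(ann: list[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            [a.sample_id, a.response, a.age if a.age is not None else "NA",
             a.tumor_size or "NA", a.node_status or "NA", a.regimen or "NA"]
            for a in ann
        ],
        columns=_SHEET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or reader.fieldnames[:2] != ["sample_id", "response"]:
            raise FormatError(f"{path}: line 1: expected columns starting 'sample_id\\tresponse'")
        for ln, rec in enumerate(reader, start=2):
            if rec["response"] not in ("PR", "SD"):
                raise FormatError(f"{path}: line {ln}: response must be PR or SD")
            out.append(
                SampleAnnotation(
                    sample_id=rec["sample_id"],
                    response=rec["response"],
                    age=None if rec.get("age") in (None, "NA", "") else int(rec["age"]),
                    tumor_size=None if rec.get("tumor_size") in (None, "NA", "") else rec["tumor_size"],
                    node_status=None if rec.get("node_status") in (None, "NA", "") else rec["node_status"],
                    regimen=None if rec.get("regimen") in (None, "NA", "") else rec["regimen"],
                )
            )
    return out


# ------------------------------------------------------------- fasta / bed

def write_fasta(ref: ReferenceSequence, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(ref.seq), id=ref.name, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as (name, uppercased sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: record 1: no FASTA records found")
    return records[0].id, str(records[0].seq).upper()


def write_bed(intervals: list[tuple], path: str | Path) -> None:
    """Intervals are (chrom, start, end) or (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(v) for v in iv) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}: line {ln}: non-integer coordinates") from None
            if end <= start:
                raise FormatError(f"{path}: line {ln}: end {end} <= start {start}")
            out.append((parts[0], start, end, *parts[3:4]))
    return out


def read_reference(fasta: str | Path, islands_bed: str | Path, tss_bed: str | Path) -> ReferenceSequence:
    name, seq = read_fasta(fasta)
    islands = tuple((s, e) for _c, s, e, *_ in read_bed(islands_bed))
    tss = tuple(TssSite(pos=s, gene=rest[0] if rest else f"TSS_{s}")
                for _c, s, _e, *rest in read_bed(tss_bed))
    return ReferenceSequence(name=name, seq=seq, islands=islands, tss=tss)


# ---------------------------------------------------------------- readings

_READINGS_COLUMNS = ["sample", "locus", "digested_band", "mock_band", "dc_digested", "pc_present"]


def write_readings(readings: dict[str, LaneReading], path: str | Path) -> None:
    rows = []
    for sample, r in readings.items():
        for locus in sorted(r.mock_bands):
            rows.append([
                sample, locus,
                int(r.digested_bands[locus]), int(r.mock_bands[locus]),
                int(r.dc_digested), int(r.pc_present),
            ])
    pd.DataFrame(rows, columns=_READINGS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_readings(path: str | Path) -> dict[str, LaneReading]:
    readings: dict[str, LaneReading] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _READINGS_COLUMNS:
            raise FormatError(f"{path}: line 1: expected columns {_READINGS_COLUMNS}")
        for ln, rec in enumerate(reader, start=2):
            try:
                dig, mock = bool(int(rec["digested_band"])), bool(int(rec["mock_band"]))
                dc, pc = bool(int(rec["dc_digested"])), bool(int(rec["pc_present"]))
            except (ValueError, TypeError):
                raise FormatError(f"{path}: line {ln}: band flags must be 0/1") from None
            r = readings.setdefault(
                rec["sample"], LaneReading({}, {}, dc_digested=dc, pc_present=pc)
            )
            if (r.dc_digested, r.pc_present) != (dc, pc):
                raise FormatError(f"{path}: line {ln}: inconsistent control flags for sample {rec['sample']}")
            r.digested_bands[rec["locus"]] = dig
            r.mock_bands[rec["locus"]] = mock
    return readings


# ------------------------------------------------------------------ report

def _load_schema() -> dict:
    with resources.files("methpanel").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (required keys + types)."""
    schema = _load_schema()
    if report.get("schema_version") != schema["schema_version"]:
        raise FormatError(
            f"report schema_version {report.get('schema_version')!r} != {schema['schema_version']!r}"
        )
    types = {"object": dict, "array": list, "number": (int, float), "string": str}
    for key, typ in schema["required"].items():
        if key not in report:
            raise FormatError(f"report missing required key {key!r}")
        if not isinstance(report[key], types[typ]):
            raise FormatError(f"report key {key!r} should be of type {typ}")


def write_report(report: dict, path: str | Path) -> None:
    report = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    validate_report(report)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
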