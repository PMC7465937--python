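"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (via Biopython), BED3/BED6, ENCODE 10-column narrowPeak, two-column
chrom.sizes, and tab-separated report tables with a structured (JSON)
variant carrying provenance.  All genomic coordinates are 0-based half-open
per the BED convention.  Malformed lines are rejected with errors naming
the offending line number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence

from Bio import SeqIO

from . import __version__
from .intervals import Genome, GenomicInterval, PeakSet
from .motifs import AMBIGUITY_AA, STANDARD_AA, ProteinRecord

DIALECTS = ("bed3", "bed6", "narrowPeak")


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> List[ProteinRecord]:
    """Read protein records from a text FASTA file.

    The identifier is the header token up to the first whitespace; the
    sequence is upper-cased and a trailing stop symbol ``*`` is stripped.
    Duplicate identifiers, empty files and residues outside the 20 standard
    codes plus X/B/Z/U are errors.
    """
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        allowed = set(STANDARD_AA) | set(AMBIGUITY_AA)
        for pos, aa in enumerate(seq, start=1):
            if aa not in allowed:
                raise FormatError(
                    f"record {rec.id!r}: invalid residue {aa!r} at position {pos}"
                )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> Genome:
    """Read a two-column (name, length) chromosome-size table."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path} line {lineno}: expected 2 tab-separated columns"
                )
            name, length_s = fields
            try:
                length = int(length_s)
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-integer length {length_s!r}"
                ) from None
            if length <= 0:
                raise FormatError(
                    f"{path} line {lineno}: non-positive length {length}"
                )
            if name in sizes:
                raise FormatError(
                    f"{path} line {lineno}: duplicate chromosome {name!r}"
                )
            sizes[name] = length
    if not sizes:
        raise FormatError(f"{path}: empty chrom.sizes file")
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak

_SKIP_PREFIXES = ("#", "track", "browser")


def _parse_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"{path} line {lineno}: non-integer {what} {value!r}"
        ) from None


def read_peaks(path, dialect: str, genome: Genome) -> PeakSet:
    """Read a peak file in one of the bed3 / bed6 / narrowPeak dialects.

    narrowPeak (10 columns): height is the signalValue (column 7) and the
    summit is start + peak offset (column 10); an offset of -1 imputes the
    summit as the interval midpoint (floor).  bed6: height is the score
    column.  bed3: no height.  Peaks on chromosomes absent from the genome
    are an error, not silently dropped.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    min_cols = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[dialect]
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path} line {lineno}: {dialect} needs >= {min_cols} columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            if start >= end:
                raise FormatError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            height: Optional[float] = None
            summit: Optional[int] = None
            if dialect == "bed6":
                try:
                    height = float(fields[4])
                except ValueError:
                    raise FormatError(
                        f"{path} line {lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            elif dialect == "narrowPeak":
                try:
                    height = float(fields[6])
                except ValueError:
                    raise FormatError(
                        f"{path} line {lineno}: non-numeric signalValue "
                        f"{fields[6]!r}"
                    ) from None
                offset = _parse_int(fields[9], path, lineno, "peak offset")
                summit = (start + end) // 2 if offset == -1 else start + offset
                if not start <= summit < end:
                    raise FormatError(
                        f"{path} line {lineno}: summit {summit} outside interval"
                    )
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, height, summit)
                )
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from None
    return PeakSet(intervals, genome)


def _fmt_height(h: Optional[float]) -> str:
    return format(h, "g") if h is not None else "0"


def write_peaks(peaks: PeakSet, path, dialect: str) -> None:
    """Write a peak set back out; read(write(x)) round-trips field-for-field."""
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t"
                    f"{_fmt_height(iv.height)}\t.\n"
                )
            else:
                offset = (
                    iv.summit - iv.start if iv.summit is not None else -1
                )
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t0\t.\t"
                    f"{_fmt_height(iv.height)}\t-1\t-1\t{offset}\n"
                )


# ---------------------------------------------------------------------------
# report tables


@dataclass
class ReportTable:
    """A small typed table with fixed column order and provenance.

    Serializes identically to tab-separated text (rows only) and to a
    structured JSON variant that additionally carries the provenance block
    (input file names, parameters, seed, tool version).
    """

    columns: List[str]
    rows: List[Dict[str, Any]] = field(default_factory=list)
    provenance: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("a report needs at least one column")
        for row in self.rows:
            if set(row) != set(self.columns):
                raise ValueError(
                    f"row keys {sorted(row)} do not match columns {self.columns}"
                )
        self.provenance.setdefault("tool_version", __version__)

    def add_row(self, **values: Any) -> None:
        if set(values) != set(self.columns):
            raise ValueError(
                f"row keys {sorted(values)} do not match columns {self.columns}"
            )
        self.rows.append(values)


def _coerce(text: str) -> Any:
    if text == "":
        return ""
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_report(table: ReportTable, path, format: str = "tsv") -> None:
    """Write a report as plain TSV or as structured JSON with provenance."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(table.columns) + "\n")
            for row in table.rows:
                fh.write("\t".join(str(row[c]) for c in table.columns) + "\n")
    elif format == "structured":
        payload = {
            "provenance": table.provenance,
            "columns": table.columns,
            "rows": table.rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path, format: str = "tsv") -> ReportTable:
    if format == "structured":
        with open(path) as fh:
            payload = json.load(fh)
        return ReportTable(
            columns=payload["columns"],
            rows=payload["rows"],
            provenance=payload["provenance"],
        )
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"{path}: empty report")
    columns = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        if not line:
            continue
        values = line.split("\t")
        if len(values) != len(columns):
            raise FormatError(f"{path}: ragged report row {line!r}")
        rows.append({c: _coerce(v) for c, v in zip(columns, values)})
    return ReportTable(columns=columns, rows=rows)
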