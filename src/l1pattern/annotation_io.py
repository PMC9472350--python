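"""Annotation I/O: GFF3 emission of pattern matches, interval reading, and
a structural GFF3 validity check.

Internally all coordinates are 0-based half-open.  GFF3 is written and
read as 1-based inclusive; BED as 0-based half-open.  Detected elements
are reported with fixed ``source=L1PD``, ``type=mobile_genetic_element``
and ``attributes=Name=LINE1``; score and phase are left blank (``.``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .evaluation import Interval
from .pattern_chaining import PatternMatch

__all__ = [
    "Gff3Record",
    "GFF3_SOURCE",
    "GFF3_TYPE",
    "GFF3_ATTRIBUTES",
    "write_gff3",
    "read_intervals",
    "validate_gff3",
]

GFF3_SOURCE = "L1PD"
GFF3_TYPE = "mobile_genetic_element"
GFF3_ATTRIBUTES = "Name=LINE1"
_STRANDS = {"+", "-", ".", "?"}


@dataclass(frozen=True)
class Gff3Record:
    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int
    score: str
    strand: str
    phase: str
    attributes: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("GFF3 record with start > end")
        if self.strand not in _STRANDS:
            raise ValueError(f"illegal strand {self.strand!r}")

    def line(self) -> str:
        return "\t".join(
            [self.seqid, self.source, self.type, str(self.start), str(self.end),
             self.score, self.strand, self.phase, self.attributes]
        )


def write_gff3(matches: Sequence[PatternMatch], path: str | Path) -> None:
    """Write detected elements as GFF3, sorted by (seqid, start)."""
    records = [
        Gff3Record(
            seqid=m.chrom,
            source=GFF3_SOURCE,
            type=GFF3_TYPE,
            start=m.element_start + 1,
            end=m.element_end,
            score=".",
            strand=m.strand,
            phase=".",
            attributes=GFF3_ATTRIBUTES,
        )
        for m in matches
    ]
    records.sort(key=lambda r: (r.seqid, r.start, r.end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(rec.line() + "\n")


def read_intervals(
    path: str | Path, format: str = "gff3", feature_type: str | None = None
) -> list[Interval]:
    """Read a GFF3 or BED file into internal 0-based half-open intervals.

    ``feature_type`` optionally restricts GFF3 records by the type column.
    Malformed lines raise ValueError with the offending line number.
    """
    fmt = format.lower()
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unknown format {format!r}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or (fmt == "bed" and line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(fields) != 9:
                        raise ValueError(f"expected 9 columns, got {len(fields)}")
                    start, end = int(fields[3]), int(fields[4])
                    if start < 1 or end < start:
                        raise ValueError("coordinate violation (1-based inclusive)")
                    strand = fields[6]
                    if strand not in _STRANDS:
                        raise ValueError(f"illegal strand {strand!r}")
                    if feature_type is not None and fields[2] != feature_type:
                        continue
                    out.append(Interval(fields[0], start - 1, end, strand))
                else:
                    if len(fields) < 3:
                        raise ValueError(f"expected >= 3 columns, got {len(fields)}")
                    start, end = int(fields[1]), int(fields[2])
                    if start < 0 or end < start:
                        raise ValueError("coordinate violation (0-based half-open)")
                    strand = fields[5] if len(fields) >= 6 else "."
                    if strand not in _STRANDS:
                        raise ValueError(f"illegal strand {strand!r}")
                    out.append(Interval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return out


def validate_gff3(path: str | Path) -> int:
    """Structural GFF3 validity check: version pragma, nine tab-delimited
    columns, numeric 1-based coordinates with start <= end, legal strand.
    Returns the number of feature records; raises ValueError otherwise."""
    n = 0
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("##gff-version 3"):
            raise ValueError("missing ##gff-version 3 pragma")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric coordinates") from None
            if start < 1 or start > end:
                raise ValueError(f"line {lineno}: start/end violation")
            if fields[6] not in _STRANDS:
                raise ValueError(f"line {lineno}: illegal strand {fields[6]!r}")
            n += 1
    return n
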