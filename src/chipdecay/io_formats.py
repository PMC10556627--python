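"""Readers and writers for the interval, coverage and table formats the pipeline touches.

Coordinate conventions are fixed package-wide: every internal coordinate is
0-based, half-open (BED convention). GFF input is converted on read and never
re-converted internally. Chromosome names are matched by exact string equality;
no ``chr`` aliasing is ever applied, because silent aliasing corrupts
hybrid-genome setups where names distinguish experimental and spike-in species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalRecord",
    "CoverageTrack",
    "ParseError",
    "ValidationError",
    "parse_intervals",
    "write_intervals",
    "parse_track",
    "write_track",
    "parse_gene_table",
    "orf_start",
    "read_count_matrix",
    "write_count_matrix",
    "read_chrom_sizes",
]

STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Malformed input line; carries the file path and 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


class ValidationError(ValueError):
    """Structurally parseable input that violates a semantic invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``; strand in {+, -, .}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class IntervalRecord:
    """One parsed interval-file record: the interval plus dialect extras."""

    interval: GenomicInterval
    name: str | None = None
    score: float | None = None
    summit: int | None = None  # absolute 0-based summit position (narrowPeak / summits)
    raw_fields: tuple = field(default=(), compare=False)

    @property
    def summit_pos(self) -> int:
        if self.summit is not None:
            return self.summit
        # summits-dialect records are 1-bp intervals; the summit is the start
        return self.interval.start


_DIALECTS = ("bed", "narrowPeak", "summits")


def parse_intervals(path, dialect: str = "bed") -> list[IntervalRecord]:
    """Parse a BED-family interval file.

    Dialects: ``bed`` (>=3 columns), ``narrowPeak`` (10 columns, summit =
    start + 10th-column offset), ``summits`` (MACS ``*_summits.bed``: 1-bp
    intervals whose start is the summit). Coordinates are kept exactly as
    written (half-open, 0-based); record order is preserved.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    records: list[IntervalRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinate in {fields[1:3]}") from None
            if start >= end or start < 0:
                raise ParseError(path, lineno, f"invalid coordinates [{start},{end})")
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            summit = None
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise ParseError(path, lineno, "narrowPeak requires 10 columns")
                try:
                    offset = int(fields[9])
                except ValueError:
                    raise ParseError(path, lineno, f"non-integer summit offset {fields[9]!r}") from None
                if offset >= 0:
                    summit = start + offset
            elif dialect == "summits":
                if end - start != 1:
                    raise ParseError(path, lineno, f"summit record must span 1 bp, spans {end - start}")
                summit = start
            records.append(
                IntervalRecord(
                    GenomicInterval(chrom, start, end, strand),
                    name=name,
                    score=score,
                    summit=summit,
                    raw_fields=tuple(fields),
                )
            )
    return records


def write_intervals(records: Iterable[IntervalRecord], path, dialect: str = "bed") -> None:
    """Write records back out; canonical-dialect fixtures round-trip byte-identically."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.raw_fields:
                fh.write("\t".join(rec.raw_fields) + "\n")
                continue
            iv = rec.interval
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if rec.name is not None or dialect != "bed":
                fields.append(rec.name if rec.name is not None else ".")
            if rec.score is not None:
                fields.append(f"{rec.score:g}")
            fh.write("\t".join(fields) + "\n")


class CoverageTrack:
    """Piecewise-constant per-bp coverage: sorted, non-overlapping intervals per chromosome.

    Stored per chromosome as parallel numpy arrays (starts, ends, values).
    Positions not covered by any interval have value 0. Values must be finite
    and >= 0.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValidationError(f"{chrom}: ragged track arrays")
            if np.any(starts >= ends) or np.any(starts < 0):
                raise ValidationError(f"{chrom}: invalid interval bounds")
            if np.any(np.diff(starts) < 0):
                order = np.argsort(starts, kind="stable")
                starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
                raise ValidationError(
                    f"{chrom}: overlapping intervals "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValidationError(f"{chrom}: values must be finite and >= 0")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "CoverageTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in per_chrom.items():
            starts, ends, values = zip(*rows)
            data[chrom] = (np.array(starts), np.array(ends), np.array(values, dtype=float))
        return cls(data)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._data

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data[chrom]

    def iter_records(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom, (starts, ends, values) in self._data.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp values over [start, end); uncovered positions are 0.

        ``start`` may be negative and ``end`` may exceed the covered span; the
        caller is responsible for masking positions beyond chromosome ends.
        """
        if chrom not in self._data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            raise ValueError("end must exceed start")
        out = np.zeros(end - start, dtype=float)
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a, b = max(int(s), start), min(int(e), end)
            if a < b:
                out[a - start : b - start] = v
        return out

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._data.items()}
        )

    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self._data.values()))


def parse_track(path) -> CoverageTrack:
    """Parse a 4-column bedGraph into a CoverageTrack.

    Overlapping intervals within a chromosome raise ``ValidationError``;
    touching intervals are retained unmerged so that a write-then-read
    round-trip reproduces values exactly.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"bedGraph needs 4 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric coordinate or value") from None
            if start >= end or start < 0:
                raise ParseError(path, lineno, f"invalid coordinates [{start},{end})")
            records.append((fields[0], start, end, value))
    if not records:
        return CoverageTrack({})
    return CoverageTrack.from_records(records)


def write_track(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def parse_gene_table(path) -> pd.DataFrame:
    """Read a gene/ORF annotation as a DataFrame.

    Accepts a headered TSV (columns ``gene_id, chrom, start, end, strand`` plus
    optional flag columns such as ``is_rp``) or GFF3 (``.gff``/``.gff3``
    suffix; 1-based inclusive coordinates converted to 0-based half-open on
    read). Duplicate gene ids and unknown strand symbols are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        df = _parse_gff(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        missing = [c for c in _GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: gene table missing columns {missing}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        sym = df.loc[bad_strand, "strand"].iloc[0]
        raise ValidationError(f"{path}: unknown strand symbol {sym!r} (genes must be stranded)")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate gene id {df.loc[dup, 'gene_id'].iloc[0]!r}")
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: gene with start >= end")
    return df.reset_index(drop=True)


def _parse_gff(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(path, lineno, f"GFF needs 9 columns, got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
            if ftype not in ("gene", "ORF", "CDS", "mRNA"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer GFF coordinate") from None
            gene_id = None
            for item in attrs.split(";"):
                key, _, val = item.strip().partition("=")
                if key in ("ID", "gene_id", "Name"):
                    gene_id = val
                    break
            if gene_id is None:
                raise ParseError(path, lineno, "GFF record without ID attribute")
            # GFF is 1-based inclusive; convert once, here.
            rows.append({"gene_id": gene_id, "chrom": chrom, "start": start_i - 1,
                         "end": end_i, "strand": strand})
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def orf_start(row) -> int:
    """Strand-aware 5' coordinate of an ORF: start for +, end-1 for -."""
    return int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1


def read_count_matrix(path) -> pd.DataFrame:
    """Peak x sample count matrix from a headered TSV (first column = peak id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate peak identifiers")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample identifiers")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing cells in count matrix")
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative values in count matrix")
    return df


def write_count_matrix(matrix: pd.DataFrame, path, float_format: str = "%.17g") -> None:
    # full precision: normalized matrices are stage-isolation intermediates and
    # must reproduce the orchestrated run exactly when re-read
    matrix.to_csv(path, sep="\t", index_label="peak_id", float_format=float_format)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV chrom -> size."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "chrom sizes need 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer size {fields[1]!r}") from None
    return sizes
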