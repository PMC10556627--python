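"""Peak windows, strand-aware ORF assignment, locus classification, quartiles.

A peak's analysis window is summit +/- 150 bp (301 bp). A peak is assigned to
a gene when its summit lies within a configurable upstream window (default
300 bp) of the ORF's strand-aware 5' coordinate; subtelomeric peaks (summit
within 15 kb of a chromosome end) stay in the genome-wide set even without an
ORF assignment. Retained peaks are partitioned into residence-time quartiles
labelled shortest / short / long / longest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import GenomicInterval, IntervalRecord, ValidationError, orf_start

__all__ = [
    "PeakWindow",
    "GeneAssignment",
    "define_peak_windows",
    "assign_to_orfs",
    "classify_subtelomeric",
    "classify_rp",
    "partition_quartiles",
    "load_rp_list",
    "QUARTILE_LABELS",
]

WINDOW_HALF = 150  # bp on either side of the summit
QUARTILE_LABELS = ("shortest", "short", "long", "longest")


@dataclass(frozen=True)
class PeakWindow:
    """Summit-anchored analysis window [summit-150, summit+151)."""

    peak_id: str
    summit: int
    window: GenomicInterval
    truncated: bool = False  # window clipped at position 0


@dataclass(frozen=True)
class GeneAssignment:
    peak_id: str
    gene_id: str | None
    distance: int | None  # strand-aware upstream distance in bp
    is_rp: bool = False
    is_subtelomeric: bool = False
    quartile: str | None = None


def define_peak_windows(summits: list[IntervalRecord]) -> list[PeakWindow]:
    """Summit +/- 150 bp windows; windows clipped at position 0 are flagged."""
    windows = []
    for i, rec in enumerate(summits):
        summit = rec.summit_pos
        if summit < 0:
            raise ValidationError(f"negative summit position {summit}")
        start = summit - WINDOW_HALF
        truncated = start < 0
        peak_id = rec.name if rec.name else f"peak_{i + 1:05d}"
        windows.append(
            PeakWindow(
                peak_id=peak_id,
                summit=summit,
                window=GenomicInterval(rec.interval.chrom, max(start, 0), summit + WINDOW_HALF + 1),
                truncated=truncated,
            )
        )
    return windows


def assign_to_orfs(
    peaks: list[PeakWindow], genes: pd.DataFrame, window: int = 300
) -> list[GeneAssignment]:
    """Assign each peak to the gene whose ORF start it sits upstream of.

    A peak qualifies for a + strand gene when its summit lies in
    [orf_start - window, orf_start), and for a - strand gene when it lies in
    (five_prime, five_prime + window] — i.e. within ``window`` bp upstream in
    strand-oriented coordinates. Among multiple qualifying genes the nearest
    ORF start wins; ties break lexicographically on gene id. The result is
    invariant under gene-table reordering.
    """
    gene_rows = []
    for _, row in genes.iterrows():
        gene_rows.append((row["gene_id"], row["chrom"], row["strand"], orf_start(row)))
    assignments = []
    for peak in peaks:
        candidates = []  # (distance, gene_id)
        for gene_id, chrom, strand, start5 in gene_rows:
            if chrom != peak.window.chrom:
                continue
            if strand == "+":
                dist = start5 - peak.summit
            else:
                dist = peak.summit - start5
            if 0 < dist <= window:
                candidates.append((dist, gene_id))
        if candidates:
            dist, gene_id = min(candidates)
            assignments.append(GeneAssignment(peak.peak_id, gene_id, dist))
        else:
            assignments.append(GeneAssignment(peak.peak_id, None, None))
    return assignments


def classify_subtelomeric(
    peaks: list[PeakWindow], chrom_sizes: dict[str, int], margin: int = 15_000
) -> dict[str, bool]:
    """True iff the summit lies within ``margin`` bp of either chromosome end."""
    flags = {}
    for peak in peaks:
        chrom = peak.window.chrom
        if chrom not in chrom_sizes:
            raise ValidationError(f"{peak.peak_id}: no size for chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        flags[peak.peak_id] = peak.summit < margin or peak.summit >= size - margin
    return flags


def load_rp_list(path=None) -> set[str]:
    """Ribosomal-protein gene ids: packaged default list, user-replaceable by path."""
    if path is not None:
        with open(path) as fh:
            return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    text = resources.files("chipdecay.data").joinpath("rp_genes.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")}


def classify_rp(assignments: list[GeneAssignment], rp_ids: set[str]) -> list[GeneAssignment]:
    """Return assignments with the RP flag set from a gene-id membership list."""
    from dataclasses import replace

    return [
        replace(a, is_rp=(a.gene_id is not None and a.gene_id in rp_ids))
        for a in assignments
    ]


def partition_quartiles(values: dict[str, float]) -> dict[str, str]:
    """Quartile labels over residence times, ascending, stable ties by peak id.

    Rank boundaries at ceil(n/4), ceil(n/2), ceil(3n/4); group sizes sum to n.
    """
    n = len(values)
    if n < 4:
        raise ValidationError(f"need >= 4 values to form quartiles, got {n}")
    for pid, v in values.items():
        if not math.isfinite(v):
            raise ValidationError(f"{pid}: non-finite residence time")
    ordered = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    b1, b2, b3 = math.ceil(n / 4), math.ceil(n / 2), math.ceil(3 * n / 4)
    labels = {}
    for rank, (pid, _) in enumerate(ordered):
        if rank < b1:
            labels[pid] = QUARTILE_LABELS[0]
        elif rank < b2:
            labels[pid] = QUARTILE_LABELS[1]
        elif rank < b3:
            labels[pid] = QUARTILE_LABELS[2]
        else:
            labels[pid] = QUARTILE_LABELS[3]
    return labels


def annotation_table(
    peaks: list[PeakWindow],
    assignments: list[GeneAssignment],
    subtel: dict[str, bool],
    quartiles: dict[str, str],
) -> pd.DataFrame:
    """Combine the annotation layers into the TSV-ready table."""
    by_id = {a.peak_id: a for a in assignments}
    rows = []
    for peak in peaks:
        a = by_id[peak.peak_id]
        rows.append(
            {
                "peak_id": peak.peak_id,
                "chrom": peak.window.chrom,
                "summit": peak.summit,
                "gene_id": a.gene_id if a.gene_id is not None else ".",
                "distance": a.distance if a.distance is not None else -1,
                "is_rp": a.is_rp,
                "is_subtelomeric": subtel[peak.peak_id],
                "quartile": quartiles.get(peak.peak_id, "unassigned"),
            }
        )
    return pd.DataFrame(rows).set_index("peak_id")
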