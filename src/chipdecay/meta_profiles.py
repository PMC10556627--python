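"""Grouped meta-gene / meta-peak coverage summaries.

Two anchorings share one averaging machinery:

* length-scaled transcript profiles — each transcript is split into ``nbins``
  equal (fractional-bp) bins in 5'->3' orientation and each bin carries the
  length-weighted mean per-bp coverage;
* summit-centered profiles — one column per bp offset in [-flank, +flank],
  with positions beyond chromosome ends masked (NaN), not zero-filled.

Group means come with per-bin t-based 95% confidence bands across loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CoverageTrack, GenomicInterval, ValidationError

__all__ = [
    "MetaProfileSet",
    "length_scaled_profile",
    "length_scaled_matrix",
    "summit_centered_profile",
    "group_mean_ci",
    "assign_transcripts",
]


@dataclass
class MetaProfileSet:
    """Per-locus coverage vectors (loci x bins, NaN = masked) with group labels."""

    profiles: np.ndarray
    labels: np.ndarray  # group label per locus
    locus_ids: list[str]
    bin_kind: str  # "scaled" (0-100% of transcript) or "offset" (bp from summit)

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.profiles.ndim != 2:
            raise ValidationError("profiles must be a 2-D loci x bins matrix")
        if len(self.labels) != self.profiles.shape[0]:
            raise ValidationError("one group label per locus required")

    @property
    def n_loci(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_bins(self) -> int:
        return self.profiles.shape[1]


def _cumulative(per_bp: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(per_bp)])


def _integral(cum: np.ndarray, per_bp: np.ndarray, a: float, b: float) -> float:
    """Integral of the piecewise-constant per-bp signal over fractional [a, b)."""

    def F(x: float) -> float:
        i = int(math.floor(x))
        if i >= len(per_bp):
            return float(cum[-1])
        return float(cum[i] + (x - i) * per_bp[i])

    return F(b) - F(a)


def length_scaled_profile(
    track: CoverageTrack, transcript: GenomicInterval, nbins: int = 100
) -> np.ndarray:
    """Length-weighted mean per-bp coverage in ``nbins`` equal bins, 5'->3'.

    Bins have fractional-bp boundaries, so any transcript length is admissible;
    minus-strand transcripts are reversed so that bin 0 is the 5' end.
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    if transcript.chrom not in track:
        raise ValidationError(f"transcript on unknown chromosome {transcript.chrom!r}")
    per_bp = track.per_bp(transcript.chrom, transcript.start, transcript.end)
    cum = _cumulative(per_bp)
    L = len(per_bp)
    width = L / nbins
    out = np.empty(nbins)
    for k in range(nbins):
        a, b = k * width, (k + 1) * width
        out[k] = _integral(cum, per_bp, a, b) / width
    if transcript.strand == "-":
        out = out[::-1]
    return out


def length_scaled_matrix(
    track: CoverageTrack, transcripts: list[tuple[str, GenomicInterval]], nbins: int = 100
) -> tuple[np.ndarray, list[str]]:
    ids, rows = [], []
    for tid, iv in transcripts:
        rows.append(length_scaled_profile(track, iv, nbins))
        ids.append(tid)
    return np.array(rows) if rows else np.empty((0, nbins)), ids


def summit_centered_profile(
    track: CoverageTrack,
    summits: list[tuple[str, int]],
    flank: int = 500,
    chrom_sizes: dict[str, int] | None = None,
) -> np.ndarray:
    """Matrix (summits x (2*flank+1)); column j = bp offset j - flank.

    Positions before 0 or at/after the chromosome end (when sizes are given)
    are NaN-masked and excluded from downstream means.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    width = 2 * flank + 1
    rows = np.full((len(summits), width), np.nan)
    for i, (chrom, summit) in enumerate(summits):
        if chrom not in track:
            raise ValidationError(f"summit on unknown chromosome {chrom!r}")
        start, end = summit - flank, summit + flank + 1
        vals = track.per_bp(chrom, start, end)
        positions = np.arange(start, end)
        valid = positions >= 0
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValidationError(f"no size for chromosome {chrom!r}")
            valid &= positions < chrom_sizes[chrom]
        row = np.where(valid, vals, np.nan)
        rows[i] = row
    return rows


def group_mean_ci(profiles: MetaProfileSet, level: float = 0.95) -> pd.DataFrame:
    """Per-group, per-bin mean with t-based confidence band across loci.

    Half-width = t(level, m-1) * sd / sqrt(m) with m the unmasked member count
    in that bin. Groups of size 1 get their mean with ``ci_defined = False``.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0,1)")
    rows = []
    for group in sorted(set(profiles.labels)):
        members = profiles.profiles[profiles.labels == group]
        m = np.sum(~np.isnan(members), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(np.isnan(members), np.nan, members), axis=0)
            sd = np.full(profiles.n_bins, np.nan)
            ok = m >= 2
            if ok.any():
                sd[ok] = np.nanstd(members[:, ok], axis=0, ddof=1)
        half = np.full(profiles.n_bins, np.nan)
        defined = m >= 2
        if defined.any():
            tcrit = stats.t.ppf(0.5 + level / 2.0, m[defined] - 1)
            half[defined] = tcrit * sd[defined] / np.sqrt(m[defined])
        for b in range(profiles.n_bins):
            rows.append(
                {
                    "group": group,
                    "bin": b,
                    "mean": mean[b],
                    "ci_lo": mean[b] - half[b] if defined[b] else np.nan,
                    "ci_hi": mean[b] + half[b] if defined[b] else np.nan,
                    "n": int(m[b]),
                    "ci_defined": bool(defined[b]),
                }
            )
    return pd.DataFrame(rows)


def assign_transcripts(
    summits: list[tuple[str, str, int]],
    transcripts: pd.DataFrame,
) -> dict[str, str | None]:
    """Nearest transcript per peak: minimal |summit - 5' end|, ties to the longer.

    ``summits`` rows are (peak_id, chrom, summit); ``transcripts`` is a gene
    table (gene_id, chrom, start, end, strand).
    """
    tx_rows = []
    for _, row in transcripts.iterrows():
        five = int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1
        length = int(row["end"]) - int(row["start"])
        tx_rows.append((row["gene_id"], row["chrom"], five, length))
    chosen: dict[str, str | None] = {}
    for peak_id, chrom, summit in summits:
        best = None  # (distance, -length, gene_id)
        for gene_id, tchrom, five, length in tx_rows:
            if tchrom != chrom:
                continue
            key = (abs(summit - five), -length, gene_id)
            if best is None or key < best:
                best = key
        chosen[peak_id] = best[2] if best is not None else None
    return chosen
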