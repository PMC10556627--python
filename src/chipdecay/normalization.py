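"""The two normalizations of the depletion pipeline.

1. Spike-in scaling: each library is scaled so that the read count assigned to
   the constant-abundance spike-in species (S. paradoxus in the original
   design) is equalized across samples. The reference constant is the median
   spike-in count, which keeps normalized counts on the raw-count scale and is
   invariant under sample reordering.

2. Display scaling: coverage tracks are divided by the bp-weighted median of
   per-bp coverage outside a caller-supplied "nonheterochromatic" exclusion
   set (HML, HMR, subtelomeres, rDNA in the original genome), so that a
   typical euchromatic position has value 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, GenomicInterval, ValidationError

__all__ = [
    "TimePointSample",
    "ScaleFactorSet",
    "read_sample_sheet",
    "spikein_scale_factors",
    "apply_scale_factors",
    "median_normalize_track",
    "bp_weighted_median",
]


@dataclass(frozen=True)
class TimePointSample:
    """One IP library of the depletion time course."""

    sample_id: str
    time: float  # minutes since depletion start
    replicate: str
    condition: str  # {"depletion", "control"}
    experiment_reads: float
    spikein_reads: float

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"{self.sample_id}: time must be finite and >= 0")


@dataclass(frozen=True)
class ScaleFactorSet:
    """Per-sample multiplicative factors; factor * spikein_reads is constant."""

    factors: dict[str, float]
    reference: float

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]


SAMPLE_SHEET_COLUMNS = ["sample_id", "time_min", "replicate", "condition",
                        "experiment_reads", "spikein_reads"]


def read_sample_sheet(path) -> list[TimePointSample]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: sample sheet missing columns {missing}")
    return [
        TimePointSample(
            sample_id=row.sample_id,
            time=float(row.time_min),
            replicate=str(row.replicate),
            condition=str(row.condition),
            experiment_reads=float(row.experiment_reads),
            spikein_reads=float(row.spikein_reads),
        )
        for row in df.itertuples()
    ]


def spikein_scale_factors(samples: list[TimePointSample]) -> ScaleFactorSet:
    """factor(s) = reference / spikein_reads(s), reference = median spike-in count."""
    if not samples:
        raise ValidationError("no samples given")
    for s in samples:
        if s.spikein_reads <= 0:
            raise ValidationError(f"sample {s.sample_id!r} has spike-in read count {s.spikein_reads} <= 0")
    counts = np.array([s.spikein_reads for s in samples], dtype=float)
    reference = float(np.median(counts))
    return ScaleFactorSet(
        factors={s.sample_id: reference / s.spikein_reads for s in samples},
        reference=reference,
    )


def apply_scale_factors(matrix: pd.DataFrame, factors: ScaleFactorSet) -> pd.DataFrame:
    """Column-wise scaling of a peak x sample matrix; the input is not modified."""
    missing = [c for c in matrix.columns if c not in factors.factors]
    if missing:
        raise ValidationError(f"no scale factor for sample column(s) {missing}")
    out = matrix.astype(float).copy()
    for col in out.columns:
        out[col] = out[col] * factors.factors[col]
    return out


def _lower_weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted lower median: smallest v with cumulative weight >= half the total."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    return float(v[int(np.searchsorted(cum, half, side="left"))])


def bp_weighted_median(track: CoverageTrack, excluded: list[GenomicInterval] = ()) -> float:
    """bp-weighted median of per-bp values, intervals weighted by unexcluded length.

    Only covered positions enter; ties resolve to the lower median.
    """
    values, weights = [], []
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in excluded:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in track.chroms:
        starts, ends, vals = track.intervals(chrom)
        lengths = (ends - starts).astype(float)
        for iv in excl_by_chrom.get(chrom, []):
            overlap = np.clip(np.minimum(ends, iv.end) - np.maximum(starts, iv.start), 0, None)
            lengths -= overlap
        keep = lengths > 0
        values.append(vals[keep])
        weights.append(lengths[keep])
    if not values or sum(len(v) for v in values) == 0:
        raise ValidationError("exclusion set covers every tracked position")
    return _lower_weighted_median(np.concatenate(values), np.concatenate(weights))


def median_normalize_track(
    track: CoverageTrack, excluded: list[GenomicInterval] = ()
) -> CoverageTrack:
    """Divide every value by the bp-weighted median outside ``excluded``."""
    if not track.chroms:
        raise ValidationError("empty coverage track")
    m = bp_weighted_median(track, excluded)
    if m <= 0:
        raise ValidationError(f"nonexcluded median coverage is {m}; cannot normalize")
    return track.scaled(1.0 / m)
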