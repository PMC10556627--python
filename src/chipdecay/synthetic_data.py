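"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a staggered nuclear-depletion ChIP time course with a
constant-abundance spike-in species: per-peak IP counts decay as
``yf + (y0 - yf) * exp(-koff * t)``, every sample carries an independent
multiplicative depth distortion, and the spike-in read count of each sample is
proportional to that distortion — which is exactly what makes spike-in
normalization necessary and sufficient to recover the decay. Accessory tracks
plant the downstream structure the analyses look for: nascent-transcription
coverage rising with dwell-time group, a factor-occupancy bump over each peak
rising with dwell-time group, and a summit-centered histone dip whose depth
grows with occupancy and whose width grows with dwell time.

Also houses the synonymous-SNP locus-disambiguation designer and its k-mer
uniqueness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import CoverageTrack, GenomicInterval, ValidationError
from .peak_annotation import load_rp_list

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "simulate_timecourse",
    "simulate_tracks",
    "write_simulation",
    "design_synonymous_snps",
    "apply_variants",
    "uniqueness_check",
]

NOISE_MODELS = ("none", "poisson", "negbin")


class SimulationError(ValueError):
    """Invalid simulation configuration; message lists every violation."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic depletion experiment.

    Defaults follow the experimental design being emulated where stated
    (5% spike-in by input; duplicate libraries) and otherwise use values a
    ChIP-seq practitioner would call realistic: a 7-point time grid spanning
    0-60 min to cover residence times of roughly 0.5-60 min, log-normal
    dwell times with a 10-min median, and negative-binomial count noise
    (ChIP counts are over-dispersed relative to Poisson).
    """

    seed: int
    n_peaks: int = 500
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 7.5, 15.0, 30.0, 60.0)
    replicates: int = 2
    residence_median: float = 8.0  # minutes
    residence_sigma: float = 0.6  # ln-scale sd of the dwell-time distribution
    y0_median: float = 80.0  # normalized-signal scale at t = 0
    y0_sigma: float = 0.7
    occupancy_residence_rho: float = 0.45  # log-scale correlation of y0 with dwell time
    yf_frac_range: tuple[float, float] = (0.02, 0.30)
    noise: str = "negbin"
    nb_dispersion: float = 0.05
    nb_variance: str = "linear"  # var = (1+d)*mu; "quadratic": var = mu + d*mu^2
    spikein_fraction: float = 0.05
    spikein_jitter_sigma: float = 0.2  # applied only when count noise is active
    depth: float = 2_000_000.0
    depth_sigma: float = 0.5  # ln-scale sd of per-sample depth distortion
    rp_fraction: float = 0.2
    rp_residence_boost: float = 2.0
    n_chroms: int = 4
    peak_spacing: int = 12_000
    include_constant_control: bool = True
    # planted track structure
    h3_base: float = 1.0
    h3_depth_base: float = 0.25
    h3_depth_slope: float = 0.5  # x occupancy percentile
    h3_width_base: float = 60.0  # bp Gaussian sigma
    h3_width_step: float = 30.0  # per dwell-time quartile index
    netseq_base: float = 2.0
    netseq_step: float = 1.0  # per dwell-time quartile index
    taf1_base: float = 2.0
    taf1_step: float = 1.0
    track_background: float = 0.2
    track_noise_sd: float = 0.15  # relative, per-bp, inside rendered windows
    track_flank: int = 600

    def validate(self) -> None:
        problems = []
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.n_peaks < 1:
            problems.append("n_peaks must be >= 1")
        if len(self.times) < 3 or any(t < 0 for t in self.times):
            problems.append("times must be >= 3 nonnegative values")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.residence_median <= 0 or self.residence_sigma < 0:
            problems.append("residence-time distribution parameters must be positive")
        if self.y0_median <= 0:
            problems.append("y0_median must be > 0")
        if not (-1 < self.occupancy_residence_rho < 1):
            problems.append("occupancy_residence_rho must be in (-1,1)")
        if not (0 <= self.yf_frac_range[0] <= self.yf_frac_range[1] < 1):
            problems.append("yf_frac_range must satisfy 0 <= lo <= hi < 1")
        if self.noise not in NOISE_MODELS:
            problems.append(f"noise must be one of {NOISE_MODELS}")
        if self.nb_dispersion <= 0:
            problems.append("nb_dispersion must be > 0")
        if self.nb_variance not in ("linear", "quadratic"):
            problems.append("nb_variance must be 'linear' or 'quadratic'")
        if not (0 < self.spikein_fraction < 1):
            problems.append("spikein_fraction must be in (0,1)")
        if self.depth <= 0:
            problems.append("depth must be > 0")
        if not (0 <= self.rp_fraction < 1):
            problems.append("rp_fraction must be in [0,1)")
        if self.n_chroms < 1 or self.peak_spacing < 2 * self.track_flank:
            problems.append("need n_chroms >= 1 and peak_spacing >= 2*track_flank")
        if problems:
            raise SimulationError("; ".join(problems))

    @property
    def peaks_per_chrom(self) -> int:
        total = self.n_peaks + (1 if self.include_constant_control else 0)
        return math.ceil(total / self.n_chroms)

    def chrom_names(self) -> list[str]:
        return [f"chr_syn{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        length = 40_000 + self.peaks_per_chrom * self.peak_spacing
        return {c: length for c in self.chrom_names()}


def _quartile_index(values: np.ndarray) -> np.ndarray:
    """0..3 quartile index by ascending value, boundaries at ceil(n/4) ranks."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    b1, b2, b3 = math.ceil(n / 4), math.ceil(n / 2), math.ceil(3 * n / 4)
    idx = np.zeros(n, dtype=int)
    idx[ranks >= b1] = 1
    idx[ranks >= b2] = 2
    idx[ranks >= b3] = 3
    return idx


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (sample sheet, raw count matrix, ground-truth table).

    Raw expected count(p, s) = distortion(s) * model(t_s; y0_p, yf_p, koff_p);
    spike-in reads are proportional to distortion(s), so spike-in scaling
    removes the distortion exactly when ``noise='none'``. Identical seeds give
    identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_peaks

    # --- genome layout ---------------------------------------------------
    chroms = config.chrom_names()
    per_chrom = config.peaks_per_chrom
    total_peaks = n + (1 if config.include_constant_control else 0)
    peak_chrom, peak_summit = [], []
    for i in range(total_peaks):
        c = chroms[i // per_chrom]
        base = 20_000 + (i % per_chrom) * config.peak_spacing
        jitter = int(rng.integers(-2_000, 2_001))
        peak_chrom.append(c)
        peak_summit.append(base + jitter)

    # --- kinetic truth ----------------------------------------------------
    # bivariate log-normal (tau, y0): sites bound longer also show higher
    # initial occupancy, as in the system being emulated
    rho = config.occupancy_residence_rho
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    tau = np.exp(math.log(config.residence_median) + config.residence_sigma * z1)
    n_rp = int(round(config.rp_fraction * n))
    rp_idx = rng.choice(n, size=n_rp, replace=False) if n_rp else np.array([], dtype=int)
    is_rp = np.zeros(n, dtype=bool)
    is_rp[rp_idx] = True
    tau[is_rp] *= config.rp_residence_boost
    koff = 1.0 / tau
    y0 = np.exp(
        math.log(config.y0_median)
        + config.y0_sigma * (rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
    )
    yf = y0 * rng.uniform(*config.yf_frac_range, size=n)

    dwell_q = _quartile_index(tau)
    occ_order = np.argsort(y0, kind="stable")
    occ_rank = np.empty(n, dtype=int)
    occ_rank[occ_order] = np.arange(n)
    occ_pct = occ_rank / max(n - 1, 1)
    occ_q = _quartile_index(y0)

    # --- genes ------------------------------------------------------------
    rp_names = sorted(load_rp_list())
    strands = rng.choice(["+", "-"], size=n)
    up_dist = rng.integers(30, 281, size=n)
    gene_len = rng.integers(600, 2_401, size=n)
    gene_ids, gene_start, gene_end = [], [], []
    rp_counter = 0
    for i in range(n):
        if is_rp[i]:
            gene_ids.append(rp_names[rp_counter % len(rp_names)]
                            if rp_counter < len(rp_names)
                            else f"{rp_names[rp_counter % len(rp_names)]}_{rp_counter // len(rp_names)}")
            rp_counter += 1
        else:
            gene_ids.append(f"GENE{i:04d}")
        s = peak_summit[i]
        if strands[i] == "+":
            start5 = s + int(up_dist[i])
            gene_start.append(start5)
            gene_end.append(start5 + int(gene_len[i]))
        else:
            start5 = s - int(up_dist[i])  # 5' coordinate = end - 1
            gene_end.append(start5 + 1)
            gene_start.append(start5 + 1 - int(gene_len[i]))

    # --- planted track structure -----------------------------------------
    h3_width = config.h3_width_base + config.h3_width_step * dwell_q
    h3_depth = np.clip(
        config.h3_depth_base + config.h3_depth_slope * occ_pct, 0.0, 0.95 * config.h3_base
    )
    netseq_level = config.netseq_base + config.netseq_step * dwell_q
    taf1_level = config.taf1_base + config.taf1_step * dwell_q

    peak_ids = [f"peak_{i + 1:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "chrom": peak_chrom[:n],
            "summit": peak_summit[:n],
            "strand": strands,
            "gene_id": gene_ids,
            "gene_start": gene_start,
            "gene_end": gene_end,
            "is_rp": is_rp,
            "is_control": False,
            "y0": y0,
            "yf": yf,
            "koff": koff,
            "residence": tau,
            "dwell_quartile": dwell_q,
            "occupancy_rank": occ_rank,
            "occupancy_quartile": occ_q,
            "h3_width": h3_width,
            "h3_depth": h3_depth,
            "netseq_level": netseq_level,
            "taf1_level": taf1_level,
        }
    ).set_index("peak_id")

    if config.include_constant_control:
        c_y0 = float(np.median(y0))
        truth.loc["peak_control_flat"] = {
            "chrom": peak_chrom[n],
            "summit": peak_summit[n],
            "strand": "+",
            "gene_id": ".",
            "gene_start": -1,
            "gene_end": -1,
            "is_rp": False,
            "is_control": True,
            "y0": c_y0,
            "yf": c_y0,
            "koff": np.nan,
            "residence": np.nan,
            "dwell_quartile": -1,
            "occupancy_rank": -1,
            "occupancy_quartile": -1,
            "h3_width": 0.0,
            "h3_depth": 0.0,
            "netseq_level": 0.0,
            "taf1_level": config.track_background,
        }

    # --- samples and counts ------------------------------------------------
    sample_grid = [
        (t, rep) for t in config.times for rep in range(1, config.replicates + 1)
    ]
    # per-sample depth distortion, normalized to median 1 so the spike-in
    # reference (median spike-in count) maps normalized counts back onto the
    # model scale exactly
    distortions = rng.lognormal(0.0, config.depth_sigma, size=len(sample_grid))
    distortions /= np.median(distortions)
    sample_rows = []
    count_cols = {}
    noisy = config.noise != "none"
    for (t, rep), distortion in zip(sample_grid, distortions):
        sid = f"t{t:g}_rep{rep}"
        distortion = float(distortion)
        frac = config.spikein_fraction
        if noisy and config.spikein_jitter_sigma > 0:
            frac *= float(rng.lognormal(0.0, config.spikein_jitter_sigma))
        spike_expected = frac * config.depth * distortion
        spikein_reads = float(rng.poisson(spike_expected)) if noisy else spike_expected
        model = truth["yf"].to_numpy() + (
            truth["y0"].to_numpy() - truth["yf"].to_numpy()
        ) * np.exp(-np.nan_to_num(truth["koff"].to_numpy(), nan=0.0) * t)
        mu = distortion * model
        if config.noise == "none":
            counts = mu
        elif config.noise == "poisson":
            counts = rng.poisson(mu).astype(float)
        elif config.nb_variance == "linear":
            # NB1: var = (1 + d) * mu — Poisson counting noise with modest
            # extra-Poisson inflation, the regime of window counts from one
            # library per time point
            d = config.nb_dispersion
            counts = rng.negative_binomial(mu / d, 1.0 / (1.0 + d)).astype(float)
        else:
            # NB2: var = mu + d * mu^2 — biological-replicate-scale dispersion
            size = 1.0 / config.nb_dispersion
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p).astype(float)
        count_cols[sid] = counts
        sample_rows.append(
            {
                "sample_id": sid,
                "time_min": t,
                "replicate": str(rep),
                "condition": "depletion",
                "experiment_reads": float(np.round((1 - frac) * config.depth * distortion)),
                "spikein_reads": spikein_reads,
            }
        )
    sample_sheet = pd.DataFrame(sample_rows)
    counts = pd.DataFrame(count_cols, index=truth.index)
    return sample_sheet, counts, truth


def _render_window(
    base: float, values_fn, start: int, end: int, rng, noise_sd: float
) -> np.ndarray:
    x = np.arange(start, end, dtype=float)
    vals = values_fn(x)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd * max(base, 1e-12), size=len(vals))
        vals = np.maximum(vals, 0.0)
    return vals


def _segmented_track(
    chrom_sizes: dict[str, int],
    windows: dict[str, list[tuple[int, int, np.ndarray]]],
    background: float,
) -> CoverageTrack:
    """Per-chromosome track: constant background with per-bp windows spliced in."""
    data = {}
    for chrom, size in chrom_sizes.items():
        starts, ends, values = [], [], []
        pos = 0
        for wstart, wend, vals in sorted(windows.get(chrom, [])):
            if wstart > pos:
                starts.append(pos)
                ends.append(wstart)
                values.append(background)
            starts.extend(range(wstart, wend))
            ends.extend(range(wstart + 1, wend + 1))
            values.extend(vals.tolist())
            pos = wend
        if pos < size:
            starts.append(pos)
            ends.append(size)
            values.append(background)
        data[chrom] = (np.array(starts), np.array(ends), np.array(values, dtype=float))
    return CoverageTrack(data)


def simulate_tracks(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[CoverageTrack, CoverageTrack, pd.DataFrame, CoverageTrack]:
    """Render (H3 track, NET-seq track, transcript table, occupancy track).

    H3: baseline minus a summit-centered Gaussian dip (depth grows with
    planted occupancy, width with dwell-time quartile). NET-seq: constant
    coverage at the planted level over each assigned transcript. Occupancy
    (Taf1-like): background plus a bump over each peak window at the planted
    level. With ``noise='none'`` every track equals its analytic template.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    sizes = config.chrom_sizes()
    noise_sd = config.track_noise_sd if config.noise != "none" else 0.0
    flank = config.track_flank

    h3_windows: dict[str, list] = {}
    taf_windows: dict[str, list] = {}
    net_windows: dict[str, list] = {}
    tx_rows = []
    for peak_id, row in truth.iterrows():
        chrom, summit = row["chrom"], int(row["summit"])
        # histone dip
        depth, width = float(row["h3_depth"]), float(row["h3_width"])
        wstart, wend = max(summit - flank, 0), min(summit + flank + 1, sizes[chrom])

        def h3_fn(x, s=summit, d=depth, w=width):
            if d <= 0 or w <= 0:
                return np.full_like(x, config.h3_base)
            return config.h3_base - d * np.exp(-((x - s) ** 2) / (2.0 * w * w))

        h3_windows.setdefault(chrom, []).append(
            (wstart, wend, _render_window(config.h3_base, h3_fn, wstart, wend, rng, noise_sd))
        )
        # occupancy bump over the summit +/- 150 window
        level = float(row["taf1_level"])
        bstart, bend = max(summit - 150, 0), min(summit + 151, sizes[chrom])
        taf_windows.setdefault(chrom, []).append(
            (bstart, bend,
             _render_window(level, lambda x, lv=level: np.full_like(x, lv), bstart, bend, rng, noise_sd))
        )
        # nascent transcription over the transcript
        if row["gene_id"] != "." and int(row["gene_start"]) >= 0:
            tstart = max(int(row["gene_start"]) - 50, 0)
            tend = min(int(row["gene_end"]) + 50, sizes[chrom])
            nlevel = float(row["netseq_level"])
            net_windows.setdefault(chrom, []).append(
                (tstart, tend,
                 _render_window(nlevel, lambda x, lv=nlevel: np.full_like(x, lv), tstart, tend, rng, noise_sd))
            )
            tx_rows.append(
                {
                    "gene_id": row["gene_id"],
                    "chrom": chrom,
                    "start": tstart,
                    "end": tend,
                    "strand": row["strand"],
                }
            )
    h3 = _segmented_track(sizes, h3_windows, config.h3_base)
    netseq = _segmented_track(sizes, net_windows, 0.0)
    taf1 = _segmented_track(sizes, taf_windows, config.track_background)
    transcripts = pd.DataFrame(tx_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return h3, netseq, transcripts, taf1


def write_simulation(outdir, config: SimulationConfig, with_tracks: bool = True) -> dict:
    """Run the generator and write every pipeline input format under ``outdir``."""
    from pathlib import Path

    from .io_formats import write_count_matrix, write_track

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_sheet, counts, truth = simulate_timecourse(config)
    paths = {
        "sample_sheet": outdir / "sample_sheet.tsv",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
        "summits": outdir / "summits.bed",
        "genes": outdir / "genes.tsv",
        "chrom_sizes": outdir / "chrom.sizes",
    }
    sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False, float_format="%.10g")
    write_count_matrix(counts, paths["counts"])
    truth.to_csv(paths["truth"], sep="\t", index_label="peak_id", float_format="%.10g")
    with open(paths["summits"], "w") as fh:
        for peak_id, row in truth.iterrows():
            s = int(row["summit"])
            fh.write(f"{row['chrom']}\t{s}\t{s + 1}\t{peak_id}\n")
    genes = truth.loc[~truth["is_control"],
                      ["gene_id", "chrom", "gene_start", "gene_end", "strand", "is_rp"]]
    genes = genes.rename(columns={"gene_start": "start", "gene_end": "end"})
    genes.to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in config.chrom_sizes().items():
            fh.write(f"{chrom}\t{size}\n")
    if with_tracks:
        h3, netseq, transcripts, taf1 = simulate_tracks(truth, config)
        paths.update(
            h3=outdir / "h3.bedgraph",
            netseq=outdir / "netseq.bedgraph",
            taf1=outdir / "taf1.bedgraph",
            transcripts=outdir / "transcripts.tsv",
        )
        write_track(h3, paths["h3"])
        write_track(netseq, paths["netseq"])
        write_track(taf1, paths["taf1"])
        transcripts.to_csv(paths["transcripts"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Synonymous-SNP designer
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _codon_aa(codon: str) -> str:
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[codon]


def _synonymous_alt(cds: str, pos: int) -> str | None:
    """Deterministic synonymous single-base substitution at ``pos``, or None."""
    ci = pos // 3
    codon = cds[ci * 3 : ci * 3 + 3]
    off = pos % 3
    aa = _codon_aa(codon)
    for alt in _BASES:
        if alt == codon[off]:
            continue
        mutated = codon[:off] + alt + codon[off + 1 :]
        if _codon_aa(mutated) == aa:
            return alt
    return None


def design_synonymous_snps(
    cds: str,
    spacing: int = 30,
    window: int = 10,
    existing_variants: list[int] | None = None,
) -> tuple[list[tuple[int, str, str]], list[int]]:
    """Place synonymous single-base variants roughly every ``spacing`` bp.

    Walks targets ``spacing`` bp apart; at each target the nearest position in
    [target - window, target + window] admitting a synonymous single-base
    substitution gets a variant (positions inside codons with no synonymous
    move, e.g. ATG/TGG, are skipped to the nearest eligible position). Targets
    with no eligible position are reported as gaps. Positions listed in
    ``existing_variants`` count as already satisfying their target, so
    re-running on an edited sequence with the prior positions supplied yields
    no further variants where spacing is respected.

    Returns (variants, gaps): variants as (0-based position, ref base, alt
    base); gaps as the unsatisfiable target positions.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    if set(cds) - set(_BASES):
        raise ValidationError(f"invalid bases {sorted(set(cds) - set(_BASES))}")
    if cds[:3] != "ATG":
        raise ValidationError("CDS must start with the ATG start codon")
    existing = sorted(existing_variants or [])
    variants: list[tuple[int, str, str]] = []
    gaps: list[int] = []
    last = -1
    target = spacing
    while target < len(cds):
        satisfied = [p for p in existing if target - window <= p <= target + window and p > last]
        if satisfied:
            last = min(satisfied, key=lambda p: (abs(p - target), p))
            target = last + spacing
            continue
        candidates = [
            p
            for p in range(max(target - window, 0), min(target + window + 1, len(cds)))
            if p > last and p not in existing and _synonymous_alt(cds, p) is not None
        ]
        if candidates:
            pos = min(candidates, key=lambda p: (abs(p - target), p))
            variants.append((pos, cds[pos], _synonymous_alt(cds, pos)))
            last = pos
            target = pos + spacing
        else:
            gaps.append(target)
            target += spacing
    return variants, gaps


def apply_variants(seq: str, variants: list[tuple[int, str, str]]) -> str:
    chars = list(seq)
    for pos, ref, alt in variants:
        if chars[pos] != ref:
            raise ValidationError(f"reference mismatch at {pos}: {chars[pos]} != {ref}")
        chars[pos] = alt
    return "".join(chars)


def uniqueness_check(reference: str, edited: str, k: int) -> float:
    """Fraction of k-mer start positions at which the two sequences differ.

    1.0 means every k-length read spans at least one variant and therefore
    maps unambiguously to one of the two copies.
    """
    if len(reference) != len(edited):
        raise ValidationError("sequences must have equal length")
    if k > len(reference):
        raise ValidationError("k exceeds sequence length")
    diff = np.fromiter((a != b for a, b in zip(reference, edited)), dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(diff)])
    n_pos = len(reference) - k + 1
    has_variant = cum[k:] - cum[:-k][:n_pos] > 0
    return float(np.mean(has_variant))
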