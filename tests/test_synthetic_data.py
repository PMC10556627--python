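import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from chipdecay.decay_fitting import DecaySeries, fit_decay
from chipdecay.io_formats import ValidationError
from chipdecay.normalization import TimePointSample, apply_scale_factors, spikein_scale_factors
from chipdecay.synthetic_data import (
    SimulationConfig,
    SimulationError,
    apply_variants,
    design_synonymous_snps,
    simulate_timecourse,
    simulate_tracks,
    uniqueness_check,
    write_simulation,
)


def normalized_counts(sheet, counts):
    samples = [
        TimePointSample(r.sample_id, r.time_min, str(r.replicate), r.condition,
                        r.experiment_reads, r.spikein_reads)
        for r in sheet.itertuples()
    ]
    return apply_scale_factors(counts, spikein_scale_factors(samples)), samples


class TestConfig:
    def test_invalid_fields_all_reported(self):
        cfg = SimulationConfig(seed=1, n_peaks=0, spikein_fraction=2.0, noise="bogus")
        with pytest.raises(SimulationError) as exc:
            cfg.validate()
        msg = str(exc.value)
        assert "n_peaks" in msg and "spikein_fraction" in msg and "noise" in msg


class TestTimecourse:
    def test_same_seed_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_peaks=12)
        p1 = write_simulation(tmp_path / "a", cfg)
        p2 = write_simulation(tmp_path / "b", cfg)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_zero_noise_fit_recovers_truth(self, small_noiseless):
        cfg, sheet, counts, truth = small_noiseless
        normalized, samples = normalized_counts(sheet, counts)
        times = np.array([s.time for s in samples])
        for pid in list(truth.index[:10]):
            if truth.loc[pid, "is_control"]:
                continue
            fit = fit_decay(DecaySeries(pid, times, normalized.loc[pid].to_numpy()))
            assert fit.converged
            assert fit.koff == pytest.approx(truth.loc[pid, "koff"], rel=1e-6)
            assert fit.y0 == pytest.approx(truth.loc[pid, "y0"], rel=1e-6)

    def test_spikein_contract_distortion_removed(self, small_noiseless):
        """With noise=none the planted depth distortion cancels exactly."""
        cfg, sheet, counts, truth = small_noiseless
        normalized, samples = normalized_counts(sheet, counts)
        by_time = {}
        for s in samples:
            by_time.setdefault(s.time, []).append(s.sample_id)
        for t, cols in by_time.items():
            if len(cols) < 2:
                continue
            sub = normalized[cols]
            np.testing.assert_allclose(sub.iloc[:, 0], sub.iloc[:, 1], rtol=1e-12)

    def test_noisy_recovery_correlates_with_truth(self, small_noisy):
        cfg, sheet, counts, truth, *_ = small_noisy
        normalized, samples = normalized_counts(sheet, counts)
        times = np.array([s.time for s in samples])
        est, true = [], []
        for pid, row in truth.iterrows():
            if row["is_control"]:
                continue
            fit = fit_decay(DecaySeries(pid, times, normalized.loc[pid].to_numpy()))
            if fit.converged and fit.p_lrc < 0.05:
                est.append(fit.residence_time)
                true.append(row["residence"])
        from scipy.stats import spearmanr
        rho, _ = spearmanr(true, est)
        assert len(est) >= 30 and rho >= 0.85

    def test_noise_monotonicity(self):
        """Median residence-time error shrinks as dispersion shrinks."""
        med_errors = []
        for disp in (0.4, 0.1, 0.01):
            errs = []
            for seed in range(8):
                cfg = SimulationConfig(seed=1000 + seed, n_peaks=25, noise="negbin",
                                       nb_dispersion=disp)
                sheet, counts, truth = simulate_timecourse(cfg)
                normalized, samples = normalized_counts(sheet, counts)
                times = np.array([s.time for s in samples])
                for pid, row in truth.iterrows():
                    if row["is_control"]:
                        continue
                    fit = fit_decay(DecaySeries(pid, times, normalized.loc[pid].to_numpy()))
                    if fit.converged:
                        errs.append(abs(fit.residence_time - row["residence"]) / row["residence"])
            med_errors.append(np.median(errs))
        assert med_errors[0] > med_errors[1] > med_errors[2]


class TestTracks:
    def test_zero_noise_analytic_template(self, small_noiseless):
        cfg, sheet, counts, truth = small_noiseless
        h3, netseq, transcripts, taf1 = simulate_tracks(truth, cfg)
        row = truth.iloc[0]
        s = int(row["summit"])
        vals = h3.per_bp(row["chrom"], s - 100, s + 101)
        x = np.arange(s - 100, s + 101, dtype=float)
        expected = cfg.h3_base - row["h3_depth"] * np.exp(
            -((x - s) ** 2) / (2 * row["h3_width"] ** 2)
        )
        np.testing.assert_allclose(vals, expected, rtol=1e-12)
        # NET-seq constant at the planted level over the transcript
        tx = transcripts[transcripts["gene_id"] == row["gene_id"]].iloc[0]
        net_vals = netseq.per_bp(tx["chrom"], int(tx["start"]), int(tx["end"]))
        np.testing.assert_allclose(net_vals, row["netseq_level"])

    def test_planted_effects_zeroed_is_flat(self):
        cfg = SimulationConfig(seed=3, n_peaks=16, noise="none",
                               netseq_step=0.0, taf1_step=0.0,
                               h3_width_step=0.0, h3_depth_slope=0.0)
        _, _, truth = simulate_timecourse(cfg)
        assert truth.loc[~truth["is_control"], "netseq_level"].nunique() == 1
        assert truth.loc[~truth["is_control"], "h3_width"].nunique() == 1

    def test_planted_orderings_recovered(self, small_noisy):
        """Group means follow the planted dwell-time ordering in both tracks."""
        from chipdecay.meta_profiles import MetaProfileSet, group_mean_ci, summit_centered_profile
        cfg, sheet, counts, truth, h3, netseq, transcripts, taf1 = small_noisy
        t = truth[~truth["is_control"]]
        # NET-seq per-transcript mean rises with dwell quartile
        means = []
        for q in range(4):
            sub = t[t["dwell_quartile"] == q]
            vals = [
                netseq.per_bp(r["chrom"], int(r["gene_start"]), int(r["gene_end"])).mean()
                for _, r in sub.iterrows()
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2] < means[3]
        # central H3 occupancy falls as occupancy quartile rises (anticorrelation)
        summits = list(zip(t["chrom"], t["summit"].astype(int)))
        mat = summit_centered_profile(h3, summits, flank=500, chrom_sizes=cfg.chrom_sizes())
        center = mat[:, 450:551].mean(axis=1)
        occ_means = [center[(t["occupancy_quartile"] == q).to_numpy()].mean() for q in range(4)]
        assert occ_means[0] > occ_means[3]


GFP_CDS = (
    "ATGTCTAAAGGTGAAGAATTATTCACTGGTGTTGTCCCAATTTTGGTTGAATTAGATGGT"
    "GATGTTAATGGTCACAAATTTTCTGTCTCCGGTGAAGGTGAAGGTGATGCTACTTACGGT"
    "AAATTGACCTTAAAATTTATTTGTACTACTGGTAAATTGCCAGTTCCATGGCCAACCTTA"
    "GTCACTACTTTCGGTTATGGTGTTCAATGTTTTGCTAGATACCCAGATCATATGAAACAA"
    "CATGACTTTTTCAAGTCTGCCATGCCAGAAGGTTATGTTCAAGAAAGAACTATTTTTTTC"
    "AAAGATGACGGTAACTACAAGACCAGAGCTGAAGTCAAGTTTGAAGGTGATACCTTAGTT"
    "AATAGAATCGAATTAAAAGGTATTGATTTTAAAGAAGATGGTAACATTTTAGGTCACAAA"
    "TTGGAATACAACTATAACTCTCACAATGTTTACATCATGGCTGACAAACAAAAGAATGGT"
    "ATCAAAGTTAACTTCAAAATTAGACACAACATTGAAGATGGTTCTGTTCAATTAGCTGAC"
    "CATTATCAACAAAATACTCCAATTGGTGATGGTCCAGTCTTGTTACCAGACAACCATTAC"
    "TTATCCACTCAATCTGCCTTATCCAAAGATCCAAACGAAAAGAGAGACCACATGGTCTTG"
    "TTAGAATTTGTTACTGCTGCTGGTATTACCCATGGTATGGATGAATTGTACAAATAA"
)


class TestSnpDesigner:
    def test_translation_invariant_random_cds(self):
        rng = np.random.default_rng(55)
        codons = [c for c in
                  ("GCT GCC GGT GGA TTA CTG TCT AGC ACT ACA CCT CCA GAT GAA AAA CGT "
                   "AAT CAA CAC ATT GTT TTC TAC TGT ATG TGG").split()]
        for trial in range(50):
            body = "".join(rng.choice(codons) for _ in range(rng.integers(20, 60)))
            cds = "ATG" + body + "TAA"
            variants, _ = design_synonymous_snps(cds, spacing=30, window=10)
            edited = apply_variants(cds, variants)
            assert str(Seq(edited).translate()) == str(Seq(cds).translate()), trial
            assert edited != cds or not variants

    def test_spacing_within_tolerance(self):
        variants, gaps = design_synonymous_snps(GFP_CDS, spacing=30, window=10)
        positions = [p for p, _, _ in variants]
        deltas = np.diff(positions)
        assert len(positions) >= 15
        # consecutive distances within spacing +/- window except across reported gaps
        assert ((deltas >= 20) & (deltas <= 40 + 40 * len(gaps))).all()
        assert ((deltas >= 20) & (deltas <= 40)).mean() >= 0.9

    def test_no_synonymous_moves_all_gaps(self):
        cds = "ATG" + "TGG" * 30 + "ATG" * 10  # Met/Trp only: no synonymous change exists
        variants, gaps = design_synonymous_snps(cds, spacing=30, window=10)
        assert variants == [] and len(gaps) > 0

    def test_rerun_with_existing_variants_adds_nothing(self):
        variants, gaps = design_synonymous_snps(GFP_CDS, spacing=30, window=10)
        edited = apply_variants(GFP_CDS, variants)
        again, _ = design_synonymous_snps(
            edited, spacing=30, window=10, existing_variants=[p for p, _, _ in variants]
        )
        assert again == []

    def test_invalid_cds_rejected(self):
        with pytest.raises(ValidationError):
            design_synonymous_snps("ATGAA")  # length not divisible by 3
        with pytest.raises(ValidationError):
            design_synonymous_snps("TTGAAATAA")  # no start codon


class TestUniqueness:
    def test_identical_sequences(self):
        assert uniqueness_check("ACGT" * 30, "ACGT" * 30, k=20) == 0.0

    def test_pigeonhole_k50_spacing30(self):
        variants, _ = design_synonymous_snps(GFP_CDS, spacing=30, window=10)
        edited = apply_variants(GFP_CDS, variants)
        n = len(GFP_CDS)
        last = max(p for p, _, _ in variants)
        usable = min(n, last + 50)  # tail beyond the last variant has no coverage
        assert uniqueness_check(GFP_CDS[:usable], edited[:usable], k=50) == 1.0

    def test_matches_brute_force_for_short_k(self):
        variants, _ = design_synonymous_snps(GFP_CDS, spacing=30, window=10)
        edited = apply_variants(GFP_CDS, variants)
        k = 20
        frac = uniqueness_check(GFP_CDS, edited, k)
        brute = np.mean([GFP_CDS[i:i + k] != edited[i:i + k]
                         for i in range(len(GFP_CDS) - k + 1)])
        assert frac == pytest.approx(brute)
        assert frac < 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            uniqueness_check("ACGT", "ACG", k=2)
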