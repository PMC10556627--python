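# chipdecay

Residence-time analysis of nuclear-depletion ("anchor-away") ChIP-seq time
courses: spike-in-normalized per-peak decay fitting, apparent off-rates and
dwell times, and the downstream group analyses that connect binding kinetics
to transcription and chromatin structure.

## The problem

When a DNA-binding protein is rapidly depleted from the nucleus, ChIP signal
at each of its binding sites decays toward background at that site's apparent
dissociation rate. Sequencing libraries taken along the depletion time course
differ in yield, so each sample is calibrated by reads from a
constant-abundance spike-in species before any comparison across time.
For every peak the normalized signal *y(t)* is fit to the asymptotic
exponential

```
y(t) = yf + (y0 − yf) · exp(−k_off · t)
```

where *y0* is occupancy at depletion start, *yf* the background asymptote,
and *k_off* the apparent off-rate (min⁻¹); the apparent residence time is
τ = 1/*k_off*. Peaks whose log-rate passes a Wald test (p < 0.05) form the
genome-wide set, which is then annotated to ORFs, split into dwell-time
quartiles, and interrogated with the field's standard battery: occupancy vs
dwell-time correlation, ribosomal-protein vs other rank-sum comparison,
occupancy ANOVA + Tukey HSD across quartiles, length-scaled nascent-
transcription meta-profiles, and summit-centered histone-occupancy profiles.

The package is aimed at genomics analysts working with depletion time courses
(or wanting to power/validate one): every stage is importable, the synthetic
generator produces a full experiment with known ground truth, and the whole
pipeline is exercised against that truth.

## Layout

- `src/chipdecay/` — the library: `io_formats` (BED/bedGraph/TSV with fixed
  0-based half-open coordinates), `normalization` (spike-in and median
  scaling), `decay_fitting` (the model, fitter, Wald filter), `peak_annotation`
  (windows, ORF assignment, quartiles), `meta_profiles`, `stats_tests`,
  `synthetic_data` (generator + synonymous-SNP designer), `cli_pipeline`.
- `analysis/` — numbered drivers that run the study end to end on synthetic
  data and write tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline quantities from scratch.
- A `chipdecay` CLI (`simulate`, `normalize`, `fit`, `run`, `snp-design`, ...)
  wraps the same library functions.

## Worked example

```
python analysis/01_simulate.py --seed 1        # 500 peaks + flat control
python analysis/02_fit_decay.py
python analysis/03_annotate_quartiles.py
python analysis/04_group_statistics.py
python analysis/05_meta_profiles.py
python analysis/06_snp_design.py
```

Output of the fitting and statistics steps (seed 1):

```
normalized 501 peaks x 14 samples (spike-in reference 86001 reads)
fit 501 peaks; 491 retained at Wald p(log k_off) < 0.05
recovery vs planted truth: Spearman(tau) = 0.937, median |relative k_off error| = 13.0%
retained residence times (min): median 9.28, IQR 5.44-14.16
residence-time quartiles: shortest n=123, short n=123, long n=123, longest n=122
occupancy (t=0) vs residence: Pearson r = 0.293, p = 3.47e-11
RP (n=98) vs other (n=393) residence: U = 29842, p = 3.67e-17; medians 16.2 vs 8.1 min
occupancy-track signal by quartile: one-way ANOVA F = 572.2, p = 3.56e-159
Tukey HSD: 6/6 quartile pairs differ at adjusted p < 0.05
NET-seq mean coverage by dwell-time quartile: shortest=2.20, short=3.07, long=3.98, longest=4.82
central H3 occupancy by t=0 occupancy rank: occ_q1=0.700, occ_q2=0.579, occ_q3=0.458, occ_q4=0.334
```

Reading the numbers: of 501 simulated peaks, 491 have an identifiable decay
rate; estimated dwell times track the planted ones (rank correlation 0.94,
median rate error 13% under negative-binomial count noise). The retained set
splits into four dwell-time quartiles; ribosomal-protein-target peaks dwell
about twice as long as the rest (rank-sum p ≈ 4e-17); the TFIID-proxy
occupancy signal rises across dwell-time quartiles (every Tukey pair
distinct); nascent-transcription coverage rises monotonically with dwell
time; and central histone occupancy falls monotonically with t = 0 binding —
the planted anticorrelation between occupancy and nucleosomes, recovered with
the correct sign.

The same run is available as one command from a YAML config
(`chipdecay run --config ...`); outputs are byte-identical across reruns.

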