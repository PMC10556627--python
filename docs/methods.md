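# Methods

## The measurement being modelled

In an anchor-away (rapamycin-induced nuclear depletion) ChIP-seq time course,
the free pool of a tagged DNA-binding protein is exported from the nucleus
while chromatin-bound molecules dissociate at their intrinsic off-rates and
are not replaced. The ChIP signal at a bound locus therefore decays from its
steady-state level toward a background asymptote, and the decay rate is an
apparent dissociation rate constant for that site. Because total library
yield falls as the factor is depleted, a fixed quantity of cells from a
second species (a spike-in whose chromatin is unaffected by the depletion) is
added to every sample before immunoprecipitation; reads mapping uniquely to
the spike-in genome calibrate each library's recovery.

## Decay model

Each peak's spike-in-normalized signal is fit to the asymptotic exponential

    y(t) = yf + (y0 − yf) · exp(−k_off · t),      k_off = exp(lrc)

with three free parameters: `y0`, the signal at t = 0; `yf`, the asymptote as
t → ∞ (unreleased or rebinding background); and `lrc = ln k_off`. The
apparent residence time is τ = 1/k_off (minutes). Fitting on the log of the
rate keeps the rate positive and makes the Wald test on the rate natural.

Assumptions: first-order dissociation with no rebinding of depleted factor
(a single exponential); noise independent across time points after spike-in
scaling; t = 0 anchored at rapamycin addition. Scaling the response rescales
`y0` and `yf` but leaves `lrc` and its p-value unchanged; shifting the time
axis is *not* an invariance, since `y0` is defined at t = 0.

### Fitting

Nonlinear least squares via Levenberg–Marquardt, run from two starting
points: (1) a moment-style self-start (`yf0` = min signal, `y00` = signal at
the earliest time, `lrc0` from an ordinary least-squares line through
log(y − yf0·0.99) vs t, falling back to log(1/median t) when fewer than two
points lie above `yf0` or the slope is nonnegative) and (2) a rate-profiled
start: for fixed k the model is linear in (y0, yf), so a 25-point grid of
`lrc` over [ln 10⁻³, ln 10] costs one 2×2 linear solve per point and its
argmin seeds a second run. The lower-RSS solution is kept. Convergence
tolerances are 1e−12 (xtol/ftol/gtol) with at most 600 function evaluations;
optimizer failure, a singular parameter covariance, or se(lrc) > 10⁶ sets
`converged = False` — never an exception. Exponential arguments are clipped
at ±700 to avoid overflow when a run explores very fast rates.

Standard errors come from the Jacobian-based covariance (rss/df)·(JᵀJ)⁻¹ with
df = n − 3. A fixed noisy series fit this way reproduces R's
`nls(ChIP ~ SSasymp(time, yf, y0, log_koff))` estimates, standard errors and
Wald p-values to ≥ 5 significant digits (tested).

### Filtering and reporting

The per-peak two-sided Wald test of `lrc` against 0 (t distribution, df
residual degrees of freedom) gives `p_lrc`; peaks with a converged fit and
`p_lrc < α` (default 0.05) form the retained set. An exact fit has
se(lrc) = 0; the p-value is then taken at its limit (0 for lrc ≠ 0, 1 for
lrc = 0). A model-comparison F-test against the constant model is available
as an extra column but does not drive the default filter. A negative fitted
asymptote is clamped to 0 for reporting only; the unconstrained optimum is
kept internally so RSS comparisons remain meaningful. Replicates are pooled
as independent observations into one fit per peak by default; a
per-replicate mode fits each replicate and reports the mean residence time
with its standard error.

## Normalization

*Spike-in scaling.* factor(s) = reference / spikein_reads(s) with reference =
the median spike-in count over samples. Any reference constant satisfies the
contract (factor × spike-in count equal across samples); the median keeps
normalized values on the raw-count scale and is invariant under sample
reordering.

*Median scaling for display tracks.* Coverage is divided by the bp-weighted
median of per-bp values outside a caller-supplied exclusion set (silent loci,
subtelomeres, rDNA in the original genome — the set is an input because its
enumeration is genome-specific). Intervals are weighted by their unexcluded
length; ties resolve to the lower median. The operation is idempotent when no
exclusions are given.

## Annotation and quartiles

Peak windows are summit ± 150 bp (301 bp, truncation at position 0 flagged).
A peak is assigned to the gene whose strand-aware ORF 5′ start lies within
the upstream window (default 300 bp; the wider 500-bp convention is available
by configuration): in strand-oriented coordinates the summit must fall in
[start − w, start) for + genes and (start, start + w] for − genes. Among
multiple qualifying genes the nearest start wins; ties break lexicographically
on gene id, making the assignment order-independent. Subtelomeric = summit
within 15 kb of either chromosome end. Ribosomal-protein classification uses
a packaged, user-replaceable gene-id list.

Residence-time quartiles sort ascending with stable ties on peak id and cut
at ranks ⌈n/4⌉, ⌈n/2⌉, ⌈3n/4⌉ (labels shortest / short / long / longest), so
group sizes always sum to n and labels are monotone in τ.

## Meta-profiles

Length-scaled profiles divide a transcript into equal fractional-bp bins
(default 100) in 5′→3′ orientation; each bin carries the length-weighted mean
per-bp coverage, so bin integrals conserve the transcript integral for any
length. Summit-centered profiles have one column per bp offset in
[−flank, +flank] (default 500); positions beyond chromosome ends are masked
and excluded from means, never zero-filled. Group summaries are per-bin
means with t-based confidence bands, half-width t(level, m−1)·sd/√m over the
m unmasked members (the CI construction of the displayed bands was not
specified upstream; the per-bin t-interval is the conventional choice, and a
group of size 1 is reported without a band). Transcript choice per peak:
minimal |summit − transcript 5′ end|, ties to the longer transcript.

## Statistics

Pearson and Spearman correlations use the two-sided t-approximation; zero
variance is flagged undefined rather than raised. The Mann–Whitney U test is
two-sided: exact by full enumeration of the C(n, n_a) labelings when
n_a + n_b ≤ 12 with no ties (p = probability of |U − μ| at least as extreme),
otherwise the normal approximation with tie and continuity corrections.
One-way fixed-effects ANOVA is computed from between/within sums of squares
(all-identical input gives F = 0, p = 1); Tukey's HSD adjusted p-values come
from the studentized-range distribution with pooled within-group variance,
q = |mean_i − mean_j| / sqrt(s²/2·(1/n_i + 1/n_j)). p-values are stored at
full precision; "< 2.2e−16" is a display convention only.

## Synthetic-data generator

The generator emulates the depletion experiment end to end with known ground
truth, so every stage is testable without sequencing data.

*Kinetics.* Default 500 peaks on 4 synthetic chromosomes (12-kb spacing).
Dwell times are log-normal, median 8 min, ln-scale sd 0.6; the 20% of peaks
designated ribosomal-protein targets get a 2× dwell-time boost (the
high-expression class binds longer). The median and spread were chosen so
that the 7-point sampling grid {0, 2, 4, 7.5, 15, 30, 60} min spans roughly
1–3 dwell times for nearly all sites — the same design rule an experimenter
uses when choosing time points, and the regime in which the rate is
identifiable at all. Initial occupancy `y0` is log-normal (median 80, sd
0.7) with ln-scale correlation 0.45 to dwell time (sites bound longer also
show higher steady-state occupancy, as observed in the emulated system);
`yf` is 2–30% of `y0`.

*Depth distortion and spike-in.* Every sample carries a log-normal
multiplicative depth distortion (ln-sd 0.5), normalized to median 1 across
the run; expected raw counts are distortion × model, and expected spike-in
reads are spike-fraction × depth × distortion. Spike-in scaling therefore
removes the distortion exactly in the noise-free limit — the property the
normalization contract tests. The spike-in fraction targets 5%; when count
noise is active the achieved fraction jitters log-normally (ln-sd 0.2,
representing input/IP variability) and spike-in reads are Poisson.

*Count noise.* Default negative binomial with dispersion 0.05 defined on the
linear-variance (NB1) scale, var = (1 + 0.05)·μ: window counts from a single
library per time point are Poisson-like with modest extra-Poisson inflation.
The quadratic (NB2) convention var = μ + 0.05·μ², appropriate for
biological-replicate dispersion, is available as `nb_variance="quadratic"`;
note that under NB2 the per-observation CV never falls below √0.05 ≈ 22%
regardless of depth, which caps achievable rate accuracy. Poisson and
noise-free modes are available. A constant-occupancy control peak (y0 = yf)
is included as a normalization control.

*Tracks.* H3 occupancy is a baseline of 1 minus a summit-centered Gaussian
dip whose depth rises with planted occupancy percentile (0.25 + 0.5·pct,
capped at 0.95) and whose sd widens with dwell-time quartile (60 + 30·q bp).
NET-seq coverage is constant over each assigned transcript at 2 + 1·q; a
TFIID-proxy occupancy track puts a bump of the same form over each peak
window. With noise enabled, per-bp Gaussian noise (relative sd 0.15,
truncated at 0) is added inside rendered windows; with `noise="none"` every
track equals its analytic template exactly. All randomness flows from a
single mandatory seed; identical seeds give byte-identical files.

*What the generator does not emulate.* Read-level artifacts (mappability, GC
bias, duplicates), peak-calling uncertainty (summits are exact), overlapping
transcription units, replicate-specific batch structure, and any coupling
between binding kinetics and local sequence. Passing tests demonstrate that
the estimators recover the model that generated the data at realistic noise;
they do not certify performance on violations of the single-exponential
assumption.

## SNP designer

For two identical-sequence loci to be separable by short reads, one copy is
recoded with synonymous single-base substitutions roughly every `spacing` bp
(default 30, tolerance ±10). The designer walks targets spacing apart and
places a variant at the eligible position nearest each target (positions in
codons with no synonymous single-base move — ATG, TGG — are skipped to the
nearest eligible position); targets with no eligible position in range are
reported as gaps. The alternative base is the first synonymous option in
A<C<G<T order, making output deterministic. Translation of the edited
sequence is always identical to the input (tested on random coding
sequences). Because synonymy is symmetric, a re-run on the edited sequence
would re-fire at the same codons; previously placed variants are therefore
passed as `existing_variants`, which count toward the spacing grid, and a
re-run supplied with them adds nothing where spacing is respected.
`uniqueness_check` reports the fraction of k-mer start positions at which
the two copies differ; spacing 30 guarantees 1.0 for k = 50 by pigeonhole
over the covered span.

## Pipeline determinism

Stages run normalize → fit → filter → annotate → quartile → stats →
profiles. Every output table carries a header comment with the package
version, a hash of the analysis parameters, and the seed; re-running with
identical inputs is byte-identical (timestamps appear only in the run log).
Intermediate matrices are written at full float precision (`%.17g`) and read
back with round-trip parsing so standalone stage runs reproduce the
orchestrated run exactly. No multiple-testing correction is applied to the
genome-wide filter (the per-peak p < α rule is the method's convention);
fewer than four retained peaks yields empty-but-valid downstream tables.

## Problem sizes used by the test suite and acceptance script

Zero-noise recovery uses 200 random parameter draws; noisy recovery and the
headline statistics use the default 500-peak, 2-replicate run; optimizer
dominance is checked against a 100³ brute-force grid on 20 seeded instances;
planted-structure detection uses 100 seeded 60-peak runs (40 for the
zero-effect negative control; 20 in the acceptance script); the rank-sum
null calibration uses 2,000 simulations; the end-to-end determinism fixture
has 12 peaks. These sizes give stable statistics while keeping a full run of
the suite in the low minutes on one CPU.

## Known limitations

- The single-exponential model conflates slow exchange with incomplete
  depletion; `yf` absorbs both, and sites with τ far beyond the last time
  point are reported as non-identifiable rather than extrapolated.
- The Wald filter is anti-conservative for very small residual df; the
  optional F-test column is stricter for flat series.
- Exact Mann–Whitney enumeration is limited to n ≤ 12 without ties; beyond
  that the corrected normal approximation is used.
- The designed SNPs ignore codon-usage optimality and RNA-structure effects;
  the designer guarantees protein identity, not expression neutrality.
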