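# Methods

`circaloh` re-implements, as one tested toolkit, four analysis stages used
to connect circadian-clock disruption with *Apc* loss of heterozygosity
(LOH) and patient outcome in colorectal cancer: rhythmicity scoring of
organoid bioluminescence recordings, digital-PCR copy-number estimation,
LOH detection from exome-style read depth, and a clock–Wnt covariance
stratification of an expression cohort against overall survival. Every
stage can be exercised on seeded synthetic data with planted ground truth;
this note records the models, the parameters that matter, and the design
choices that were genuinely open.

## Rhythm analysis

**Model.** A luminescence trace is modelled as baseline + linear drift +
a damped cosine, `A exp(-d t) cos(2π(t−φ)/T)`, plus Gaussian noise.
Analysis follows the standard chronobiology chain:

1. **Detrend** — OLS line subtraction by default; a centred 24 h
   moving-average baseline is available (`method="movavg"`). The
   literature rarely states the detrend operator; linear is the least
   committal and leaves a pure cosine intact over whole periods.
2. **Rank rhythm test (JTK-style)** — the detrended values are compared
   with cosine references of preset period 24 h at every candidate phase
   (step = sampling interval) via Kendall's S, counting only pairs untied
   in both vectors. The best |S| is referred to the exact permutation
   null of S — computed from the inversion-count distribution (convolution
   of discrete uniforms) for n ≤ 50, a normal approximation with variance
   n(n−1)(2n+5)/18 and continuity correction beyond — and Bonferroni
   multiplied by the number of phase alternatives. Because reference ties
   shrink the attainable |S| while the null assumes none, and because the
   Bonferroni factor over-counts correlated phase alternatives, the
   reported p is conservative: the measured false-positive rate of the
   rhythmic call on white noise is well below the nominal 0.001.
3. **FFT-NLLS fit** — period, amplitude, damping, phase and offset are
   fit by Levenberg–Marquardt least squares, initialised from the dominant
   discrete-Fourier component inside an 18–34 h band. The relative
   amplitude error (RAE) is the half-width of the amplitude's asymptotic
   95% CI divided by the amplitude; noise-only traces produce RAE > 0.5.
   If the band holds no Fourier component the fit is flagged unusable
   (period 0).
4. **Classification** — rhythmic iff p < 0.001 (strict) and
   22 h ≤ T ≤ 30 h (inclusive); failures are reported nonrhythmic with
   the first failing reason. "NR" is the sentinel in text reports, NaN in
   machine-readable output.
5. **Paired amplitudes** — tumor amplitude / matched-normal amplitude per
   patient ("amplitude" = fitted envelope at t = 0, the usual convention
   of FFT-NLLS reports); compared against a null ratio of 1 by an exact
   Wilcoxon matched-pair signed-rank test (dynamic-programming null over
   midranked |differences| for n ≤ 25; zeros dropped). Note the exact
   two-sided floor at n = 7 pairs is 2/128 ≈ 0.0156.

**Precision limit worth knowing.** For a 72 h hourly recording, the
Fisher information of the damped-cosine model puts the standard deviation
of the fitted period at ≈ 0.39 h when amplitude is twice the noise SD, so
roughly one trace in five lands outside ±0.5 h of the true period at that
signal-to-noise even with an efficient estimator. Period estimates should
be trusted to the half-hour only at amplitude-to-noise ratios of ~3 and
above, or with longer recordings.

## dPCR copy number

Template molecules distribute across ~20,000 partitions approximately
Poisson, so the positive fraction p̂ per channel inverts to a mean load
λ = −ln(1 − p̂) (copies/partition); the 95% CI is the Wilson interval on
p̂ pushed through the same monotone transform. Copy number is
`ref_copies · λ_target / λ_reference` with a first-order delta-method CI;
the reference locus is assumed autosomal and stable at 2 copies. Discrete
states use conventional thresholds (< 0.3 homozygous loss, < 1.5
heterozygous loss, ≤ 2.5 diploid, else gain; CI wider than 1 copy →
indeterminate); all are overridable, as the underlying experiments report
states only qualitatively ("proximal to" 0/1/2). A saturated channel
(every partition positive) is an error, not an estimate.

## LOH from read depth

Inputs are integer counts over tiled intervals (BED, 0-based half-open;
200 bp tiles by default) for replicate samples in two groups. Counts are
assumed pre-filtered upstream (MAPQ ≥ 20, pair distance ≤ 1000 bp) — the
module treats that as a contract on its input rather than re-parsing
alignments. The chain:

1. **Library-size normalisation** to the largest sample's total. When a
   real deletion is present this compensation biases the within-segment
   log2 fold change toward zero (a 40-tile full deletion in a 200-tile
   panel shifts −1 to ≈ −0.85) — a known property of total-count
   normalisation, visible in the tests.
2. **Quantification**: log2((count + 1) / length_kb).
3. **Moderated t** per interval (late − early): the pooled interval
   variance s² (d residual df) is shrunk toward an empirical-Bayes prior,
   s̃² = (d₀s₀² + d s²)/(d₀ + d), and the statistic referred to t on
   d₀ + d df. The prior (d₀, s₀²) is fit by matching the first two
   moments of log s² — Var(log s²) = ψ′(d/2) + ψ′(d₀/2) identifies d₀ by
   trigamma inversion, the mean identifies s₀². d₀ = 0 reproduces the
   ordinary pooled t exactly; d₀ = ∞ a fixed-variance z statistic; the
   measured null false-positive rate at p < 0.01 sits on the nominal rate.
4. **Segment calling**: maximal runs of ≥ 3 consecutive intervals with
   log2FC ≤ −1 (overridable; −0.5 suits a single-copy loss given the
   normalisation bias above) and p < 0.01. Runs may bridge one
   non-qualifying interval (`max_gap=1`) so a single noisy tile does not
   split a real deletion; a segment never starts or ends on a bridged
   tile. Null tracks produce no segments in ≥95% of simulations.

## Clock–Wnt covariance and survival

The cohort analysis mirrors a TCGA-style workflow: genes kept when
expressed (> 0) in strictly more than half the samples; tumor vs normal
decided by the trailing two-digit barcode code (01–09 tumor, 10–19
normal); per-gene two-sided Welch t tests flag clock-gene shifts at
p < 0.001. Correlation structure uses the **biweight midcorrelation**
(Tukey biweights around medians, unscaled MAD with the 9·MAD tuning
constant, Pearson fallback at MAD = 0) with p-values from the
t-approximation on n−2 df. Clock×Wnt pairs significant at p < 0.001
define a gene union; PCA of the standardised union over tumor samples
yields per-individual contributions 100·score²ᵢₖ/Σscore²ⱼₖ to the chosen
component (deciles recorded for transparency); a median split of
|contribution| assigns "high" vs "low" covariance (odd n → extra
individual to "low"; ties broken by stable sample-id order); the groups
are compared by Kaplan-Meier curves and a two-group log-rank test
(backed by `lifelines`, cross-checked in the tests against hand-computed
product-limit and hypergeometric-moment sums).

Open choices resolved here: the driving component defaults to PC1
(configurable, as the source workflow does not name it); the correlation
screen runs on tumor samples by default (`corr_samples="normal"`
available) — with a latent covariance level that varies between patients,
the tumor cohort itself carries the correlation signal; genes are
standardised before PCA so contributions are not dominated by
high-variance genes; samples without survival records are dropped before
scoring (logged), mirroring cohorts whose stratified n falls short of the
full tumor count.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their config (seed included).

- **Traces**: damped cosine + drift + i.i.d. Gaussian noise. Defaults:
  72 h hourly sampling, T = 24 h, A = 3, damping 0.01/h, noise SD 0.5.
  Conditions: `tumor` blunts amplitude ×0.2 (matching the qualitative
  normal-vs-tumor contrast), `arrhythmic` sets A = 0, `abnormal_period`
  draws T from [16, 20] ∪ [32, 36] h. Not emulated: non-Gaussian photon
  noise, amplitude-dependent noise, desynchronisation between cells.
- **dPCR plates**: per-channel Binomial(n, 1−e^−λ) occupancy with
  λ_target = λ_ref·CNV/2, λ_ref = 0.5, n = 20,000. Not emulated: rain
  (intermediate-intensity partitions), volume variation, cross-talk.
- **Cohort**: genes × samples log2-like matrix; clock and Wnt genes load
  (loadings U(0.7, 1.3)) on one shared Gaussian factor — present in all
  normals with strength `covariance_strength`, and in tumors only for
  patients whose latent binary covariance level is high. Survival is
  exponential with hazard `baseline_hazard · hazard_ratio^(1−level)`;
  censoring marks a `censor_rate` fraction, with censoring times uniform
  on (0, event time). Defaults mirror the cohort scale the analysis
  targets: 470 tumors, 57 matched normals (barcodes `-01`/`-11`), 12
  core clock genes (canonical symbols), 20 Wnt genes and 200 background
  genes as desk-scale stand-ins for GO:0016055 and the transcriptome;
  baseline hazard 10⁻³/day (median survival ≈ 2 years), noise SD 1,
  strength 0.8, hazard ratio 2.5, censoring 0.3. Not emulated:
  count-level noise, batch effects, continuous covariance levels,
  competing risks — so passing tests demonstrate recoverability of the
  planted low-rank structure, not robustness to real RNA-seq artefacts.
- **Depth tracks**: negative binomial with variance μ + μ²/dispersion
  (dispersion=None → Poisson). Defaults: 200 × 200 bp tiles, depth 100,
  dispersion 40 (CV ≈ 0.19, typical of exome tile counts across
  biological replicates), 4 early vs 4 late replicates, deletion planted
  at tiles [40, 80) with fold 0.5 (0 = complete loss, producing exact
  zeros). Not emulated: GC/mappability waves, correlated noise along the
  genome, subclonal mixtures.

## Problem sizes and numerics

Simulation-based checks run at: 100 plates per dPCR genotype; 1000
white-noise traces (48 h) for the rhythm false-positive rate and 100
seeds (72 h) for recovery; 50 cohorts × 300 tumors per survival arm; 100
depth panels of 200 tiles plus one 2000-tile null panel for calibration —
sizes at which every binomial acceptance band is informative while the
whole suite runs in well under an hour on one core. Numerical choices:
NLLS convergence at xtol/ftol 1e-12 with ≤ 2500 function evaluations;
amplitude sign normalised into phase; exact nulls switch to normal
approximations at n > 50 (Kendall) and n > 25 (Wilcoxon); correlation
p-values are floored at the smallest positive float rather than 0;
zero-variance genes yield p = 1 by convention; all tabular output TSV
with "NA" for missing values.

## Known limitations

- The JTK p-value is conservative under reference ties and Bonferroni;
  it is a gatekeeper, not an unbiased tail probability.
- Period precision at low SNR is bounded by the Fisher information (see
  above); the toolkit reports RAE but does not propagate period
  uncertainty into the rhythmic call.
- Total-count depth normalisation biases fold changes when large
  aberrations are present; median or control-region normalisation would
  be preferable for panels dominated by CNAs.
- The covariance score uses a single principal component; signal split
  across components is not pooled.
- The moderated-t model assumes approximately Gaussian log-scale values;
  heavy overdispersion at very low counts is not specially handled.
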