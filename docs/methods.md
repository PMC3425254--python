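# Methods

This note documents the models implemented in `cnvlrr`, the conventions
chosen where the underlying procedures are not fully published, and what
the synthetic data do and do not emulate.

## Signal model

Each probe reads two allele-specific fluorescence channels X (A allele) and
Y (B allele). For a sample carrying `c` copies of the locus, `b` of them
B alleles, at a probe with diploid full intensity `F` and background
fraction `f`, the noiseless channels are

```
X0 = F * ((c - b)/2 + f/2)        Y0 = F * (b/2 + f/2)
```

so the noiseless total is `R0 = F * (c/2 + f)`. The default
`f = 0.095` is solved from `log2(f / (1+f)) = -3.53`, making the
reference-normalized LRR of a 0-copy sample coincide with the 0-copy HMM
state mean; this is what makes reference-mode calling well-posed.

Noise has two components with distinct roles:

* **Differential (channel-transfer) noise** `delta ~ N(0, 0.04 * F)`,
  applied as `X = X0 + delta`, `Y = Y0 - delta`, with `delta` clipped so
  both channels stay nonnegative. It conserves R exactly and models
  fluctuating allocation of fluorescence between the two channels. Where
  true allele signal exists (c >= 1) it only jitters theta slightly; at
  zero copies both channels read comparable nonspecific background, so the
  polar angle — and hence the BAF — of null samples is scrambled across
  [0, 1]. The default 0.04 keeps the BAF drift of a clean diploid sample at
  ~0.0014, below the 0.002 exclusion threshold, while still spreading null
  BAF over the full unit interval.
* **Common-mode intensity noise**, a multiplicative factor `2**g` with
  `g ~ N(0, lrr_noise_sd)` on both channels. This is the noise that
  per-probe LRR standard deviations measure; the default is 0.05 for
  calling fixtures and 0.10 for the association/concordance fixtures,
  within the range of published per-probe LRR SDs at such loci (~0.11-0.28,
  which mix class separation with noise).

Raw fluorescence noise for this platform is not published; the
decomposition above is calibrated to the two signal properties that are
documented — near-uniform null-sample BAF, and per-probe LRR dispersion —
rather than to channel-level statistics. A purely additive channel noise of
comparable size would make the 0-copy total intensity (mean 0.095 F) so
noisy on the log scale that no normalization could keep null LRR compressed,
which contradicts the observed behaviour of real cohort-normalized data.

### Signal regimes

* **raw** (default): intensities follow the copy-number signal model above.
  Used for all calling experiments.
* **compressed**: locus-probe totals are drawn as `R = F(1+f) * 2**L` with
  `L ~ N(m_c, lrr_noise_sd)` and class means `m = (-0.10, +0.08, +0.17)`
  for 0/1/2 copies — the compressed, ordered residual that survives a
  cohort-based vendor normalization at a common deletion (the vendor
  pipeline's normalization internals are proprietary, so its *output*
  distribution is emulated instead of its mechanism). Null-sample theta is
  scrambled as in the raw regime. Used for the two-class association and
  concordance fixtures, where the question is what the downstream summary
  and mixture model recover from such a signal.

## Cohort

The default cohort mirrors a hospital-based case-control design: 773 cases
and 759 controls drawn retrospectively from a large simulated source
population (fixed margins, genotype distribution within each arm following
from the disease model). Genotype classes for 0/1/2 copies default to
(52.96%, 38.10%, 8.94%); the deletion is a single locus-wide event shared
by all 5 locus probes. Covariates are fixture conventions, not claims about
any real population: gender Bernoulli(0.87 male), age N(66, 10) truncated
to [21, 80], region uniform over 5 labels, smoking (0.3/0.3/0.4); their
disease effects default to 0, so adjustment machinery is exercised without
built-in confounding. The disease model is logistic:
`logit P(case) = intercept + beta*g (+ covariate terms)` with `g` either
the copy number (trend mode, default `beta = ln 0.74` per copy) or a
carrier indicator (two-class mode, `beta = ln 0.66`).

The panel has 5 locus probes at their published 1p13.3 coordinates plus
2000 diploid background probes at 10 kb spacing flanking the locus.
B-allele frequency defaults to 0.5 at all probes (maximal heterozygosity,
the hardest case for cluster models).

## Normalization

`theta = (2/pi) * arctan(Y/X)` (0.5 when both channels are 0), `R = X + Y`.

**Reference mode** bins a panel of known two-copy samples at theta 1/3 and
2/3 into AA/AB/BB candidate clusters (clusters with fewer than 3 members
are dropped), takes each cluster's median theta and median R, and
interpolates `R_exp` linearly in theta between cluster centers with
constant extrapolation beyond the outermost ones. This yields LRR ~ 0 for
diploid samples and ~ -3.53 for null samples.

**Cohort mode** emulates processing in which the clusters come from the
analysis cohort itself. Total intensity is clustered on the log2 scale
(1-D k-means, k <= 3) over all samples, and each sample's expected
intensity is the posterior-weighted mean of the component medians,

```
R_exp(R) = sum_k w_k(R) * median_k,
w_k(R) ∝ weight_k * exp( -(log2 R - log2 median_k)^2 / (2 s^2) ),
```

with a fixed log2-scale softness `s = 1.0`. Because component weights enter
the posterior, a majority null class drags every sample's `R_exp` toward
the deleted intensity cloud: at the default locus composition this
compresses the locus LRR class means to roughly (-0.17, +0.03, +0.87) for
0/1/2 copies — ordered and sign-correct but collapsed from the reference-
mode spread of (-3.53, -0.88, 0). The minority two-copy class retains the
largest residual (its clusters are the most contaminated *relative to its
own intensity*), which is why its mean sits near +0.9 rather than 0; the
deletion classes stay within (-1, 1), far above anything the HMM would call.
The softness value is the one free parameter: smaller values collapse the
null/het ordering margin (~0.015 at s = 0.8), larger ones push null LRR
toward deletion territory; 1.0 keeps both effects controlled.

BAF in both modes interpolates theta piecewise-linearly through the cluster
centers mapped to the canonical positions 0 / 0.5 / 1 (clipped to [0, 1];
no special-casing of 0-copy samples — their scrambled theta naturally
yields spread-out BAF). Zero-intensity cells receive an LRR floor of -10
and are flagged.

## Sample QC

Four per-sample summaries with the standard exclusion thresholds: LRR SD
(sample SD over all probes, > 0.28 fails), BAF median (over probes with BAF
in (0.25, 0.75), outside [0.45, 0.55] fails — the statistic targets the
heterozygote band center, which a median over all probes, dominated by 0/1
values, would not), BAF drift (mean squared distance to the nearest of
{0, 0.5, 1}, > 0.002 fails; called CNV regions are not excluded, avoiding
circularity with calling), and wave factor (SD, ddof 0, of mean LRR over
non-overlapping 50-probe windows, outside [-0.04, 0.04] fails). The drift
and wave statistics have no published closed form; these are declared
conventions, with the thresholds kept at their published values. A sample
fails if any criterion is violated; all violated criteria are reported.

## Copy-number HMM

Five states (0-4 copies). Emissions: LRR ~ Normal with state means
(-3.53, -0.66, 0, 0.40, 0.68) and SDs (1.0, 0.30, 0.18, 0.22, 0.24) — only
the means are published; the SDs are chosen so the state bands do not
overlap at the means and are tunable. BAF: state 0 is uniform on [0, 1]
(no allelic information without DNA); states 1-4 are equal-weight mixtures
of Gaussian bands (SD 0.04, truncated and renormalized on [0, 1]) at the
canonical allelic-ratio positions of the state. Transitions are sticky and
distance-independent (stay 0.9996, off-diagonal mass split equally) — a
single locus is analyzed, so distance-dependent transition modelling adds
nothing. Initial distribution (0.01, 0.02, 0.94, 0.02, 0.01) favors
diploid. Viterbi ties break toward the state closest to diploid (preference
2, 3, 1, 4, 0), making the caller conservative. Deletion calls are maximal
constant runs of states {0, 1} of at least 3 probes (the 5-probe locus
clears this); a cohort-level locus count is the number of samples with a
call overlapping any locus probe.

With cohort-mode normalization the locus LRR of deletion carriers sits
within ~±0.4 of 0 while a switch away from the diploid state costs ~18.4
log units of transition penalty against at most ~2 log units of emission
gain per probe — the zero-call failure is therefore structural, not a
sampling accident, and holds across seeds.

## Association

* **Per-probe LRR tests**: logistic regression of disease on the LRR at
  each locus probe, adjusted for gender, continuous age, region and
  smoking. OR per unit LRR; constant predictors are rejected.
* **Trend test**: logistic regression with (called or true) copy number as
  a linear per-copy term, same adjustment.
* **Signal summary**: first principal component of the standardized locus
  LRR matrix (sign fixed positive against mean LRR), provisional classes
  from a 1-D Gaussian mixture of the scores, then the first Fisher
  discriminant for those classes applied to the probe matrix (fallback to
  the PC score if classes degenerate or the within-class scatter is
  singular).
* **Joint latent-class mixture**: the summary is a K-component Gaussian
  mixture (component-specific variances; labels resolved by sorting on
  means). Null model: mixing shared by cases and controls, disease depends
  only on covariates. Alternative: membership in any component other than
  the lowest-mean one (carrier) shifts the disease log-odds by `beta`.
  Both fitted by EM (deterministic quantile-spread restarts, tolerance
  1e-8 on the log-likelihood, max 500 iterations; the M-step disease
  update is a fractionally weighted IRLS). LRT = 2(ll_alt - ll_null) on
  chi-square(1); OR = exp(beta) with a Wald CI from the final weighted
  logistic fit (this CI conditions on the posterior weights and slightly
  understates classification uncertainty — the LRT p-value is the primary
  inference). K defaults to 2 (null vs carrier, matching a two-category
  clustering of such a locus); BIC for K in {2, 3} is reported by the
  pipeline. Age enters the mixture model in quartile classes — the latent-
  class framework admits only categorical adjustment — but continuously in
  the regression tests.
* **Concordance**: fraction of samples whose maximum-posterior component
  (lowest-mean component ≡ homozygous-null) matches true null status.

Logistic fits use an in-package IRLS solver (convergence 1e-8, 50
iterations, fits with any |coefficient| > 15 flagged as quasi-separated);
no multiple-testing adjustment is applied across the 5 probes — raw
p-values are reported, with the count of probes below 0.05 available as a
descriptive excess-of-signal summary.

## Numerical conventions

Master seeds derive stage seeds through `numpy.random.SeedSequence`
spawning, so stages are reproducible standalone and whole runs are
bit-identical under a fixed configuration. All tables are tab-separated
with header lines; intensities round-trip through text at 6 significant
digits. k-means is quantile-seeded Lloyd iteration (deterministic); empty
components are dropped. Mixture SDs are floored at 1e-3 of the data scale
to prevent component collapse.

## Problem sizes

The default fixture is 1532 samples x 2005 probes; a full two-mode pipeline
run takes ~20 s on one CPU. Replicate studies (trend-OR bias over 200
cohorts, mixture power over 100, the 2000-replicate null calibration of the
per-probe test) trim the background panel to 20-40 probes, since locus
calling and association are unaffected by background beyond flanking
context for the HMM; the acceptance script likewise averages a handful of
full-sized replicates per quantity so that single-cohort sampling error
does not dominate the reported estimates.

## What the simulation does and does not emulate

Emulated: the genotype-class structure of a common full-gene deletion, the
cluster-contamination mechanism that compresses cohort-normalized LRR and
scrambles null BAF, retrospective case-control sampling, covariate
adjustment asymmetries, and the published effect-size regime (protective
per-copy OR ~0.74; carrier OR ~0.66). Not emulated: linkage disequilibrium
and breakpoint variation (the deletion is one locus-wide event), segmental-
duplication cross-hybridization, multi-allelic CNV (>2 copies), plate and
batch effects, GC waves (the wave factor is measured, not corrected), and
the proprietary vendor normalization itself — the compressed regime
reproduces its output statistics, not its algorithm. Consequently, passing
tests show that the *methods* behave as described on signal with these
statistical properties; they are not a validation against real array data.

## Known limitations

The cohort-mode cluster model is a deliberately transparent stand-in for
proprietary cohort-based processing; it reproduces the qualitative
compression (ordering, sign, zero-call failure) but not exact published
LRR class means. The mixture CI is Wald-conditional as noted above. The
HMM omits distance-dependent transitions and family-based joint calling,
and duplication states 3-4, while implemented, are not exercised by the
fixtures.
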