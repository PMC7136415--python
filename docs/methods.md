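# Methods

## Model

Behavior is a binary sequence S[0..N) at fixed bins (10 s by default):
`A` if the bin's activity count is positive, `R` otherwise. Intensity of
activity is deliberately discarded — the object of study is the *duration*
of rest and activity. The model is a first-order, phase-inhomogeneous
two-state Markov chain: the state of bin n+1 depends only on the state of
bin n and the circadian phase label of bin n,

    α(X) = P(S[n+1]=A | S[n]=R, phase[n]=X),
    β(X) = P(S[n+1]=R | S[n]=A, phase[n]=X),   X ∈ {DAY, NIGHT}.

Within a phase the chain is homogeneous; each animal in each condition
therefore contributes four probabilities. The maximum-likelihood estimator
is the transition-count ratio α̂(X) = n_RA(X)/(n_RA(X)+n_RR(X)) and
symmetrically for β̂. Binomial standard errors accompany the estimates.

Consequences used throughout:

* dwell times (bout lengths) are geometric: P(L=k) = (1−p)^(k−1)·p with
  exit probability p (α for rest, β for activity); the mean bout is 1/p
  bins, i.e. `bin_seconds/(60·p)` minutes;
* the stationary fraction of time active within a phase is α/(α+β);
* rest and activity bouts strictly alternate, so their counts in any
  contiguous interval differ by at most one — only the total is reported.

## Conventions and edge cases

* **Bin-n attribution.** A transition between bins n and n+1 is attributed
  to the phase of bin n, the conditioning variable in the estimator. This
  affects only the two boundary pairs per cycle.
* **Gaps.** Missing stretches of recording are kept as break markers.
  No transition, state triple, or bout ever spans a break; estimates are
  therefore unbiased by missingness (at the cost of a few lost pairs).
* **Truncated bouts.** Bouts touching a record edge or a gap have censored
  lengths. They are counted in transition estimation (which is pair-based
  and unaffected) but excluded from empirical bout-length histograms by
  default.
* **Degenerate phases.** A phase with no qualifying transitions yields NaN
  with an `EstimationWarning`, never a silent zero.

## Phase labeling

Under LD, phase is the light flag (DAY = lights on). Under DD, subjective
phase is inferred from the raw counts by cosinor fitting: for each
candidate period T on a grid (20–28 h in 0.1-h steps, bracketing murine
free-running periods) the model mean + a·cos(2πt/T) + b·sin(2πt/T) is fit
by exact linear least squares, and the T maximizing variance explained is
selected — convex per period and fully reproducible, with no nonlinear
optimization. Subjective NIGHT is the half-period window centered on the
acrophase, tiled periodically: the nocturnal convention that the activity
peak lies in subjective night. Records shorter than four cycles of the
longest candidate period are refused (the cohort inclusion rule), as are
constant or all-zero records (degenerate fits). Labels are invariant to
uniform scaling of the counts.

## Synthetic cohorts

The generator is first-class: it produces cohorts with the statistical
structure the analysis assumes, standing in for recordings that are not
publicly available.

* **Cohort means.** Per-phase (α, β) are derived from the reference
  bout-length table via p = bin/(60·mean): LD day 4.50/0.54 min
  (rest/activity), LD night 1.75/0.75; DD subjective day 4.05/0.55,
  subjective night 2.68/0.67. The LD values are pooled across T-cycles, so
  all three T-cycle cohorts share them.
* **Composition.** The study-like cohort is 8/16/8 animals at T = 22/24/26 h
  plus 16 in DD, each recorded for `record_days` 24-h days (default 7,
  satisfying the ≥ 4-cycle inclusion rule for every condition).
* **Heterogeneity.** Per-animal α and β are drawn independently lognormal
  around the cohort means with coefficient of variation 0.2 — a knob
  chosen to visually match reported per-animal scatter, not a fitted
  quantity. Draws are parameterized to preserve the arithmetic mean.
* **Entrainment screening.** LD animals in the study were verified to be
  entrained before inclusion. The generator mirrors this: an LD draw whose
  implied day/night average-activity ratio is ≥ 0.6 (day not clearly less
  active than night) is rejected and redrawn. The bound is lenient —
  reported cohort ratios are ~0.35–0.40 with intervals up to ~0.47 — and
  rejects ~3% of draws; DD animals are never screened.
* **Phase tracks.** LD: equal light/dark halves at T, lights-on first.
  DD: subjective phase tiled at a per-animal free-running period drawn
  normal (23.8 ± 0.15 h), near but distinct from 24 h.
* **Initial state.** Stationary by default (P(A) = α/(α+β) of the first
  bin's phase) to avoid burn-in transients, matching the stationarity
  assumption of the model.
* **Determinism.** Everything derives from a single `SeedSequence`;
  identical configs give bit-identical cohorts.

What the generator does *not* emulate: activity intensities (counts beyond
0/1), light-masking dynamics beyond phase-switched parameters,
non-geometric rest-bout tails (real data show excess very short and very
long rest bouts), and within-phase inhomogeneity. Tests that pass on
synthetic cohorts therefore validate the estimator and the pipeline, not
these departures in real data.

## Diagnostics

* **Split-half stability.** The record is split at its midpoint bin (the
  simplest reproducible rule) and the model is fit to each half
  independently; across a cohort the two halves' estimates are correlated
  per parameter, pooling animals and phases.
* **Markov-order check.** The plug-in conditional mutual information
  I(S[n+1]; S[n−1] | S[n]) in bits, from empirical triple frequencies
  (zero-count cells contribute zero; no bias correction). First-order
  sequences give values near zero — the plug-in bias is ~df/(2N·ln2) ≈
  1.4×10⁻⁶ bits at 10⁶ bins, and the package's own simulations measure
  < 10⁻³ bits there. A deterministic R,R,A pattern gives exactly 2/3 bits
  (past and future perfectly coupled given a middle R, weighted by
  P(R) = 2/3), a closed-form anchor for the estimator.
* **Bout-distribution comparison.** Observed normalized histograms of
  non-truncated bout lengths per phase × state, against the geometric pmf
  at the fitted exit probability, with the predicted tail mass beyond the
  longest observed bout; summarized by total-variation distance.

## Rhythm screens

The Enright (χ²) periodogram folds the series into K complete rows of P
columns (partial final row discarded) and refers

    Q_P = K·N'·Σ_h (M_h − M̄)² / Σ_i (x_i − M̄)²,   N' = K·P,

to the χ² distribution with P−1 degrees of freedom. Q is invariant to
affine transforms of the series, so binary states and raw counts give the
same statistic whenever encoding is affine.

The χ² calibration assumes the folded values are serially uncorrelated
under the null. Encoded behavior at 10-s bins is strongly autocorrelated —
the mean bout spans several bins, giving lag-1 correlation ≈ 1−α−β ≈ 0.7 —
which fattens the upper tail of Q (the statistic is a quadratic form whose
eigenvalues follow the AR(1) spectrum, up to (1+ρ)/(1−ρ) ≈ 4.7) and
manufactures spurious "rhythms" at native resolution (~2 per 7-day null
animal in our measurements). The screens therefore aggregate to bins
coarse relative to the bout length before testing, the long-standing
practice for this periodogram:

* **Ultradian screen**: 1-min bins, every integer bin period from 2 to
  120 min. With this aggregation the screen is calibrated (zero hits on
  matched null simulations).
* **Circadian screen**: 6-min bins, periods 20–28 h in 6-min steps; the
  22/24/26-h T-cycle periods fall exactly on the grid.

Significance uses a Bonferroni correction. For the ultradian screen the
default family is the whole screen — all tested periods across all
animals — controlling the probability of *any* spurious cohort-level
"ultradian rhythm" at 0.05; per-animal correction is available
(`family="animal"`), but with ~48 animals a per-animal family-wise level
of 0.05 would yield a false alarm somewhere in the cohort about half the
time even under perfect calibration. The raw `chi2_periodogram` accepts
any series and grid, including the native 10-s resolution.

## Cohort statistics

Per-animal quantities (mean bout lengths, average activity, total bouts)
are aggregated multiplicatively: cohort point estimates are geometric
means (log-scale means back-transformed — the variance-stabilizing choice
for fold-change estimands), day/night contrasts are within-animal ratios,
and 95% confidence intervals come from a seeded animal-level
nonparametric bootstrap (2000 resamples, percentile method). LD/DD
contrasts are ratios of day/night folds with both groups resampled
independently. This preserves the estimands of the original design —
paired fold changes with uncertainty — while remaining self-contained;
the intervals are comparable to, not identical with, mixed-model
intervals.

## Problem sizes and tolerances in the test suite

Statistical tests run at fixed seeds chosen a priori. Long-run estimator
checks use 10⁵–10⁶ bins (relative errors < 1–2%); the generate-and-refit
recovery checks use one-week cohorts of 16 animals and accept 5% on
cohort geometric means, which estimation error (~1%) dominates only
because fits are compared with each animal's own realized parameters —
comparing a 16-animal cohort mean with the *nominal* generating value
would confound estimator quality with ~5% sampling noise of the
heterogeneity draw itself. The rhythm-screen checks run on a 48-animal
synthetic study (one week per animal).

## Known limitations

* The geometric law understates heavy rest-bout tails seen in real data;
  the diagnostics quantify, but the model does not capture, that excess.
* Cosinor phase assignment assumes a single stable free-running rhythm;
  split or fragmented rhythms are out of scope.
* The periodogram screens assume gap-free records (folding has no notion
  of missing time); simulated cohorts satisfy this.
* CMI thresholds ("close to zero") are calibrated per record length by
  simulation, not by an analytic null distribution.
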