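# Methods

## Impulse–momentum jump analysis

A jumper of mass *m* on a force plate obeys m·a(t) = F(t) − m·g, where F is
the vertical ground reaction force. With the jumper at rest when recording
starts, integrating the net force once gives COM velocity and twice gives
displacement; every quantity the package reports derives from this.

**Body weight.** Mean and sample SD of F over the first 0.5 s of quiet
standing (500 samples at the nominal 1000 Hz). The window is specified in
seconds so behaviour is invariant to sampling rate. Mass is weight/g with
g = 9.81 m/s² throughout.

**Movement onset.** The first sample after the body-weight window with
|F − W| > 5·SD, backed off by 30 ms (clamped at zero). The threshold is
two-sided because a CMJ first unweights (force drops) while an SJ pushes
(force rises). On noiseless synthetic traces the resting SD is zero and the
threshold would be degenerate, so a 0.5 N floor is applied to the SD before
multiplying; on real plate noise (a few N) the floor is inert. Disabling
the floor on a zero-SD trace raises a configuration error rather than
returning a meaningless onset.

**Take-off and landing.** First sample after onset with F < 20 N, and first
sample after take-off with F > 20 N, both on the raw force (the optional
low-pass filter, off by default, affects only the kinematic integration).

**Kinematics.** a = (F − W)/m over [onset, take-off]; v and s by cumulative
trapezoidal integration with v(onset) = s(onset) = 0; power P = F·v
(signed: negative during unweighting).

**Phases.** CMJ: weighting [0, A), unweighting [A, C), braking [C, D),
propulsion [D, F), flight [F, landing), landing onward, with A = onset,
C = the velocity minimum, D = the first non-negative velocity after C and
F = take-off. At a velocity extremum the acceleration is zero, so the
velocity minimum is also where force crosses back through body weight; the
force-crossing index is recorded separately (`events.bw_return`) and the
two coincide within ±2 samples on clean data, but the velocity minimum is
used as the phase boundary because it keeps the segmentation contiguous
when noise separates the two by a sample. SJ: weighting, propulsion,
flight, landing. A trial labelled CMJ whose velocity never goes negative is
rejected with a hint to analyze it as an SJ.

**Metrics** are evaluated on the movement interval I = [onset, take-off):
peak power max P; mean power ∫P dt / |I| (the signed braking-phase power is
included for the CMJ, which is why CMJ mean power is an order of magnitude
below peak power while SJ mean power is not); relative net impulse
∫(F − W)dt / m; jump height v²_TO/2g; peak kinetic energy ½·m·v²_peak. Two
identities tie the chain together and are asserted in tests: relative net
impulse equals take-off velocity exactly (both are ∫(F/m − g)dt from rest),
and jump height from v_TO agrees with g·t²_flight/8 from the flight time.

**Best trial.** Among repeated trials of one participant and jump type, the
trial with the greatest jump height is kept (ties: earliest trial).

## Synthetic trials

The simulator prescribes COM acceleration as raised-cosine (Hann) lobes:
an unweighting lobe of amplitude −A₁ (CMJ only), a push lobe of amplitude
+A₂ spanning braking + propulsion, then a 2 ms half-cosine force release
from body weight to zero at take-off, ballistic flight at exactly 0 N for
2·v_TO/g, a 50 ms half-sine landing pulse sized to absorb the landing
momentum, and quiet standing at each end. Hann lobes integrate to A·T/2 and
join with zero slope, so the waveform is C¹ and the push amplitude that
delivers the requested take-off velocity is available in closed form
(A₂ = 2(v_TO + v_un + g·T_rel/2)/T_push). The unweighting amplitude is
calibrated by a scalar root-solve so the rendered countermovement depth
matches the requested depth. Defaults (70 kg, v_TO = 2.8 m/s CMJ /
2.45 m/s SJ, 0.25 m depth, 0.35/0.18/0.27 s unweighting/braking/propulsion,
5 s quiet standing before and after, 1000 Hz, 3 N contact noise) emulate a
trained adult on a laboratory plate: peak force ≈ 2.6 BW, unweighting
trough ≈ 0.5 BW, SJ mean power ≈ 1.4 kW.

Two deliberate conventions:

- **Short take-off release (2 ms).** The release is the only interval where
  velocity falls between its peak and take-off (Δv = g·T_rel/2); keeping it
  to two samples keeps the peak velocity within a couple of samples of
  take-off and PKE within 1% of m·g·JH, which the test suite relies on.
  Real plates show a longer (~tens of ms) roll-off; robustness to that is
  not what the synthetic suite tests.
- **Operational ground-truth onset.** The thresholded onset rule fires
  during the gentle start of a smooth lobe and its 30 ms back-off then
  lands slightly *before* the prescribed movement start, inside the
  zero-power quiet stand. Ground truth therefore records the onset the
  rule defines — evaluated exactly on the continuous noiseless profile with
  the analyzer's noiseless threshold (2.5 N) — and evaluates mean power
  over [that onset, take-off]. Peak power, impulse, jump height and PKE are
  insensitive to the interval start. This makes "analyzer output vs ground
  truth" a test of the numerical chain, not of an unreachable latent
  instant.

Noise is zero-mean Gaussian on ground-contact samples only; flight samples
stay at exactly 0 N so the 20 N take-off rule is exercised as on a real
plate (a `flight_noise` flag adds it everywhere for robustness tests).
Identical spec + seed gives bit-identical recordings.

What the simulator does **not** emulate: drift and low-frequency plate
noise, filtering artefacts, bilateral asymmetry, arm-swing or technique
variations, and non-idealized landings. Passing the synthetic suite shows
the detection/integration/statistics chain is correct under the stated
waveform family, not that it is robust to every hardware pathology.

Cohorts (`simulate_cohort`) draw each metric independently from a normal
distribution truncated at zero (defaults: PKE ~ N(315.7, 113.1²) J, n = 13)
and set measured 1RM = 0.352·PKE + 12.775 + N(0, 13.27²) kg, i.e. a
population R² of 0.90 around the published line. No cross-metric
correlation structure is imposed; tests that need collinear predictors
construct them explicitly.

## Strength model

The published equations are fixed constants; refitting never overwrites
them. `OneRMRegressor` first removes, from any pair of candidates with
|r| > 0.9, the one less correlated with measured 1RM, then runs forward
stepwise selection with partial-F entry at α = 0.05 and removal at
α = 0.10 (the conventional defaults; the selection criteria are otherwise
an open choice). OLS fits come from statsmodels. Adjusted
R² = 1 − (1−R²)(n−1)/(n−k−1); SEE uses the N−2 denominator. Fits require
n ≥ 8. When nothing enters, the regressor degrades to predicting the mean
("no model") rather than erroring, so pipelines can report the outcome.

The reported "mean error as % of mean measured 1RM" is ambiguous between a
mean-absolute-error and an SEE-based reading; `mean_error_percent`
implements MAE as the default (the SEE-relative value would be ~10.7% for
the CMJ model, not the reported 7.4%) and exposes the SEE variant.

## Reliability, agreement and power

ICC uses the two-way random-effects absolute-agreement decomposition
(rows = participants, columns = trials): ICC(2,1) =
(MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n), CI by the F
approximation with Satterthwaite degrees of freedom, and ICC(2,k) via the
Spearman–Brown step. Single-measure is the default since the single/average
choice is not fixed by convention; both are exposed. The implementation is
written from the sums of squares directly and is cross-checked against
pingouin in the tests. Qualitative bands (poor < 0.5 ≤ moderate < 0.75 ≤
good < 0.9 ≤ excellent) are applied to the CI lower bound.

SEM = SD·√(1−ICC) with SD taken as the between-participant SD of
per-participant trial means (the within/between choice is not standardized;
this one matches the reliability-table worked examples), SEM% = 100·SEM/mean.

Agreement: paired t (two-sided), Cohen's d for paired data =
mean(diff)/SD(diff), Bland–Altman bias ± 1.96·SD(diff). Degenerate
zero-variance differences: zero bias → d = 0, p = 1; nonzero bias → p = 0
with infinite t, both documented conventions rather than NaNs.

Power: the R²-deviation-from-zero F test with df₁ = k, df₂ = n − k − 1 and
noncentrality λ = f²·n; `power_min_n` scans n upward until the target is
met, and the suite cross-checks the analytic power against a 10⁴-replicate
Monte-Carlo rejection rate on a fixed design with exact noncentrality.
Cohen's f² = R²/(1−R²). Shapiro–Wilk delegates to scipy.

## Problem sizes in the test suite

Synthetic trials are ~11 s at 1000 Hz; batch tests use 6 participants × 3
trials; Monte-Carlo checks use 200–500 seeds for regression recovery and
10⁴ replicates for power and Bland–Altman coverage. These sizes give
sampling error comfortably inside the asserted tolerances (e.g. SE ≈ 0.004
on a 0.85 rejection rate at 10⁴ replicates) while keeping the whole suite
around ten seconds.

## Known limitations

- The stepwise procedure inherits the usual caveats of stepwise selection
  on small cohorts (inflated in-sample R²); `loo_predictions` offers a
  leave-one-out honesty check but no further cross-validation is built in.
- Only the vertical force component of a single plate is modelled and
  analyzed; no landing-phase loading, RSI or contact-time metrics.
- The XLSX supplementary format of raw study data is not parsed; recordings
  travel as delimited text.
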