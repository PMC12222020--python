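# Methods notes

This note records the models implemented, the defaults chosen where the
design was genuinely open, and what the synthetic generator does and does
not emulate.

## Conventions

Voltages are µV, frequencies Hz, times ms relative to face onset. Epochs
span the half-open interval [−1000, 1200) ms at 512 Hz → 1126 samples.
All millisecond windows are half-open with both endpoints mapped to sample
indices by flooring; e.g. the baseline window [−500, −260) covers exactly
122 samples. Every stochastic routine takes one integer seed; internal
streams are split with `numpy.random.SeedSequence.spawn`, so a single seed
determines the whole simulation bit-for-bit.

Epoched data live in an `EpochSet`: a flat `(trials, channels, samples)`
array with an aligned per-trial design table carrying the subject id. A
flat trial axis (rather than a subjects × trials array) is used because
trial counts diverge across subjects after artifact rejection.

## Synthetic generator

The generator's purpose is to carry, with known ground truth, exactly the
statistical structure the analyses target.

**Design.** 722 trials per subject: per stimulation condition
(off/early/late), 16 identities × (6 neutral + 4 happy + 4 sad)
repetitions, plus 50 stimulation-only trials; order is a uniform shuffle
repaired by random swaps until no five consecutive trials share a
stimulation condition or emotion, with a hard move budget — failure raises
rather than silently relaxing a constraint.

**Background noise.** 1/f^α noise (α = 1, RMS 8 µV) plus white noise
(SD 2 µV), both Gaussian, generated by spectral shaping. This reproduces
the broadband 1/f character of EEG and nothing else.

**N170.** A Gaussian bump centred at 175 ms (σ = 12.5 ms) on the 18
posterior electrodes, normalised so its mean over the 150–200 ms
extraction window is exactly 1; the planted per-trial amplitude is
therefore recovered to machine precision by the extractor on noise-free
data. Amplitude = base (−5 µV) + emotion delta (happy −1.5, sad −1.0)
+ a main-effect shift under early stimulation (+1 µV, i.e. a reduction)
+ an extra happy-specific shift under early stimulation (+2 µV default).
The interaction term exists because a pure main effect is, by
construction, invisible to the happy−sad double subtraction; the published
pattern (stimulation shrinking the happy−sad difference) is an
interaction. The magnitude of the reduction is a free parameter — no µV
value is published for it.

**Beta coupling.** From 650 ms (20 ms cosine ramp), every central
(Cz, C1–C4) and left-occipital (P1–P7 odd, PO3/5/7) channel receives
`amp · (√c · shared + √(1−c) · private)`, all terms unit-variance
13–22 Hz Gaussian noise. Absent background noise, across-trial magnitude
coherence between any central–occipital pair converges to `c` — this
analytic limit is the estimator's oracle. Default couplings by
(condition, eventual choice) follow the published masked means: off
(0.340 happy / 0.316 sad), late reversed (0.318 / 0.332), early given the
same reversed trend (0.320 / 0.332, reported as non-significant).

**Artifact.** 35 biphasic pulses (70 Hz × 500 ms) in the early
(−250…250 ms) or late (500…1000 ms) window. A 100 µs phase is far shorter
than one 1.95 ms sample, so each pulse is a signed two-sample transient
of configurable amplitude (default 60 µV) with a frontal-dominant spatial
profile interpolated along the template head's anterior–posterior axis
(the source sits on the cheeks). The waveform is identical for every
trial of a condition — the property that makes the double subtraction
cancel it to machine precision, mirroring the analysis rationale.

**Choices.** Bernoulli with
`logit P(happy) = b₀ⱼ + b_emotion + b_fnmes`, where `b₀ⱼ ~ N(0, σᵤ²)`.
Defaults: b_happy = 5.50, b_sad = −4.23, b_early = 0.17, b_late = 0.133
(the published estimates) and σᵤ = 1.36, chosen to match the published
conditional R² ≈ 0.36 of the neutral-face model via the latent-scale ICC
σᵤ²/(σᵤ² + π²/3).

**AU traces.** OpenFace-style 30 Hz intensity columns (`AU04_r`, `AU06_r`,
`AU12_r`, `AU15_r`) over −2…+2 s around stimulation onset, baseline level
0.5, additive Gaussian noise (SD 0.05), and a multiplicative AU12 lift
during the 500 ms stimulation window with default gains 0 / 0.137 / 0.156
(off/early/late — the published condition means).

What the generator does **not** emulate: volume conduction or any forward
head model, eye blinks and EMG, line noise, trial-to-trial latency jitter
of components, and non-stationary noise. Tests passing on this generator
therefore validate the *estimators and their calibration*, not robustness
to every artifact class of real recordings.

## Preprocessing

4th-order Butterworth filters applied forward–backward (`sosfiltfilt`,
zero phase — the standard ERP choice since it preserves latencies); the
filter family is not dictated by the analysis recipe, only its cutoffs
(0.5–80 Hz first pass, 40 Hz final low-pass). Rejection is strict:
a trial drops iff |v| **exceeds** 100 µV ("exceeded" read literally, so a
sample at exactly 100 µV is retained). Baseline window [−500, −260) ms —
a period free of stimulation in both conditions. Bad-channel
interpolation is an inverse-distance-weighted mean of template-coordinate
neighbours within 4.5 cm (≥3 good neighbours required; weights sum to 1);
spherical splines were deliberately avoided in favour of a method whose
weights are directly testable. A 50 Hz notch exists but defaults off
(the generator produces no line noise). Operations warn when applied
outside the canonical order (band-pass → interpolation → rejection →
baseline → low-pass → average reference) and log themselves for
provenance. ICA-based artifact removal is out of scope: the pipeline's
artifact strategy is differencing + rejection.

## ERP statistics

Mass-univariate testing operates on subject-level maps (one-sample t
against zero of per-subject double-difference maps — algebraically the
paired t-test between conditions), not on pooled single trials; this is
the standard across-subject mass-univariate formulation. The FDR variant
is Benjamini–Hochberg applied jointly across all channel × time cells.
Zero-variance cells get p = 1 with a warning. N170 extraction defaults to
the fixed published ROI (18 posterior electrodes × [150, 200) ms) for
comparability; the data-driven mask from `mass_univariate` can be used
instead via `mask_to_runs`.

## Coherence

"Coherence coefficients" are implemented as **magnitude** coherence (not
squared): published masked means around 0.32–0.34 are consistent with
magnitude coherence at mid-sized trial counts, whereas squared coherence
of weakly coupled EEG at ~70 trials would sit far lower. A `squared=True`
toggle exists. The STFT coefficient at (f, t) is the plain DFT of the
5-cycle Hanning-tapered segment centred on t; segments may draw on
samples outside the 0–1000 ms analysis range (the epoch extends from
−1000 to +1200 ms), and cells whose window would cross the epoch edge are
NaN, never zero-filled — NaN propagates through ROI averages and is
excluded from cluster formation. Coherence is pooled across trials within
subject × condition × choice (it is not defined per trial); group
statistics act on subject-level maps. Cells with fewer than 10 trials
(configurable) are skipped.

## Cluster permutation

Cluster statistic: mass (sum of member t-values), the field-standard
"maxsum". Adjacency: 4-connectivity on the frequency × time grid, no
diagonals. Two-tailed handling: positive and negative clusters are pooled
into a single max-|mass| null and tested at the final alpha (the
alternative — per-tail at α/2 — is noted but not default). Permutations
are full sign flips of whole subject maps, sampled with replacement
without uniqueness enforcement; p-values use the plus-one rule and so are
never zero and never smaller than 1/(n_perm+1). All three occipital ROIs
are analysed; defaults are 2000 permutations, cluster α = 0.01, final
α = 0.05. The masked-mean ANOVA uses Greenhouse–Geisser-corrected
repeated measures (hence fractional degrees of freedom) with partial η²
and Bonferroni-corrected paired-t post-hocs of choice within condition.

## Choice GLMM

The estimator maximises the Laplace approximation of the marginal
likelihood of a logistic model with one Gaussian intercept per subject:
the inner problem (per-subject posterior mode) is a vectorised 1-D
Newton iteration; the outer problem optimises fixed effects and log σᵤ by
BFGS on a per-observation-scaled objective; standard errors come from the
numerical Hessian at the optimum. Random-slope requests are accepted and
simplified to the intercept structure with a recorded note (mirroring the
simplify-on-singularity practice). Detected separation (|b| > 12) refits
with a small ridge penalty and flags the fit; a boundary variance
estimate (σᵤ → 0) or failed optimisation falls back to a fixed-effects
logistic fit with cluster-robust (by subject) errors, also flagged,
never silent. The test suite cross-checks the estimator against lme4's
`glmer` on identical data (agreement to ~0.01 in coefficients and ~5% in
standard errors and σᵤ).

Effect sizes: `d = b/(π/√3)`, the latent-logistic standardisation. Note
one rounding subtlety: converting the published rounded coefficient 0.17
gives d = 0.09, while the published d = 0.10 corresponds to the unrounded
coefficient (z × SE ≈ 0.177); both facts are asserted in the tests.

PSE: per subject × condition, a logistic fit of choice on the emotion
continuum (sad −1, neutral 0, happy +1); PSE = −intercept/slope. Cells
with invariant responses (subjects labelling every neutral face the same
way) yield a missing PSE with a flag rather than an error, matching the
exclusion practice for such subjects.

Power: Monte-Carlo over sample sizes — simulate a neutral-trial design
and choices, fit the GLMM, score the Wald test of the early coefficient;
Wilson binomial CIs. The random-effect variance behind any published
power figure is not recoverable from reported numbers, so σᵤ is an
explicit input and no specific historical power value is claimed.

## Problem sizes in the shipped checks

The calibration and recovery suites run at sizes chosen to make their
statistical claims testable at interactive cost: 200 global-null
replicates with 500 sign flips for false-positive calibration (binomial
slack 2·MC-SE over 200); 25 simulations of 48 subjects × 288 neutral
trials for choice-effect recovery (bias bound 0.05); 8 subjects × 20
trials/cell for N170 recovery; 10 subjects × 40 trials/cell for the
planted coherence cluster. These are the package's own scaled study
conditions; the estimators themselves have no size-dependent switches.

## Known limitations

* The artifact model is sample-aligned and perfectly stationary; real
  stimulation artifacts jitter relative to the sampling grid and vary
  with electrode impedance.
* Neighbour interpolation is inverse-distance, not spherical-spline, and
  uses idealised template positions.
* The GLMM supports Gaussian random intercepts only; slope variance is
  approximated by simplification, not estimated.
* Coherence offers no phase-lag-index or imaginary-coherency variants, so
  zero-lag common sources (e.g. volume conduction in real data) inflate
  estimates by design.
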