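# Methods

This note documents the models, numerical choices and known limitations of
the `oxytouch` pipeline, in the order data flow through it.

## Synthetic cohort generator

The generator is first-class, tested code: its role is to produce cohorts
whose generative structure matches what the downstream analyses assume, so
every stage can be validated by parameter recovery rather than by fiat.

**Design.** A session is 20 blocks of 30 s stimulation followed by 15 s
rest (900 s) at 6.78 Hz; gentle stroking touch and medium pressure massage
occupy separate sessions. The default cohort enrolls 180 subjects —
intranasal OT / oral OT / placebo — and flags 5 "incomplete" plus 4
"technical" exclusions (allocated round-robin across arms), leaving
analyzed group sizes of 56/57/58.

**fNIRS forward model.** Per channel, the neural drive for each block is a
boxcar of height `amplitude(ROI, condition)` (µM); where a prolongation
constant `τ(ROI, condition, group)` is set, the drive decays as
`exp(-Δt/τ)` past block offset instead of stopping. The drive is convolved
with the canonical double-gamma HRF and scaled so a sustained block
plateaus at its amplitude. Defaults: gentle touch drives mOFC/mlOFC
(0.40 µM), pSTS (0.30), lOFC (0.20), S1 (0.15); massage drives S1 most
strongly (0.40); both OT groups get τ = 8 s in mOFC/mlOFC/pSTS for gentle
touch and the placebo group τ = 0 — the response-prolongation effect the
classifier is meant to detect. On top: white sensor noise (SD 0.3 µM),
systemic sinusoids for cardiac (1.1 Hz, 0.08 µM), respiratory (0.25 Hz,
0.08) and Mayer (0.10 Hz, 0.12) oscillations with random phase, and
Poisson motion artifacts (0.5/channel/min), each either a 0.5–1.5 s spike
(~3 µM) or a baseline step (~1 µM). Spikes are given realistic sub-second
to second durations because shorter glitches carry almost no energy below
the TDDR 0.5 Hz split frequency at this sampling rate. Between-subject
variability: a common amplitude gain (CV 0.2) and additive τ jitter
(SD 1.5 s).

**Mediation structure.** With X the 0/1 treatment indicator of one OT
route versus placebo, the post-treatment plasma change is `M = aX + ε_M`
(σ_M = 4 pg/ml) on a baseline of N(8.8, 2.5²) pg/ml floored at 0.5, and
gentle-touch pleasantness is `Y = 5.5 + c′X + bM + ε_Y` (σ_Y = 1.1),
clipped to the 1–9 scale. Default paths: a = 6.57, b = 0.06, c′ = 0.37
(intranasal) and a = 2.41, b = 0.06, c′ = 0.50 (oral). The noise scales
were fixed once from the dispersions such a study reports; with them the
probability of clipping is below 1%, and replicate simulation shows path
biases of ~1% (a) and <1% (b) at full cohort size — small enough that the
mean recovered indirect effect sits within Monte-Carlo error of a·b.

**Determinism.** `SeedSequence(seed)` spawns child seeds; child 0 drives
roster/exclusion assignment and child i+1 drives subject i in roster
order (groups in configuration order, analyzed subjects before that
group's excluded ones). Cohorts are therefore extensible by enlarging the
final group or appending groups without perturbing existing subjects;
inserting subjects into an earlier group renumbers everyone after it.

**What it does not emulate.** Scalp optics and head geometry (optode
positions are schematic), deoxy-Hb dynamics (HbR is carried through the
Beer–Lambert stages but not modelled as a signal), serially correlated
sensor noise, rater idiosyncrasies, or dropout mechanisms that correlate
with treatment. Passing tests certify the statistical machinery, not the
biological realism of any particular parameter value.

## Preprocessing

Order is fixed: Beer–Lambert conversion → polynomial detrend → TDDR →
bandpass.

- **Optical density** uses the natural-log convention
  `OD = -ln(I/Ī)`; the per-channel mean is the reference intensity.
- **Modified Beer–Lambert.** `Δc = (EᵀE)⁻¹Eᵀ(ΔOD_λ/(DPF_λ·d))` solved per
  channel/sample. Extinction coefficients at 760/850 nm are literature
  constants (Cope's compiled spectra as shipped with the Homer toolchain,
  rescaled to cm⁻¹·µM⁻¹ under the natural-log convention); DPF defaults to
  6.0 at both wavelengths, source–detector distance 3 cm. All overridable;
  the inverse is exact against the forward model to numerical precision.
- **Detrend**: least-squares polynomial per channel, default order 1,
  evaluated on a [-1, 1]-scaled time axis for conditioning.
- **TDDR**: low/high split at 0.5 Hz (order-3 Butterworth, zero phase),
  Tukey-biweight reweighting of the low-band temporal derivative with
  tuning 4.685 and MAD scaling, iterated until the robust mean converges
  to relative machine precision (max 50 iterations) — the stopping rule of
  the published reference code, which this implementation matches
  bit-for-bit (and is cross-checked against in the tests). Two
  consequences worth knowing: single-sample glitches live above the split
  frequency and are left for the bandpass stage; and because the biweight
  shrinkage re-applies on every pass, TDDR is only approximately
  idempotent (re-application moves a corrected fixture by a few percent
  RMS). On recordings whose low band is noise-dominated the reweighting
  also injects a little low-frequency drift — irrelevant downstream
  because the 0.01 Hz high-pass edge removes it.
- **Bandpass**: order-4 Butterworth, 0.01–0.08 Hz, applied
  forward–backward (zero phase, so effective attenuation is doubled),
  second-order sections for stability. Gain ≥ 0.95 at 0.04 Hz and
  ≤ 0.01 at 1 Hz by construction.

## GLM and ROI statistics

The canonical HRF is a double gamma, `(t/d)^(d/b) e^{-(t-d)/b}` per lobe,
peaking exactly at d = 6 s with a 16 s undershoot at ratio 1/6, dispersion
0.9 s, truncated at 32 s and peak-normalized. Design columns are condition
boxcars convolved with this kernel and divided by the kernel sum, so a
sustained response of A µM yields β = A; rest intervals are modelled as
their own regressors (the implicit baseline is only inter-session time)
and the contrast of interest is stimulation β minus the matching rest β.
All four canonical condition columns are always built (empty ones are
identically zero); single-session fits either drop empty columns
explicitly or concatenate the two sessions, which is what the pipeline
does. Estimation is ordinary least squares per channel; no prewhitening is
applied — after the 0.01–0.08 Hz prefilter the residual spectrum is
already dominated by the passband, and this is a documented limitation
rather than a modelling claim. ROI values are unweighted means of member
channels.

## Classification

Features: block-averaged preprocessed oxy-Hb, 5–35 s after gentle-touch
onset (203 samples at 6.78 Hz), averaged within mOFC, mlOFC and pSTS and
concatenated in that fixed order (609 values). No baseline re-anchoring by
default (an onset-anchored subtraction flag exists). A held-out subject is
assigned to the group whose mean pattern (recomputed without that subject)
it correlates with more strongly; Pearson correlation is the default
similarity, cosine available. Exact similarity ties and undefined
correlations (constant vectors) are scored as incorrect and counted. The
permutation null shuffles group labels (default 10,000 draws) and
`p = #(null ≥ observed)/m` — the literal proportion, with an optional
`(b+1)/(m+1)` estimator off by default. Under label-independent features
the test is calibrated: across 200 replicate null cohorts the rejection
rate at α = 0.05 stays inside the binomial 95% band.

## Autonomic indices

SCR amplitude is the mean over stimulation onsets of
`max(window) - value(window start)` in a 15 s window, floored at zero per
event ("base" = window-start value; a local-trough definition would differ
on noisy tonic drifts and is intentionally not used). Heart rate is
`60000/mean(RR)`. HF power cubic-interpolates the RR tachogram onto a 4 Hz
grid, removes a linear trend, and integrates the Welch spectrum over
0.15–0.40 Hz (ms²). DFA-α1 integrates the centered series, fits a line per
non-overlapping box for box sizes 4–16 beats, and reports the slope of
log F(n) versus log n. Finite-size behaviour: at these short scales the
estimator runs slightly above 0.5 on white noise (≈ 0.58 at 1000 beats,
a known small-scale bias of first-order DFA) and ≈ 1.0 on 1/f surrogates;
both sit within the ±0.1 bands the tests assert.

## Inference

The mixed repeated-measures ANOVA uses the classical totals decomposition
with subject as the error stratum: between effects are tested against
subjects-within-groups, each within effect against its own
factor-by-subject-within-group interaction (weighted-means sums of squares
under unequal group sizes; identical to pingouin on the one-within case).
Effect size is partial η² = SS_effect/(SS_effect + SS_error). With a
single within level the table degenerates to the one-way between-subjects
test. No sphericity correction is applied by default (two-level within
factors need none; the five-level region factor is reported uncorrected,
matching the convention of reporting uncorrected df).

Mediation fits M~X, Y~X+M and Y~X by OLS; the indirect effect is a·b,
identically c − c′, with a percentile bootstrap CI (default 5,000 subject
resamples; percentile rather than bias-corrected, matching the plain
[low, high] reporting convention). Resamples with a degenerate (constant-X)
draw are discarded. Two-tailed p-values throughout.

The a-priori sample-size solver evaluates one-way fixed-effects ANOVA
power from the noncentral F distribution with ncp = f²·N and steps over
equally allocated totals N = k·m, returning the smallest N meeting the
target. Equal allocation is deliberate: for k = 3, f = 0.25, α = 0.05,
power = 0.80 it returns 159 (power 0.805), whereas the unconstrained
integer minimum would be 158 — the equal-allocation convention is what an
a-priori k-group design uses.

## Problem sizes used by the shipped runs

The analysis drivers simulate 12 subjects per arm with 2,000 permutations
and 2,000 bootstrap resamples; the test suite uses cohorts of up to 20+20
subjects (50 replicates, 1,000 permutations) for end-to-end
discrimination, 200-replicate batteries for calibration and coverage
checks, and 300 replicate cohorts for path recovery. These sizes were
chosen as the smallest at which the binomial/Monte-Carlo error bands in
the assertions are meaningful; all scale up by configuration only.

## Known limitations

- No short-separation-channel regression or spline/wavelet motion
  correction; TDDR plus bandpass is the only artifact path.
- HbR is converted but not analyzed; HbT is not computed.
- The classifier is strictly two-group leave-one-out; three-way decoding
  and alternative cross-validation schemes are out of scope.
- The payment-willingness rating is stored on a 1–9 scale; the instrument
  it emulates mixes a 1–100 phrasing with 1–9 anchors, an ambiguity the
  generator documents rather than resolves.
- Listwise deletion is the only missing-data policy in the stats layer.
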