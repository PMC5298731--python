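# Methods

This note documents the models, algorithms and numerical choices behind
`ectobeat`, and what the synthetic study conditions do and do not show.

## Delineation

**R peaks.** Pan–Tompkins with the classic constants: 2nd-order Butterworth
band-pass 5–15 Hz (zero-phase), derivative, squaring, 150 ms moving-window
integration, dual adaptive thresholds (signal/noise EWMA factors 0.125 and
0.25), a 200 ms refractory period and search-back at half threshold when
the interval since the last beat exceeds 1.66× the running RR average.
Each accepted fiducial is refined to the raw-ECG local maximum within
±25 ms, so "R amplitude" is defined on the unfiltered signal. Refinement is
done on the raw ECG (the method's reference description does not state raw
vs. filtered; raw keeps the amplitude features physical).

**Pulse peaks.** A plain maximum search between adjacent R peaks, on a
zero-phase 0.4–12 Hz band-passed PPG. The record pipeline blanks the first
180 ms after each R peak: a peripheral pulse cannot arrive that early
(shortest PAT in the operating range is ≈ 200 ms), and without the blank
the decaying previous pulse or its dicrotic wave can out-vote a small
premature pulse. The blank is a pipeline parameter; the bare function
defaults to the unblanked search.

**Pulse onsets.** The default onset is the *intersecting tangent*: the
maximum-upslope point of the systolic rise, located within 150 ms before
the peak, extrapolated back to the horizontal line through the local
minimum just before it. A plain foot-minimum search is available but is
not the pipeline default: the zero-phase smoothing needed at low SNR
smears the foot "V" asymmetrically and biases the plain argmin ~40 ms
early, while the tangent construction is first-order immune to that smear
(it extrapolates through the well-preserved steep rise). On the standard
cohort the tangent onset recovers 100 % of true feet within ±20 ms at
20 dB SNR; the plain minimum recovers none.

Beats are assembled per interior R peak; the first and last R peaks lack a
neighbour and are flagged invalid. A beat is complete for PPG features
only when the *next* pulse's fiducials exist (needed by the
amplitude-ratio feature), which the last interior beat lacks.

## The 20 beat features

Order and definitions are listed in the README. Two normalization choices
make every feature exactly gain- and offset-invariant:

* ECG features de-mean the analysis window and divide by the absolute
  de-meaned value at the R sample (falling back to the window maximum when
  that is below the floor ε = 10⁻⁶ of the channel's dynamic range);
* PPG features subtract the onset value and divide by the peak-minus-onset
  amplitude.

The "fractional amplitude" features are instantiated as the normalized
pulse value at 25/50/75 % of the onset-to-onset duration (fractions
configurable); the max/min feature floors |min| at 10⁻⁶. Features depend
only on samples between the previous R peak and the end of the next pulse,
which bounds the streaming buffer at roughly three beats.

## Classifier and the SCG engine

The beat classifier is a 20-10-8-3 perceptron (inputs resize automatically
for the ECG-only/PPG-only subsets): tanh hidden layers, softmax output
over (N, S, V), cross-entropy loss. Training is Møller's scaled conjugate
gradient with his published constants (σ = 10⁻⁴, initial λ = 10⁻⁶),
full-batch; the training loss is non-increasing over accepted steps by
construction. Tanh/softmax/cross-entropy are conventional choices; the
logistic hidden activation is available.

Early stopping holds out a random 10 % validation split and stops after
`patience` iterations without a new validation minimum, returning the
best-validation weights. The low-level `TrainConfig` default is
`patience=1` ("stop as soon as the error increases"); the estimator
classes default to `patience=8` (classifier) and `patience=15`
(morphology regressor) because SCG validation curves are noisy and
single-increase stopping routinely quits within a handful of iterations.

Classes are balanced before training by undersampling every class to the
minority count (seeded). Inputs are z-scored on the training set inside
the estimator: the amplitude-invariance property concerns signal gain, not
feature scale, and SCG convergence benefits from comparable scales.
Prediction is argmax with ties broken to the lowest class index
(N < S < V); "ectopic" means any non-N winner. Everything is deterministic
under a fixed seed.

## Evaluation

Leave-one-subject-out: one classifier instance per fold, trained on all
other subjects' beats, tested on the held-out subject; the 3×3 confusion
matrices are summed. Sensitivity is the fraction of truly ectopic beats
predicted as either ectopic class; specificity the fraction of truly
normal beats predicted normal. The wording "beats labeled as ectopic" is
read as ground-truth labels (standard sensitivity); the alternative
reading (positive predictivity) is computed and reported under its own
name. Per-class sensitivities use the any-ectopic convention (the headline
task is binary), with strict same-class variants reported alongside. A
fold whose training pool lacks a class is skipped with a warning (or
raises in strict mode).

## Blood-pressure estimation

**Chen.** `Pe(t) = Pb − (2 / (γ·Tb))·(PAT(t) − Tb)`, γ = 0.017 mmHg⁻¹.
This is the first-order Taylor form that follows from the exponential
elasticity and Moens–Korteweg relations: with `E = E₀·e^{γP}` and
`v = √(h·E/(2rρ))`, PAT = L/v gives `P(T) = const − (2/γ)·ln T`, whose
derivative at the calibration point is `−2/(γ·T)`. (The compact typography
of the defining formula can also be parsed as the product `2·γ·Tb·ΔT`,
which would give a sensitivity of order 10⁻⁵ mmHg per ms — physically
meaningless — and is rejected.) Recalibration replaces (Pb, Tb) at the
first usable beat after each interval boundary (default 60 s).

**Cattivelli.** Per target, `BP = a·PAT + b·HR + c` fitted by ordinary
least squares on the first 40 usable beats, with the RLS inverse
covariance seeded from the normal equations. One RLS update (forgetting
factor λ, default 0.99) runs per calibration interval; with λ = 1 the RLS
trajectory reproduces batch least squares on all data seen (tested to
1e-8). HR is 60/RR_prec of the same beat. The inverse covariance is
re-symmetrized after each rank-one update to keep it positive definite
over long runs.

**Kurylyak.** 21 pulse-morphology features: systolic and diastolic widths
at 10–70 % of pulse amplitude (14, crossings by linear interpolation),
systolic upstroke time, diastolic time, pulse period, and
diastolic/systolic width ratios at 10/30/50/70 % (the reference feature
list is not public; this instantiation follows the published description
of "systolic and diastolic widths at different heights"). They feed the
shared SCG engine in regression mode (default hidden layers 15-10, linear
output). Widths are measured on the band-passed PPG — on the raw signal
the level crossings are dominated by broadband noise.

**Clearance.** The default policy drops exactly the beats the detector
flags as ectopic; `drop_following` also removes the potentiated next
beat. Calibration events falling on dropped beats defer to the next
retained beat. PAT uses the pulse-foot fiducial for both PAT-based models
(the original methods' fiducial choices are adopted as published
descriptions allow).

**Error metrics.** Errors e = estimate − reference per beat: mean, sample
SD (n−1), Pearson correlation, MSE, RMSE, mean ± SD absolute error,
mean ± SD relative error (% of reference) and the fraction of beats whose
relative error is within configurable bounds (default 5/10/16 %).
Relative errors are reported as undefined when the reference contains
zeros. The beat-wise systolic reference is the ABP-channel maximum over
each RR interval.

## Synthetic study conditions

The generator produces multi-subject ECG/PPG/ABP records with exact
ground truth. Defaults (one record): 500 Hz, 300 s, 72 bpm with AR(1) RR
variability (φ = 0.4, σ = 25 ms), 5 % VEB and 5 % SVEB per beat (≈ 9–10 %
ectopic overall, never adjacent), SNR 20 dB plus sinusoidal baseline
wander (0.3 Hz; amplitude 0.10 of the ECG, 0.05 of the PPG scale).

*Rhythm.* Ectopic coupling intervals are drawn per beat
(0.60 ± 0.10 of the sinus RR, clipped to 0.5–0.9). A VEB's following
interval is extended so the flanking intervals sum to exactly twice the
sinus RR (full compensatory pause); an SVEB resets the rhythm
(non-compensatory).

*ECG.* Gaussian P/Q/R/S/T waves per beat. VEBs omit the P wave, widen the
QRS ×1.8, scale its amplitude ×1.4 and carry a large inverted T wave
(−0.6 mV, 80 ms); SVEBs omit the P wave only.

*Pressure → PAT.* SBP(t) = 120 + 8·sin(2πt/120 s) + 2.5·sin(2π·0.25 t)
(+ per-subject baseline jitter in cohorts); DBP = SBP − 40. Velocity
follows `v = √(h·E₀·e^{αP}/(2rρ))` with α = 0.017 mmHg⁻¹ and
E₀ = 6351 Pa, h = 1 mm, r = 4 mm, ρ = 1060 kg/m³, L = 0.6 m — chosen so
PAT ≈ 250 ms at 120 mmHg (documented, arbitrary within the physiological
range). PAT adds 5 ms pre-ejection jitter (so PAT ≠ PTT; disable for
exact-inversion checks); ectopic beats eject late (+30 ms ± 20 ms),
mirroring the sharp PAT deflections ectopy causes in practice.

*PPG.* Per-beat pulses with a quarter-sine upstroke (100 ms at 120 mmHg),
a two-phase decay (40 ms fast post-systolic drop, 400 ms slow runoff at
weight 0.3) and a dicrotic bump (+180 ms after the apex, 0.10 relative
amplitude). The quarter-sine rise has non-zero foot slope, so the
rendered minimum coincides with the ground-truth foot. Pulse amplitude
scales with the preceding RR interval (stroke-volume proxy) with 8 %
beat-to-beat jitter. VEB pulses collapse to 0.30× the preceding pulse and
narrow ×0.55 (notch-like); SVEB pulses keep normal shape and recover
amplitude with coupling (slope 2.2 per unit coupling ratio — a
late-coupled SVEB is nearly invisible in the pulse wave). The following
beat is potentiated up to ×1.20, scaled by prematurity. Systolic width
shrinks 0.5 % per mmHg above 120, which is what gives the pulse-morphology
estimator its signal.

*ABP.* Rendered per beat so the within-beat maximum/minimum equal the
ground-truth SBP/DBP.

*Cohorts.* Subjects jitter heart rate (62–80 bpm), baseline SBP
(108–132 mmHg) and RR variability; the morphology–pressure coupling is
shared. Subjects are redrawn deterministically until each carries at
least 5 beats of both ectopic classes.

**What the conditions do not emulate:** motion artifacts, arrhythmia runs
(bigeminy, tachycardia), pathological PPG morphologies, sensor contact
loss, multi-wavelength effects, or hemodynamic/postural confounders.
Passing results therefore demonstrate the internal consistency and the
qualitative ectopy-vs-BPE mechanism, not field performance on real
wearable recordings.

## Experiment design

The three-condition experiment holds one synthetic subject out: its
record with ectopic beats, and a twin generated from the same seed with
ectopy disabled (identical pressure trace). The detector is trained on a
4-subject cohort and the morphology regressor on 3 clean records spanning
62–80 bpm, all disjoint from the test subject. Conditions: clean twin;
EB record unprocessed; EB record with detector-flagged beats removed.
Problem sizes (300 s records, ~360 beats each, 4 + 3 training subjects)
keep a full experiment under ~10 s while leaving ≈ 30 ectopic beats in
the test record.

## Numerical notes and limitations

* All sample indices are 0-based; intervals half-open.
* Seeded `numpy.random.Generator` streams are split per synthesis stage,
  so e.g. disabling ectopy does not perturb the pressure trace.
* CSV round-trips are bit-exact (`float_precision="round_trip"`); the
  minimal WFDB format-16 writer is lossless to its declared ADC gain.
* The MLP's softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 1e-300.
* Tie-breaks: argmax takes the earliest index everywhere (pulse peaks,
  class prediction).
* The detector's performance on the synthetic cohort (sensitivity ≈ 98 %,
  specificity ≈ 99 %) is better than what heterogeneous clinical data
  allows; the cohort's value is in exact ground truth and
  subject-disjoint evaluation, not in difficulty.
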