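# ectobeat

Multimodal (ECG + PPG) **ectopic-beat detection** and a quantitative study of
what ectopic beats do to **pulse-arrival-time blood-pressure estimation** —
and how much accuracy a detector-based beat clearance restores.

## Who this is for

Researchers and engineers working on cuffless blood-pressure estimation
(BPE), wearable cardiovascular monitoring, or beat-level arrhythmia
screening, who need a transparent, dependency-light reference pipeline:
delineation → amplitude-invariant beat features → classifier → subject-wise
evaluation → downstream BPE impact.

## The problem and the method

Premature heartbeats that originate outside the sinus node (**ectopic
beats**, EBs) come in two flavours. A **ventricular** ectopic (VEB) has no
P wave, a broad high-energy QRS with a discordant T wave, a full
compensatory pause, and — because the ventricle ejects almost no blood — a
collapsed, notch-like pulse wave. A **supraventricular** ectopic (SVEB) is
premature but conducts normally: near-normal QRS and pulse shape, a
non-compensatory pause, and a pulse amplitude that recovers as the coupling
interval grows. Both corrupt the per-beat timing (pulse arrival time, PAT)
and pulse morphology that PAT-based blood-pressure estimators depend on.

The detector works per beat, buffering only the signal between three ECG
R peaks:

1. **Delineation** — Pan–Tompkins QRS detection (5–15 Hz band-pass,
   derivative, squaring, 150 ms integration, dual adaptive thresholds with
   search-back), pulse peaks by maximum search between adjacent R peaks,
   pulse feet by an intersecting-tangent onset.
2. **20 amplitude-invariant features** — the RR-interval ratio
   `f1 = RR_prec / RR_foll`; ECG window power, mean and max/min ratio
   (f2–f4) and 10 equally spaced samples (f5–f14) over
   `[R − 0.35·RR_prec, R + 0.65·RR_foll]`, normalized by the R amplitude;
   PPG fractional amplitudes at 25/50/75 % of pulse duration (f15–f17),
   pulse power and mean (f18–f19), and the current/next pulse-amplitude
   ratio f20 — all exactly invariant to channel gain and offset.
3. **Classification** — a 20-10-8-3 multilayer perceptron (tanh hidden
   layers, softmax output over {N, S, V}) trained with Møller's scaled
   conjugate gradient, class-balanced by undersampling, early-stopped on a
   10 % validation split. A beat is *ectopic* whenever the winning output
   is not N.
4. **Evaluation** — leave-one-subject-out cross-validation with summed
   confusion matrices; sensitivity over ectopic beats, specificity over
   normal beats, per-class sensitivities.

Three BPE models consume the delineated beats:

* **Chen** — `Pe = Pb − 2·ΔT / (γ·Tb)` with `γ = 0.017 mmHg⁻¹`: first-order
  PAT tracking around an intermittent cuff calibration `(Pb, Tb)`.
* **Cattivelli** — `SBP = a·PAT + b·HR + c`, least-squares fitted on 40
  calibration beats and recalibrated online by recursive least squares.
* **Kurylyak** — 21 pulse-waveform features (systolic/diastolic widths at
  10–70 % of pulse amplitude, timing features, width ratios) feeding a
  neural-network regressor; no PAT at all.

A seeded synthetic generator provides multi-subject ECG/PPG/ABP records in
which systolic pressure drives PAT through the exponential arterial
elasticity law `E = E₀·e^{αP}` and the Moens–Korteweg pulse-wave velocity
`v = √(h·E / (2 r ρ))` — so every stage has exact ground truth.

## Worked example

```python
import numpy as np
from ectobeat import SyntheticConfig, generate_record, delineate_record, extract_features
from ectobeat.pipeline import match_labels
from ectobeat.experiment import three_condition_experiment

record, annotations, truth = generate_record(SyntheticConfig(duration_s=120), seed=42)
beats = delineate_record(record)
X, idx = extract_features(record, beats)
labels = np.array([match_labels(beats, annotations, record.fs)[i] for i in idx])
for cls in "NSV":
    m = labels == cls
    print(f"median {cls}: f1={np.median(X[m,0]):.3f}  f2={np.median(X[m,1]):.3f}  "
          f"f20={np.median(X[m,19]):.3f}   (n={m.sum()})")

result = three_condition_experiment(seed=7)
for model in ("chen", "cattivelli", "kurylyak"):
    print(f"{model:10s} RMSE clean {result.rmse('clean', model):5.2f}  "
          f"with EBs {result.rmse('with_eb', model):5.2f}  "
          f"cleared {result.rmse('cleared', model):5.2f} mmHg")
```

prints

```
median N: f1=1.005  f2=0.038  f20=1.049   (n=125)
median S: f1=0.570  f2=0.047  f20=0.206   (n=13)
median V: f1=0.418  f2=0.055  f20=0.192   (n=6)
chen       RMSE clean  3.56  with EBs  8.06  cleared  2.99 mmHg
cattivelli RMSE clean  4.28  with EBs  7.20  cleared  4.00 mmHg
kurylyak   RMSE clean  1.68  with EBs  4.11  cleared  1.80 mmHg
```

Reading it: ectopic beats are premature (`f1 < 1`), VEBs carry extra window
energy (`f2`), and both classes show a collapsed pulse relative to the
potentiated following beat (`f20 ≪ 1`). Downstream, ~10 % ectopic beats
roughly double each model's systolic RMSE; removing the beats the trained
detector flags brings every model back to (or below) its clean-record
error.

## Command line

```bash
ectobeat simulate --seed 7 --out-dir data/           # synthetic record + truth
ectobeat delineate --record data/record.csv --out beats.csv
ectobeat extract  --record data/record.csv --beats data/annotations.csv --out features.csv
ectobeat train    --features features.csv --out model.json
ectobeat evaluate --n-subjects 10 --subset all --subset ppg --report eval.json
ectobeat bpe      --seed 7 --report bpe.json
ectobeat convert  --in data/record.csv --out data/record.hea --format wfdb
```

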