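# gaitfluct

Mapping ON/OFF motor fluctuations in Parkinson's disease from a **single
waist-worn triaxial accelerometer**.

Patients with advanced Parkinson's disease alternate between an ON phase
(medication controls the symptoms; gait is fluent) and an OFF phase
(symptoms re-emerge; gait turns slow and effortful). Knowing *when* a
patient is OFF is the key input for adjusting therapy, but ON/OFF diaries
are burdensome and unreliable. `gaitfluct` implements a validated
sensor-based alternative: it analyses the patient's gait whenever they
happen to walk and classifies each walking episode as ON or OFF.

The package is aimed at movement-disorder researchers and digital-health
engineers who want to reproduce, stress-test or extend this class of
algorithm. Because the original patient recordings are not publicly
available, the package ships a first-class synthetic-data generator that
emulates the study conditions (200 Hz waist acceleration, alternating rest
and walking bouts, ON/OFF contrast, observer diaries), so the entire
pipeline is testable end to end on any machine.

## The algorithm

Four phases, applied to the signal downsampled from 200 Hz to 40 Hz:

1. **Walking detection.** The signal is cut into non-overlapping 3.2 s
   windows (128 samples at 40 Hz). Each window is summarised by the
   axis-summed spectral power P[b₁,b₂] in the bands [0.1, 3] Hz and
   [0.1, 10] Hz (selected offline from all 19,900 band pairs on a 0.1 Hz
   grid by ReliefF feature ranking), and classified walking / not-walking
   by an RBF-kernel SVM tuned by stratified 10-fold cross-validation.
2. **Stride segmentation.** Within each walking episode (first and last
   window dropped as gait initiation/termination), initial-contact events
   are detected as relative maxima of the forward trunk acceleration; a
   stride spans two consecutive contacts of the same foot (event *i* to
   event *i + 2*).
3. **Fluency.** Each stride is scored by its spectral power in
   [0.1, 10] Hz — the *fluency*, higher in ON.
4. **Decision.** Stride fluencies of an episode are averaged (disregarding
   the two initial and two final strides) and compared with a
   patient-specific threshold θ: mean fluency > θ ⇒ ON, otherwise OFF.
   θ is the splitting scalar of a linear-kernel maximum-margin SVM fitted
   on a calibration subset (a stratified random 20% of the patient's
   labeled episodes).

Validation follows the clinical protocol: decisions are compared with an
observer diary, excluding ±5 min around every motor-phase transition and
all INTERMEDIATE/UNDEFINED intervals; sensitivity, specificity, PPV and
NPV (**OFF is the positive class**) are averaged over 30 repeated
calibration/evaluation splits, per patient and across the cohort, both for
all walking segments and for segments with ≥ 10 strides.

## Worked example

```python
import gaitfluct as gf

# a synthetic 30-minute session with fast-alternating ON/OFF phases
patient = gf.simulate_patient(
    seed=7, sched=gf.make_schedule(1800.0, phase_median_s=300.0)
)

# walking classifier trained on a separate synthetic training cohort
model = gf.train_default_walking_model(
    seed=11, n_sessions=2, session_duration_s=600.0, max_windows_per_class=150
)

decisions = gf.extract_decisions(patient.recording, model)
labeled = gf.label_decisions(decisions, patient.diary, margin_s=60.0)
for d in labeled.labeled[:3]:
    print(f"{d.decision.timestamp:7.1f}s  strides={d.decision.stride_count:3d}"
          f"  fluency={d.decision.mean_fluency:.4f}  diary={d.label}")
```

prints

```
   24.0s  strides=  7  fluency=0.0351  diary=OFF
  214.4s  strides= 13  fluency=0.0350  diary=OFF
  353.6s  strides= 14  fluency=0.1134  diary=ON
```

Each line is one walking episode: its midpoint, the number of strides it
contained, the episode mean fluency (g², spectral power in [0.1, 10] Hz),
and the diary state at that instant. ON episodes carry systematically
higher fluency (here ≈ 3× — the generator's default amplitude contrast of
1.8 squared), which is exactly the separation the patient-specific
threshold exploits.

The same workflow is available from a shell:

```bash
gaitfluct simulate --n-patients 15 --duration-h 3 --seed 1 --output-dir data/
gaitfluct train-walking --seed 1 --output-dir model/
gaitfluct validate --data-dir data/ --model model/walking_model.json \
    --repeats 30 --seed 1 --output-dir report/
```

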