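# vestgait

Classification of vestibular-deficit gait from wearable inertial sensors.

Vestibular schwannoma (VS), a benign eighth-cranial-nerve tumor, disrupts
balance and gait, yet patients often score normally on clinician-rated
batteries such as the Functional Gait Assessment. `vestgait` implements a
deep-learning pipeline that detects the subtle kinematic signatures such
scores miss: six body-worn IMUs (wrist, both ankles, waist, upper back,
head), each recording 3-axis linear acceleration and 3-axis angular velocity
at 500 Hz, are segmented into individual gait cycles and classified
patient-vs-control cycle by cycle.

The pipeline, end to end:

1. **Segmentation** — gait cycles are delimited by successive dominant
   positive peaks of the right-ankle pitch angular velocity; every sensor is
   sliced on those shared boundaries and each cycle is linearly resampled to
   a fixed **6 × 512** matrix.
2. **Normalization** — per-channel min/max ranges are fitted on the training
   cycles of a fold and applied unchanged to held-out data (no clipping).
3. **Model** — a six-branch parallel 1-D CNN: each channel feeds its own
   branch of four `Conv1d(k=3, pad=1) → ReLU → BatchNorm → MaxPool(2,2)`
   blocks (filters 8/16/32/64); branch outputs are flattened, concatenated,
   and passed through two `Linear → ReLU → BatchNorm → Dropout(0.5)` blocks
   (128/64 units) to a single sigmoid output with a 0.5 decision threshold.
   The network, backpropagation, Adam, and the step learning-rate schedule
   (lr 0.1, ×0.1 every 25 epochs, 100 epochs, batch 64, binary
   cross-entropy) are implemented in numpy inside this package.
4. **Evaluation** — subject-paired leave-one-out cross-validation: each fold
   holds out one control and one patient; a subject's accuracy is the
   fraction of their cycles classified with their true label
   (`Accuracy = (TP + TN) / (TP + FP + TN + FN)` at cycle level), and group
   means are averages of per-subject accuracies.
5. **Transfer learning** — pretrain on an external source (an unsegmented
   two-class activity-window set, or a segmented pathological cohort), then
   freeze the convolutional stage bit-for-bit and fine-tune only the dense
   stage for 20 epochs.
6. **Experiments** — per-sensor sweeps, transfer deltas against a baseline,
   and subject/sample subsampling ablations (25/50/75%, repeated
   iterations).

Because the clinical recordings are not distributable, the package ships a
synthetic cohort generator (`vestgait.synthetic`) producing quasi-periodic
multi-sensor gait with subject random effects, per-cycle duration jitter,
configurable group amplitude effects, and sensor noise — enough statistical
structure to exercise and test every stage without any download.

## Worked example

```python
import vestgait as vg
from vestgait.fixtures import fixture_cohort_config, fixture_model_spec, fixture_train_config

cohort = vg.generate_cohort(fixture_cohort_config("strong", seed=11))
dataset = vg.build_cycle_dataset(cohort, "level_walk_short", "head")
report = vg.run_loocv(dataset, fixture_model_spec(seed=11), fixture_train_config(seed=11))
print(f"control {report.control_mean:.3f}  patient {report.patient_mean:.3f}  "
      f"overall {report.overall_mean:.3f}")
```

prints

```
control 0.875  patient 1.000  overall 0.938
```

i.e. on a 16-subject synthetic cohort whose patient class carries a strong
(50%) amplitude effect, paired LOOCV classifies control subjects' cycles
with mean accuracy 0.875 and patient subjects' with 1.000 — the model
recovers the planted group difference. A zero-effect cohort run the same way
lands near 0.5 (chance).

The same flows are available from the shell:

```sh
vestgait simulate --out cohort/ --seed 7
vestgait validate cohort/
vestgait evaluate cohort/ --out run/ --placement head --seed 7
vestgait ablate cohort/ --out ablation/ --mode subjects --iterations 5
```

Every command writes a `manifest.json` (resolved settings, seed, package
version, input digests) so runs can be reproduced exactly.

## Layout

| module | contents |
| --- | --- |
| `vestgait.io` | trial/cohort text formats, rotation to the global frame |
| `vestgait.synthetic` | cohort and activity-window generators |
| `vestgait.segmentation` | cycle detection, shared-boundary slicing, 6×512 resampling |
| `vestgait.normalization` | train-range normalization |
| `vestgait.nn` / `vestgait.model` | numpy NN engine and the six-branch classifier |
| `vestgait.training` | training, pretraining, freeze-then-fine-tune, checkpoints |
| `vestgait.evaluation` | metrics, paired LOOCV, report tables |
| `vestgait.experiments` | sensor sweep, transfer comparison, ablations |
| `vestgait.studies` | packaged synthetic-cohort property studies |
| `vestgait.reference` | bundled reference result tables of the target study |
| `vestgait.cli` | `vestgait` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
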