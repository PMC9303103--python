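# vesselkd

Channel-wise knowledge distillation for fine-grained segmentation of the
three vessels — pulmonary artery (PA), aorta (AO) and superior vena cava
(SVC) — in fetal-cardiac-ultrasound-like images, with a synthetic
speckle-phantom generator standing in for clinical data.

## The problem and the method

In the three-vessel view the vessels occupy only a small portion of the
image, so a segmentation network trained on full-size images tends to
produce rough boundaries and to miss the smallest vessel (the SVC)
altogether.  `vesselkd` implements a teacher–student scheme targeting
exactly this:

* a **teacher** trains on ROI crops — the bounding box of all labelled
  vessel pixels padded by 50 px per edge (at 512×512 scale), resized to the
  square model input — so the vessels fill its field of view;
* a **student** trains on full-size images; the teacher's crop-space logits
  are restored to the recorded full-image coordinates and a channel-wise
  distillation loss aligns the two networks there.

For logits y of shape H×W×C, each class channel is converted to a spatial
probability distribution by a temperature softmax over pixels,
φ(y)_{c,i} = exp(y_{c,i}/τ) / Σ_{i'} exp(y_{c,i'}/τ), and the distillation
loss is the channel-wise KL divergence

    L_KD(yᵀ, yˢ) = (τ²/C) Σ_c Σ_i φ(yᵀ)_{c,i} · log( φ(yᵀ)_{c,i} / φ(yˢ)_{c,i} ).

The training objective is

    L = α·L_CE(y_gt, y_pred) + β·L_Dice(y_gt, y_pred) + γ·L_KD(yᵀ, yˢ)

with α = β = 1 everywhere, γ = 0 for the teacher, and γ = 3, τ = 4 in the
student's distillation stage.  Both roles train in two stages
(frozen-encoder warm-up, then end-to-end) with Adam, learning-rate decay
lr_init·0.92^(epoch−1), and early stopping on validation loss.
Segmentation accuracy is reported per class and as a three-vessel mean of
IoU = |S_a∩S_b|/|S_a∪S_b|, PA = |S_a∩S_b|/|S_a| and
Dice = 2|S_a∩S_b|/(|S_a|+|S_b|), in percent (S_a predicted pixels, S_b
ground truth).

The network is a small DeepLab-style encoder–decoder (strided encoder,
optional atrous pyramid, skip-connected decoder) implemented directly on
numpy arrays with gradient-checked backprop — no deep-learning framework
required.  See `docs/methods.md` for the full model description, design
choices and limitations.

## Worked example

```python
from vesselkd.experiments import run_kd_comparison

out = run_kd_comparison(seed=1)       # ~4 minutes on one CPU core
print(out["baseline"].to_text("Baseline (γ=0)"))
print(out["student"].to_text("KD student (γ=3, τ=4)"))
```

This trains, on 200 synthetic 64×64 phantoms, a ROI-crop teacher and then a
distilled student and a γ=0 baseline with identical budgets, and evaluates
on 30 held-out phantoms.  Output from seed 1:

```
Baseline (γ=0)
(n=30 images, micro aggregation)

                            IoU (%)  PA (%)  Dice (%)
Pulmonary artery (PA)        96.9     97.4    98.4
Aorta (AO)                   93.5     93.7    96.6
Superior vena cava (SVC)     86.5     86.6    92.8
Mean                         92.3     92.6    95.9

KD student (γ=3, τ=4)
(n=30 images, micro aggregation)

                            IoU (%)  PA (%)  Dice (%)
Pulmonary artery (PA)        96.2     98.1    98.1
Aorta (AO)                   95.1     96.6    97.5
Superior vena cava (SVC)     87.4     87.8    93.3
Mean                         92.9     94.2    96.3
```

The distilled student comes out ahead on every mean metric (+0.6 mean IoU,
+1.6 mean PA, +0.3 mean Dice at this seed), with the largest per-class
margins on the aorta and the small SVC.  How pronounced the gap is depends
on the replicate: at seeds where the baseline's budget is too short to pick
up the SVC at all, the student — whose distillation signal localises that
channel from the start — leads by tens of mean-IoU points.  The acceptance
suite asserts the direction of this comparison over three replicates.

The same pipeline is scriptable:

```bash
vesselkd gen-data --config experiment.yaml --out data/
vesselkd train --config experiment.yaml --role teacher  --data data/ --out runs/
vesselkd train --config experiment.yaml --role student  --data data/ --out runs/ \
               --teacher-ckpt runs/teacher.npz
vesselkd train --config experiment.yaml --role baseline --data data/ --out runs/
vesselkd eval  --checkpoint runs/student.npz --manifest data/manifest.csv \
               --split test --out student.json
vesselkd compare student.json baseline.json
```

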