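# mscaseg

3D brain-tissue segmentation with multiscale convolutional attention, an
edge-overlap label-quality-weighted loss, and a Dice / HD95 evaluation
suite — exercised end to end on synthetic brain phantoms with exact ground
truth.

## What problem this addresses

Automated segmentation of T1-weighted brain MRI into cerebrospinal fluid
(CSF), gray matter (GM) and white matter (WM) usually trains on labels that
were themselves produced by automated pipelines, so some annotations are
wrong — and a network trained on them inherits the errors.  This package
implements a segmentation method built around two ideas:

1. **3D multiscale convolutional attention (MSCA).**  A U-shaped five-stage
   encoder–decoder whose deep stages compute attention weights from
   multi-branch depth-wise *strip* convolutions (kernel extents 5, 7, 11 as
   k×1×1, 1×k×1, 1×1×k triples) over a 5×5×5 depth-wise aggregation,
   multiplied elementwise with the input:

       out = Conv1×1×1( Σᵢ Scaᵢ(ConvD(x)) ) ⊗ x

   Three orthogonal strips of extent k give a k³ receptive field at 3k cost
   per channel.  Instance normalization is used throughout; deep-supervision
   heads at five decoder resolutions carry weights
   (0.03125, 0.0625, 0.125, 0.25, 0.5), ascending with resolution.

2. **Label-quality weighting.**  For each training patch, Canny edges of the
   image and of its label map are compared; their Dice overlap W ∈ [0, 1]
   scores annotation quality (accurate tissue boundaries coincide with
   image gradients).  The loss

       L_total = Σₛ wₛ (ℓ_dice + ℓ_ce) + λ · W · ℓ_ce

   down-weights badly annotated patches (λ defaults to 1).

Training follows the reference recipe — SGD with momentum 0.99, weight
decay 3×10⁻⁵, poly learning-rate decay lr₀(1 − e/E)^0.9 from 0.01, axial
flip / right-angle rotation augmentation, 5-fold cross-validation helpers —
and evaluation reports per-class Dice (%) and the 95th-percentile Hausdorff
distance (mm).  Since the original MRI cohorts are not redistributable, a
phantom module generates skull-stripped-style volumes (nested ellipsoidal
tissue compartments, bias field, Gaussian/Rician noise) with exact labels
and controllable corruption, so every mechanism is testable end to end.
See `docs/methods.md` for the full model description and design decisions.

## Worked example

```python
import numpy as np
import mscaseg as m

# a 96³ phantom with noise, plus exact labels
volume, labels = m.generate_phantom(m.PhantomConfig(shape=(96, 96, 96)), seed=1)

# the first 200 iterations of the reference schedule (≈4 min on one CPU)
train_cfg = m.TrainConfig(patch_size=32, batch_size=4,
                          max_epoch=500, iters_per_epoch=250,
                          max_iterations=200, seed=0, augment=())
net, log = m.train([(volume, labels)], train_cfg, m.ArchConfig.tiny())

# whole-volume sliding-window inference and evaluation
pred = m.predict(net, volume, train_cfg)
report = m.evaluate_segmentation(pred, labels)
for name, dice in report.dice_pct.items():
    print(f"{name}: Dice {dice:.1f}%  HD95 {report.hd95_mm[name]:.2f} mm")
```

Output from this exact run (see `examples/04_train_and_evaluate.py`):

```
CSF: Dice 94.5%  HD95 1.41 mm
GM: Dice 86.7%  HD95 35.81 mm
WM: Dice 91.3%  HD95 48.26 mm
```

Dice is the percent overlap with the exact phantom labels per tissue class;
HD95 is the 95th-percentile boundary distance in millimetres.  After only
200 iterations the CSF boundary already lands within about one voxel; the
large GM/WM HD95 values show how the metric punishes the residual scatter
of misclassified voxels far from the true structures — more than 5% of the
mask voxels must sit that far out for the 95th percentile to reach them,
which is exactly the undertraining the short schedule leaves behind.  The
quality-weighting mechanism is demonstrated in
`examples/02_quality_weights.py`: the mean patch weight W falls
monotonically as label corruption grows.

A thin CLI wraps the same functions:

```bash
mscaseg phantom --seed 1 --out-image img.nii.gz --out-labels lab.nii.gz
mscaseg describe --tiny
mscaseg qc-score img.nii.gz lab.nii.gz --patch-size 32 --out qc.csv
mscaseg train --config cfg.yaml --image img.nii.gz --labels lab.nii.gz \
              --checkpoint net.npz
mscaseg predict net.npz img.nii.gz --out pred.nii.gz
mscaseg evaluate pred.nii.gz lab.nii.gz --out-csv report.csv
```

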