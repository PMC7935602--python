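# advseg — adversarially trained 3D cardiac segmentation

`advseg` is a volumetric segmentation toolkit for cardiovascular MR:
it labels every voxel of a 3D volume as background, **myocardium** or
**blood pool**. Automating this segmentation matters because building
patient-specific 3D heart models for surgical planning in congenital
heart disease currently requires slow manual contouring, and the
myocardium — a thin, tortuous wall with weak contrast against
neighbouring structures — is the hard class.

The core idea is to train a 3D U-Net-style encoder-decoder **S**
against a small VGG-style convolutional discriminator **D** that sees
the image together with a segmentation and predicts whether that
segmentation is a manual annotation. The segmenter minimises

    J = J_CE + α · J_adv

where `J_CE = −(1/N) Σ_classes Σ_i g_i ln p_i` is the voxel-wise
cross-entropy against the one-hot annotation and
`J_adv = −E[ln D(x, S(x))]` is the non-saturating adversarial term
(α = 0.15 by default; α = 0 is the pure cross-entropy baseline). The
discriminator minimises the binary cross-entropy
`−ln D(x, y) − ln(1 − D(x, S(x)))`; the two networks are trained in
alternation with Adam (lr 0.001). The discriminator acts as a learned,
global shape-consistency loss that complements the purely local
cross-entropy — which is precisely where the thin myocardial shell
benefits.

Training and inference operate on 64³ blocks: random, augmented blocks
during training (axial-plane rotations and through-plane flip);
a regular overlapping grid at inference, with overlapping probability
maps averaged and labels taken per-voxel by argmax. Evaluation uses the
Dice coefficient `DSC = 2|X∩Y| / (|X|+|Y|)` per foreground class.

Everything — the networks, backpropagation, Adam — is implemented in
NumPy with numba-JIT convolution kernels, so the package runs anywhere
scientific Python runs, CPU-only. Volumes are read and written as
NIfTI via nibabel. A built-in phantom generator produces cardiac-like
test volumes (bright multi-lobed pool, thin intermediate-intensity
shell, noise, smooth bias field) so the whole pipeline is testable
without any data download; see `docs/methods.md` for what the phantoms
do and do not emulate.

## Worked example

Train the baseline and the adversarial arm on generated phantoms and
compare held-out Dice (this is the package's ablation driver; ~4 min on
one CPU core):

```python
from advseg import RunConfig, generate_dataset
from advseg.phantom import PhantomSpec
from advseg.training import ablation

cases = generate_dataset(8, seed=1, spec=PhantomSpec(shape=(64, 64, 64)))
config = RunConfig(patch_size=32, stride=16, batch_size=4, steps=100,
                   scales=2, base_channels=8, disc_channels=(8, 16, 32, 32),
                   seed=1)
for row in ablation(cases, config, alphas=(0.0, 0.15), n_holdout=2):
    print(f"{row['arm']:<12} myocardium {row['dice_myocardium']:.3f}  "
          f"blood pool {row['dice_blood_pool']:.3f}")
```

```
baseline     myocardium 0.862  blood pool 0.955
adversarial  myocardium 0.855  blood pool 0.935
```

Both arms segment the bright, simply-shaped blood pool nearly
saturated, while the thin myocardial shell is the harder class — the
structural pattern that motivates the adversarial term. At this desk
scale the two arms are statistically close; the directional comparison
(adversarial not worse than baseline) is what the acceptance suite
checks across seeds.

The same estimator is available with a scikit-learn interface:

```python
from advseg import AdversarialVolumeSegmenter

est = AdversarialVolumeSegmenter(alpha=0.15, scales=2, base_channels=8,
                                 patch_size=32, stride=16, batch_size=4,
                                 steps=100, random_state=1)
est.fit([c.volume for c in cases[:6]], [c.labels for c in cases[:6]])
labels = est.predict([cases[6].volume])[0]      # LabelMap, values {0,1,2}
```

A `click` CLI mirrors the library: `advseg phantoms` (write a phantom
dataset as NIfTI pairs + manifest), `advseg train`, `advseg predict`,
`advseg evaluate` (TSV Dice report with voxel counts), and
`advseg ablation`.

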