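# jellydet

Underwater image enhancement and jellyfish detection at desk scale.

Jellyfish blooms are a recurring hazard for coastal ecosystems, power-plant
intakes and aquaculture, and optical monitoring is the only modality that can
tell species apart in real time. Two things make it hard: the water column
degrades every frame (wavelength-dependent color loss, veiling haze, blur,
sensor noise), and the targets are translucent, overlapping and often small.
`jellydet` implements both halves of a detection system for this setting:

* **Enhancement.** An improved underwater enhancement pipeline that runs a
  Multi-Scale Retinex with Color Restoration (MSRCR) branch and a
  denoise/contrast branch in parallel, then merges them by weight-map
  Laplacian-pyramid fusion. The classical comparators — dark-channel-prior
  dehazing, guided-filter contrast enhancement, plain MSRCR, and classic
  underwater fusion — are implemented alongside, plus the four no-reference
  quality metrics used to rank them (Entropy, UCIQE, UIQM, EOG).
* **Detection.** A YOLOv4-tiny–style two-scale detector (CSPDarknet-tiny
  backbone) with a Convolutional Block Attention Module (CBAM) inserted after
  the upsampling step, trained with mosaic augmentation, label smoothing
  (ε = 0.01), a cosine-annealed learning rate and Adam, and scored with
  per-class AP, mAP, precision, recall and F1.
* **Synthetic data.** A generator of annotated underwater-style scenes
  (elliptical, tentacled targets over a water gradient, 7 jellyfish classes +
  fish) degraded by the parametric formation model `I = J·t + A·(1−t)`, so the
  dehazer can be tested as a parameter-recovery problem against known ground
  truth.

The whole stack is pure scientific Python (numpy/scipy/scikit-image; the
network and its training run on a small in-repo reverse-mode autodiff engine),
so everything is reproducible on one CPU.

## The core models

**Haze formation and its inverse.** A degraded frame obeys
`I_c(x) = J_c(x)·t(x) + A_c·(1−t(x))` per channel `c`, where `J` is the clean
scene, `t ∈ [0,1]` the transmission and `A` the veiling light. The
dark-channel prior (`min_c min_patch J_c/A_c ≈ 0`) gives
`t̂ = 1 − ω·dark(I/Â)`, refined by a guided filter, and the scene is recovered
as `Ĵ = (I − Â)/max(t̂, t₀) + Â`.

**MSRCR.** Per channel `i`:
`R_i = Σ_k w_k·[log(I_i+ε) − log(G_{σ_k} * I_i + ε)]`, scaled by the color
restoration factor `C_i = β·[log(α·I_i) − log(Σ_j I_j)]`, followed by a
1%/99% percentile stretch. Defaults: σ = (15, 80, 250), equal weights,
α = 125, β = 46.

**Fusion.** Each branch gets per-pixel contrast (|Laplacian of luminance|),
saliency and saturation weights, normalized across branches to sum to 1; the
branches' Laplacian pyramids are blended under the Gaussian pyramids of the
weights and reconstructed.

**Detection.** Two heads at strides 32 and 16 predict 3 anchors × (5 + K)
channels; CBAM gates the upsampled coarse features channel-wise then
spatially before they merge with the fine passthrough. Training uses
1 − CIoU for assigned anchors, binary cross-entropy objectness with an
ignore band, and class BCE against `(1−ε)·onehot + ε/K` targets.

## Worked example

```bash
jellydet demo --n 30 --steps 50 --seed 1 --out demo_out
```

generates 30 degraded annotated scenes (split 25/2/3 following the
80.45/8.95/10.61% train/valid/test proportions), enhances the test split,
trains a quarter-width smoke model for 50 steps, detects, evaluates, and
prints:

```
{"splits": {"train": 25, "valid": 2, "test": 3},
 "mean_entropy_gain": 2.2759095766349164,
 "final_loss": 5.544829368591309,
 "test_mAP": 0.0}
```

`demo_out/metrics.csv` holds the Table-style quality comparison on the test
images:

```
method,entropy,uciqe,uiqm,eog
identity,5.1668,0.2668,0.8693,47.01
improved,7.4427,0.4912,1.1216,997.11
```

Reading: the improved pipeline raises the gray-level entropy of the degraded
inputs by ≈ 2.3 bits and the gradient energy (EOG) ≈ 20-fold — the same
directional ordering that motivates fusing MSRCR with a contrast branch.
`loss.csv` shows the composite YOLO loss falling from ≈ 9 to ≈ 5.5 over the
50 smoke steps; a 50-step run is a plumbing check, not a trained detector,
so the test-split mAP of 0 is expected (the suite's 200-step single-image
overfit run reaches mAP@0.5 = 100, which is the capacity check).

Individual stages are available as `jellydet simulate | enhance | metrics |
train | detect | evaluate`; see `--help` for the options of each.

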