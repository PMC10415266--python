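# Methods

This note documents the models implemented in `jellydet`, the defaults and
why they were chosen, what the synthetic scenes do and do not emulate, and
the numerical conventions that make the test suite exact.

## Degradation model and synthetic scenes

Underwater optics are modelled with the standard single-scattering formation
model, applied in float [0,1]:

    I_c = a_c · J_c · t + A_c · (1 − t),   c ∈ {R,G,B}

followed by optional Gaussian blur (`blur_sigma`, px) and additive Gaussian
sensor noise (`noise_sigma`), clipped to [0,1]. `t` is the transmission
(scalar or per-pixel map), `A` the veiling light, and `a` a per-channel
attenuation factor modelling wavelength-selective absorption (red is lost
first in water, so realistic presets use `a_R < a_G < a_B`). Quantization to
8 bits happens only at file write, which keeps inversion tests exact.

Scenes are water-color gradients with elliptical, tentacled targets drawn
from a fixed 8-class palette (seven jellyfish species plus a fish disruptor
class). Targets may overlap and extend out of frame so the detector sees
occlusion and clipped boxes. Boxes are tight to the rasterized target
extent, in 0-based half-open pixel coordinates; Pascal-VOC writers convert
to that format's 1-based inclusive dialect at the file boundary.
`make_dataset` splits 9594/1067/1265 out of 11,926 by default
(floor(n·f) with the remainder assigned to training) and writes PNG + VOC XML
+ YOLO-txt + a JSON manifest.

What the generator does *not* emulate: photometric realism (no refraction,
caustics, particulate backscatter point-spread), real jellyfish morphology,
or label noise. Passing tests therefore demonstrate algorithmic
correctness and the right directional behaviour under a controlled
degradation model — not field performance on ocean footage.

### Dehazing fixtures and the prior's validity

The dark-channel prior assumes each patch of the *clean* scene contains a
near-zero channel minimum, and airlight estimation assumes some region
carries the veil color. The dedicated dehazing fixture (`haze_test_scene`)
realizes both conditions the way real water does: a bright surface band at
the top whose color equals the ambient light (its thickness is exactly one
dark-channel patch radius, enough for an unbiased airlight estimate), a
gradient into dark deep water, and sparse near-black detritus speckles
(density 0.02) below the band. Under these conditions, constant-transmission
degradations with t between 0.3 and 0.9 are inverted at ≥ 25 dB PSNR. On
scenes violating the prior (for instance a bright veil-colored object with
constant transmission behind it), dark-channel dehazing is biased — a known
limitation of the method, not of the implementation.

## Enhancement

* **MSRCR** — scales σ = (15, 80, 250) px with equal weights, color
  restoration α = 125, β = 46, log-offset ε = 1/255, per-channel 1%/99%
  percentile stretch; a flat map stretches to mid-gray 0.5. These are the
  canonical retinex-literature values; gain/offset default to (1, 0) since
  the stretch absorbs them.
* **Dark-channel dehazing** — patch 15, ω = 0.95, t₀ = 0.1, airlight from
  the brightest 0.1% of dark-channel pixels (mean color), guided-filter
  refinement with radius 40 and eps 1e-3.
* **Guided filter** — box windows of size 2r+1; when `var + eps = 0` the
  local slope is defined as 0 (output falls back to the window mean), which
  makes the eps = 0, guide = src case an exact identity.
* **Contrast branch** — self-guided filtering (r = 2, eps = 1e-3) for
  denoising, adaptive histogram equalization (clip limit 0.01) on the
  luminance channel followed by a 1%/99% stretch, chroma preserved by
  luminance rescaling. Images smaller than 16 px skip the tiled
  equalization.
* **Fusion** — contrast = |Laplacian of luminance|, saliency = distance of
  the blurred color from the image mean color, saturation = RGB standard
  deviation around luminance; raw sums regularized by δ = 1e-3 and
  normalized across inputs. Pyramid depth 5 by default, automatically
  reduced to ⌊log₂ min(H, W)⌋. Blending uses a Gaussian-smoothed zoom
  pyramid; reconstruction is exact by construction, so identical inputs (or
  degenerate 1/0 weights) reproduce the input to machine precision.
  Multi-scale blending is only approximately range-preserving: around step
  edges where the weights switch, ringing of a few hundredths occurs (the
  band-limited-input tests bound it at 0.02; the final clip to [0,1] is the
  safety net on hard content).
* **Improved pipeline** — fuses the MSRCR branch with the contrast branch.
  The choice of these two branches (rather than fusing with the original) is
  a design decision: the two branches have complementary failure modes
  (color recovery vs texture recovery), which is what the fusion weights
  exploit.
* All filtering uses edge-replication padding and luminance
  Y = 0.299R + 0.587G + 0.114B, one convention everywhere.

## Quality metrics

Entropy is Shannon entropy of the 256-bin gray histogram (bits). EOG is the
*mean* (not summed) squared forward difference over pixels having both
neighbors, making it resolution-independent; it uses the 0-255 gray scale.
UCIQE = 0.4680·σ_chroma + 0.2745·con_l + 0.2576·μ_sat with CIELab
quantities divided by 100, con_l the 1%-99% lightness spread, and saturation
chroma/lightness (zero-lightness pixels contribute 0). UIQM = 0.0282·UICM +
0.2953·UISM + 3.5753·UIConM with 0.1/0.1 α-trimmed colorfulness statistics,
Sobel-based block EME sharpness, and Michelson-entropy block contrast; 8×8
blocks, partial edge blocks dropped, degenerate blocks contribute 0. Whether
these conventions reproduce any particular published table depends on the
image set; within this package they are fixed, deterministic, and verified
against naive loop implementations.

## Detector

Full-scale configuration: 416×416 input, CSPDarknet-tiny backbone (three
cross-stage-partial stages with half-channel splits and 2×2 max-pools),
512-channel tail, heads at strides 32 (13×13) and 16 (26×26) each predicting
3 anchors × (5+K) channels, K = 8. Exactly one CBAM (reduction 16, spatial
kernel 7) sits immediately after the ×2 nearest upsample, before
concatenation with the 256-channel stage-3 passthrough — re-weighting the
coarse semantic features before they are mixed with fine detail, which is
where a tiny two-scale network most under-serves small and occluded targets.
Activations are LeakyReLU(0.1); batch normalization follows every
convolution except the 1×1 head outputs. Anchors default to the canonical
tiny set ((10,14),(23,27),(37,58) / (81,82),(135,169),(344,319)). The
full-width model has 5,892,569 parameters (logged, not asserted — layer
counting conventions differ between frameworks). Inference defaults:
decode confidence 0.5, per-class NMS at IoU 0.45.

The network runs on `jellydet.nn`, a reverse-mode autodiff engine over
numpy (im2col convolution, pooled/upsampled spatial ops, batch norm,
attention gates); every operator is finite-difference checked in the suite.

## Training recipe

Composite YOLO loss: 1 − CIoU for anchor-assigned positives (anchor chosen
by best width-height IoU across both scales, cell by box center); objectness
BCE over all cells with positives 1, negatives 0, and an ignore band where a
decoded prediction overlaps any ground truth above IoU 0.5 without being
assigned; class BCE against label-smoothed targets (ε = 0.01 — the bell
shapes of several species are nearly indistinguishable, so hard labels
overstate annotator certainty). The CIoU aspect term's weight α is treated
as a constant during differentiation, as is standard. Box and class terms
are normalized by the number of positives, objectness by cell count.

Mosaic augmentation stitches four flipped, HSV-jittered (hue ±10°,
saturation/value ±30%), zoomed (1.0–1.5×) and cropped samples into the four
quadrants of a canvas split uniformly in the central 40-60% of each axis;
transformed boxes are clipped to their quadrant and dropped below 25%
surviving area. Mosaic applies with probability 0.5 per sample when enabled.
Cosine annealing runs from `base_lr` to `base_lr/100` (the floor is a
package choice; only the schedule's shape is canonical). Optimizer is Adam.
Full-scale defaults follow the reference recipe (base_lr 1e-4, batch 16 for
the improved configuration, 4 for baselines).

### Desk-scale problem sizes

Smoke runs use a quarter-width model at 96 px input with anchors matched to
the generator's target statistics, batch 4, and base_lr 1e-3 — a learning
rate scaled up because a 50-200-step run must traverse in hundreds of steps
what full training does in thousands of epochs. These sizes keep a full
train/evaluate cycle in tens of seconds on one CPU while preserving every
code path (CSP splits, CBAM, both heads, mosaic, schedule, loss). They are
capacity and correctness checks: a 50-step run decreasing its loss and a
200-step single-image run reaching mAP@0.5 = 100 demonstrate that the
gradients, target assignment and decoding agree end-to-end, not that the
model is field-ready.

## Evaluation

AP uses all-point interpolation (area under the monotone envelope of the
precision-recall curve) at IoU 0.5, greedy one-to-one matching per class in
confidence order; a class with detections but no ground truth scores 0;
mAP averages over classes present in ground truth or detections.
Precision/recall/F1 are micro-averaged at confidence 0.5. The report never
contains a field named "accuracy": mAP and precision are kept explicit and
separate. FPS can be measured (`measure_fps`) but is informational only —
it reflects hardware, not correctness — and is excluded from all assertions.

## Known limitations

* The enhancement pipeline's absolute metric values depend on image content;
  only the directional ordering (improved > degraded inputs in entropy and
  EOG) is asserted, on the generator's scenes.
* Dark-channel dehazing requires its prior; scenes violating it (uniform
  bright scenes, veil-colored objects) are restored with bias.
* The numpy engine favors clarity over throughput: full-scale 416-px
  training is out of its intended envelope; full-width inference runs at
  seconds per frame, so real-time frame rates are outside its envelope.
* Mosaic HSV jitter operates in float RGB↔HSV, which can slightly shift
  colors of saturated pixels relative to integer implementations.
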