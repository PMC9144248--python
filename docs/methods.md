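# Methods

## Problem and model

The package segments paired short-axis cardiac MR slices of two
contrasts — a cine-SSFP-like image and an LGE-like image of the same
anatomy at the matched cardiac frame — into background, left
ventricular cavity (LVC, label 1; papillary muscle counts as cavity),
left ventricular myocardium (LVM, label 2) and right ventricle (RV,
label 3, wall plus cavity).

Two architectures are provided. The single-image UNet is the
conventional 2D design: at each of `depth` levels (default 4 at desk
scale, 5 at full scale) a block of two 3×3 convolutions, each followed
by batch normalization (optional) and ReLU; 2×2 max pooling between
encoder levels; a 2×2 stride-2 transposed convolution per decoder
level; skip connections by channel concatenation between equal levels;
and a 1×1 convolution + per-pixel softmax head. Channel width starts at
`base_channels` and doubles per level.

The MI-UNet runs one such stream per contrast with **separate encoders
and decoders**. At the join level (default: the deepest level, the
bottom of the "U") the two encoders' feature maps are summed
elementwise and pass through a single shared block, giving the two
streams a common deep embedding. Decoder skip connections come only
from the stream's own encoder (or from shared levels when `join_level`
is moved above the bottleneck, in which case the shared encoder levels
feed both decoders). The additive join requires equal channel counts,
which holds because both streams use one configuration; no adapter
convolution is inserted. The two softmax outputs are never fused: the
model always yields one mask per contrast.

With `join_level < depth` the levels from the join downward behave as a
single-input UNet over the summed features. The join level is exposed
as a searchable hyperparameter because the best placement is
data-dependent; the default shares only the bottleneck.

## Objective

For each branch the segmentation loss is `λ₁·L_DSC + (1−λ₁)·L_BCE`.

- `L_DSC(x, x̂) = 1 − 2Σxᵢx̂ᵢ / (Σxᵢ² + Σx̂ᵢ²)` — the soft Dice loss
  with *squared* sums in the denominator. Multi-class probability maps
  are scored one-vs-rest per channel and averaged over the three
  foreground channels only; including the dominant background channel
  would saturate the term. Both-empty inputs score 0 (perfect).
- `L_BCE` — binary cross-entropy, averaged over all elements (the mean,
  not the sum), with probabilities clipped to `[1e-7, 1 − 1e-7]` before
  any logarithm. For multi-class maps it averages over all four
  channels.
- `λ₁` defaults to 0.5 (no principled asymmetry between the terms at
  phantom scale); it is a constructor parameter and grid-searchable.

The joint objective adds two coupling terms to the sum of the branch
losses:

- **Total variation** `TV(x) = (1/N)Σ|Δx|`, realized as forward
  differences along both axes with replicated edges (zero difference at
  the last row/column), applied to each foreground probability channel
  and averaged. It penalizes ragged segment boundaries. Weight `λ_TV`,
  default 0.15.
- **Cross-contrast consistency** — the BCE evaluated with the cine
  probabilities as prediction and the LGE probabilities as a *soft*
  target, averaged over all channels. Gradients flow into both branches
  by default; `stop_gradient ∈ {none, lge, cine}` exposes the
  alternative reading in which the high-SNR contrast acts as a fixed
  prior. Weight `λ_Sp`, default 0.5.

With `λ_TV = λ_Sp = 0` the objective reduces exactly to the sum of the
two branch segmentation losses; the tests assert this identity and
check every term against independent scalar-loop oracles and
finite-difference gradients (central differences, h = 1e-4, relative
tolerance 1e-3).

## Compute backend

Networks are built on `miunet.nn`, a compact reverse-mode autodiff
engine over numpy arrays written for this package. Convolutions are
evaluated as one GEMM over an `as_strided` im2col view; batch
normalization is a fused primitive with a hand-derived backward rule
(validated against a composed-op reference); max pooling uses a
first-match tie-break. Model weights are float32; weights draw from a
zero-mean normal whose per-layer std follows He scaling
(`sqrt(2/fan_in)`, the default) or a fixed configurable σ, biases zero,
all from a seeded generator. He scaling is the default because a fixed
small σ left desk-scale training one-in-several-runs fragile: a stream
could sit near-background for the whole budget. Training uses Adam with
standard coefficients. Everything is
deterministic given (config, seed): weight init, epoch shuffles and
augmentation angles derive from independent streams of one seed
sequence, so reruns are bit-identical.

## Phantom simulator

The generator emulates the statistical structure the method assumes,
not MR physics. Geometry: a disc LVC, an annular LVM whose septal
sector (the sector facing the RV) is thickened by a factor ≥ 1 to mimic
the asymmetric hypertrophy of HCM, and a crescent RV hugging the
epicardium over a configurable angular extent. Parameters are drawn
uniformly from configured ranges; the defaults at 128 px (LVC radius
14–22 px, wall 6–10 px, septal factor 1.2–2.0, RV extent 1.6–2.6 rad)
scale linearly to other frame sizes.

Contrast presets map classes to intensities in [0, 1]:

| class      | SSFP-like | LGE-like |
|------------|-----------|----------|
| background | 0.05      | 0.05     |
| LVC blood  | 0.90      | 0.80     |
| LVM        | 0.40      | 0.15     |
| RV         | 0.80      | 0.70     |
| noise σ    | 0.02      | 0.15     |

so the SSFP-like image has high blood/myocardium contrast and high SNR,
while in the LGE-like image the nulled myocardium sits only ~0.7 noise
standard deviations above background — per-pixel delineation of the
wall is genuinely poor, as it is clinically, and segmenting it requires
shape context. (Blood/myocardium separation remains ~4σ.) An earlier,
milder noise level left the LGE contrast trivially learnable at study
scale, which collapsed the single-vs-joint comparison into ties at
ceiling; the preset was corrected to honor the low-SNR design goal. 1–3 bright patches (boost 0.35–0.55, radius capped by the
local half-wall so they stay inside the LVM) are rendered only in the
LGE image, emulating patchy enhancement. Noise is additive Gaussian —
not Rician — because the method is noise-model-agnostic and σ is simply
the SNR control. Optional misregistration is a rigid integer-pixel
translation of the LGE image and mask (frames are assumed matched, so
small shifts suffice to exercise the consistency term); out-of-frame
pixels refill as background.

What the phantoms do *not* emulate: real anatomical shape variability,
partial-volume and bias fields, Rician noise statistics, papillary
sub-structure, through-plane effects. Passing the synthetic studies
therefore demonstrates the *mechanics* of joint training — that the
shared embedding and consistency term behave as designed — not clinical
segmentation accuracy.

## Preprocessing

Real images go through: zero-pad to square (content centered, odd
deficit padded bottom/right) → centered crop by `crop_fraction`
(default 0.5 *per linear dimension*, i.e. 25 % of the area; the
fraction is configurable since "crop by 50 %" is ambiguous) → Gaussian
anti-aliasing with σ = 0.6 × the decimation factor followed by uniform
subsampling to `target_size` (default 128). The σ coefficient is chosen
so a unit impulse retains 1/factor² of its energy after 2× decimation
to well under 2 % at any sampling phase; a unit ratio bypasses the
filter. Masks follow the same geometry with nearest-neighbor variants
(no low-pass), so integer labels survive and the label set never grows.
Augmentation rotates image (bilinear, zero fill) and mask
(nearest-neighbor) about the frame center by angles drawn uniformly
from ±60°; in joint training both members of a pair always receive the
same angle. DICOM series are ordered by InstanceNumber and min-max
rescaled to [0, 1] per slice (a configurable choice; no bias-field
correction is attempted).

## Training protocol and study sizes

Estimators follow the sklearn contract. The fixed-epoch loop logs the
full per-term loss breakdown every epoch and, when a validation set is
given, per-contrast validation Dice; the best-validation-Dice
checkpoint is restored at the end (`select_best`), mirroring
validation-driven model selection. Transfer learning pretrains a UNet
on one contrast and fine-tunes the whole network (no freezing) on the
other. Grid search evaluates every combination (batch size within
2–24, learning rate within 1e-6–1e-1, batch norm, constraint weights,
join level), maximizes validation mean Dice, and breaks ties toward the
lower learning rate, then the smaller batch.

The predefined synthetic studies (`miunet.experiments`) run at a
desk-scale working point: 60/10/20 anatomies at 64×64, depth 4, base
width 8, 20 epochs, batch 6, Adam at 3e-3. The learning rate was
selected for reliability: 1e-2 converged fastest but occasionally
collapsed a run outright, while 3e-3 with He initialization converged
within the 20-epoch budget at every probe seed. Augmentation is off in
these studies — the phantom generator already samples fresh anatomies,
so rotation copies add cost without changing the comparison.

The consistency study uses a smaller setting (24/6/10 at 48×48, depth
3, 10 epochs) and, crucially, a 1–2-pixel rigid misregistration between
the contrasts. With perfectly co-registered phantoms the two streams of
an unconstrained MI-UNet already agree to within about 1% of pixels, so
the effect of λ_Sp on agreement drowns in seed noise; under a small
misregistration the streams' own targets disagree — the regime the
consistency term exists for — and raising λ_Sp from 0 to 0.5 reduces
held-out inter-contrast mask mismatch consistently across seeds.

## Evaluation

Reported Dice is the *hard* coefficient `2|A∩B|/(|A|+|B|)` on argmax
masks (ties at the argmax go to the lower label, so uniform
probabilities predict background); the soft squared-denominator form is
used only as a training loss. Both-empty masks score 1.0. Reports list
per-slice per-structure Dice, per-structure mean ± SD, and a "Mean" row
of per-slice structure-means; SDs are per-slice sample SDs (n−1).
Model comparisons use paired two-tailed t-tests at the 5 % level on
per-slice scores, pairing by slice: `t = mean(d)/(sd(d)/√n)`, df = n−1,
two-tailed p from the Student-t survival function (cross-checked
against an independent statistical routine). All-zero differences give
t = 0, p = 1; zero-variance nonzero-mean differences report p = 0 with
a degeneracy flag.

## Numerical choices and degenerate inputs

- Probability clip ε = 1e-7 before logarithms; losses are finite for
  any input in [0, 1].
- Soft Dice on two empty vectors is 0 (loss form) / hard Dice 1.0
  (score form) — agreement on absence is perfect.
- Odd padding/crop remainders go to the bottom/right, deterministically.
- Batch-norm: momentum 0.1, eps 1e-5; evaluation uses running
  statistics.
- Archives and checkpoints are zip containers with fixed member
  timestamps so identical content is byte-identical — `np.savez` stamps
  wall-clock times and cannot honor the reproducibility contract.

## Known limitations

- Phantom realism, as above: results bound the method's mechanics, not
  clinical performance. The SSFP-like contrast saturates (Dice ≈ 1.0)
  for every model; on the noisy LGE-like contrast the joint model's
  gain over the single-contrast UNet is consistent in direction but
  modest in size at this scale. The studies assert direction, not
  magnitude.
- The desk-scale networks (~120k parameters) are far from the
  full-scale configuration (depth 5, base 64, tens of millions of
  parameters); the full-size network is constructed and counted
  analytically in tests but not trained.
- Single-process CPU training only; no mixed precision, no
  distribution.
- The consistency term assumes co-located pairs; large misregistration
  (≥ 1/8 of the frame) is rejected rather than compensated.
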