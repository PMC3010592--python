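# Methods

## Model

`foldlight` operates on low-resolution RGB pre-scan images of stained
histology slides, represented internally as H×W×3 float arrays on the unit
cube (8-bit inputs divided by 255, 16-bit by 65535; conversion happens only
at the I/O boundary). Two per-pixel quantities are computed from the
original image:

- saturation `S = 1 − 3·min(R,G,B)/(R+G+B)`, the HSI chromaticity
  (distance from the gray line R = G = B), with `S = 0` assigned at the
  black singularity `R+G+B = 0` — black is achromatic, and a finite value
  keeps downstream arithmetic NaN-free;
- luminance `V = (R+G+B)/3`, the channel mean.

The physical premise is that a fold is a doubled-over, hence thicker,
piece of section: it absorbs more dye, so it is darker (lower V) and more
strongly saturated (higher S) than the adjacent single-thickness tissue,
while glass background is bright and nearly achromatic. The difference
`f_sv = S − V` therefore separates folds (positive) from tissue and
background (negative) independently of hue, which is what varies with
staining batch and scanner color calibration.

The enhancement is a single pass that shifts all three channels of each
pixel by the same amount and clips to the cube:

    f'_k = clip(f_k + α·(S − V), 0, 1)

with S and V always taken from the original image, never iterated.
Consequences, all exact in the absence of clipping and verified by the
test suite:

- luminance change `dV = α(S − V)`;
- saturation change
  `dS = 3(3·min − T)·α(S−V) / (T·(T + 3α(S−V)))`, `T = R+G+B`, whose
  channel factor is never positive, so the sign of `α(S−V)` alone decides
  the direction: a positive shift brightens *and* desaturates, a negative
  one darkens and saturates;
- hue is exactly unchanged (channel differences are invariant under an
  equal shift), which is the source of the method's robustness to
  staining/scanner color variation.

Detection is purely per-pixel: fold ⇔ `dV > 0` strictly, with `dV`
measured on the clipped result (`dV = 0`, including the degenerate α = 0,
is non-fold). Clipping can shrink |dV| but never flip its sign, so the
detected mask is independent of α wherever no channel clips.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `alpha` | 1.5 | – | shift weight; 1.5 suits H&E, 1.2 IHC with light counterstain |
| `alpha_grid` | 0…3 step 0.25 | – | sweep grid for coefficient selection |
| `plateau_tol` | 0.01 | luminance per grid step | forward-difference threshold declaring the luminance plateau |
| `n_bins` | 64 | – | S−V histogram bins over [−1, 1] |

The sweep enhances a sample of fold pixel colors (500 single-pixel samples
is the conventional size) at each grid value and records their mean
enhanced luminance `mean_v` and the mean applied shifting factor
`mean_sv = α·mean(S−V)`. `mean_sv` is exactly linear in α; `mean_v` rises
until the samples' channels saturate at the top of the cube and then
plateaus. The recommended α is the first grid point whose forward
difference in `mean_v` drops below `plateau_tol`; "significant increase"
is not standardized anywhere, so the threshold is an explicit knob rather
than a hidden constant. If no plateau occurs on the grid the largest value
is returned with a warning flag. Note the plateau criterion is a forward
difference, so it can also fire on a *decreasing* curve (e.g. white
samples clipping toward black at the very first step) — that is the
correct degenerate answer: enhancing further changes nothing useful.

The enhanced S′−V′ of fold samples is deliberately *not* the recorded
sweep statistic: because a positive shift desaturates while it brightens,
S′−V′ falls with α; the quantity that grows linearly and is contrasted
with the luminance plateau is the applied shift α(S−V).

## Evaluation

Masks are compared with the overlap ratio `TP/(FN+TP+FP)` —
intersection-over-union of the fold sets. Conventions at the empty
boundary: both masks empty → 1.0 (perfect agreement on absence); exactly
one empty → 0.0. The S−V histogram operation bins `f_sv` separately over
fold and non-fold pixels on a fixed [−1, 1] range so that densities from
different images are comparable.

## Phantom generator

The generator emulates only the colorimetric structure the detector uses,
with fully known ground truth:

- near-white background (default mean (0.97, 0.97, 0.97), S−V ≈ −0.97);
- an irregular tissue blob (radial field plus smoothed Gaussian noise,
  thresholded), eosin-pink mean (0.91, 0.65, 0.76), S−V ≈ −0.61;
- fold ribbons: random-walk polyline spines dilated to a constant width,
  clipped to the tissue blob; dark purple mean (0.45, 0.20, 0.40),
  S−V ≈ +0.079 — deliberately a *small* positive margin, as real folds
  sit close to the decision boundary;
- optional nuclei speckle: per-pixel Bernoulli draws at rate
  `nuclei_density` over the tissue, dark hematoxylin purple
  (0.30, 0.15, 0.45), S−V ≈ +0.20, reproducing the detector's
  false-positive mode as isolated pixels.

Per-channel Gaussian color noise is truncated by re-clipping to [0, 1]
(sd defaults: background 0.01, tissue 0.02, fold 0.005, nuclei 0.02). The
fold sd is kept tight because the fold mean's S−V margin is small:
first-order error propagation gives sd(S−V) ≈ 2.7·sd per channel for the
fold color, so 0.005 keeps per-pixel sign flips at the ~6σ level and the
fold region sign-pure, matching the premise that a fold is a dense,
homogeneous structure. Specs whose *mean* colors violate the region sign
structure are rejected up front with the offending region named, and the
realized per-region mean signs are re-validated after drawing. Generation
is bit-for-bit reproducible from (spec, seed) via `numpy.random.default_rng`.

What the phantom does **not** model — and therefore what passing tests do
not show about scanned slides: optical blur and scanner PSF, JPEG
artifacts, illumination gradients, real stain co-localization, textured
chromatin, folds whose colorimetry violates the S > V premise (e.g. folds
brighter than tissue, where the method is known not to apply). Phantom
results demonstrate correctness of the algorithm, not clinical accuracy.

## Numerical choices and degenerate inputs

- Clipping to [0, 1] is the out-of-range policy (the bright "solid white"
  rendering of folds is clipping at the top face); the fraction of clipped
  channel values is reported as `clip_fraction` so the behavior is
  observable.
- The closed-form dS is returned as NaN where it is undefined
  (`T = 0` or `T + 3α(S−V) ≤ 0`) rather than raising, except achromatic
  pixels, which are 0 for every α: an equal shift keeps gray on the gray
  line. Minimum-channel ties are value-neutral in the formula (the three
  branches coincide), resolved in fixed order R, G, B.
- Hue uses the two-branch inverse-cosine HSI convention
  (`360 − acos(β)` when B > G), achromatic pixels mapped to 0. Hue never
  enters the method; it exists to make hue invariance testable.
- 8-bit round-trips quantize by at most 1/(2·255) per channel; pixels with
  |dV| below ~1/255 may flip classification across a save/load cycle. The
  disk-vs-memory detection agreement is therefore specified as ≥ 99.5% of
  pixels, not exact.

## Design notes

- S and V feeding the shift always come from the original image; the
  enhancement is one pass, not a fixed point.
- The detector has no spatial post-processing (no morphology, no minimum
  blob size) — it is strictly per-pixel, which is why isolated dark nuclei
  survive as false positives. Spatial filtering or channel-specific
  coefficients (α_R ≠ α_G ≠ α_B) would address this but are out of scope.
- Problem sizes in the test suite and acceptance script (100 random 64×64
  images for the analytic identities, 256–512 px phantoms, 500-sample
  sweeps) were chosen as the smallest sizes at which every property is
  exercised including clipping and confounders; all checks are exact or at
  1e-9 tolerances, so larger images add runtime without adding evidence.

## Known limitations

- The S > V premise fails for unstained or bleached folds and for stains
  whose folds brighten rather than darken; the method is then inapplicable
  by design.
- Nuclei false positives are inherent to the per-pixel rule.
- The α sweep recommendation depends on the representativeness of the
  fold samples; unrepresentative samples move the plateau.
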