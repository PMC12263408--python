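# Methods

## Scoring model

A photograph taken at maximal horizontal gaze shows one eye *abducting*
(rotating temporally, toward its lateral canthus) and the fellow eye
*adducting* (rotating nasally, toward its medial canthus). The severity
of a movement deficit is read from how far the pupil center falls short
of the movement's **target canthus**, normalized by the horizontal
canthal width:

    w  = |x_lateral − x_medial|
    R  = max(0, (x_pupil − x_target) · sign(x_other − x_target)) / w

where `target = lateral` for abduction and `medial` for adduction. The
signed form clamps an overshooting pupil (past the target canthus) to
`R = 0`, which keeps the score monotone at the anatomical extreme; a
pupil that never leaves the opposite corner gives `R ≈ 1` or above.
The integer score is the quartile bucket of `R`, with every boundary
belonging to the *lower* score (`R = 1/4 → 1`, `R = 1/2 → 2`,
`R = 3/4 → 3`). Only x-coordinates enter the ratio: the small vertical
disparity between medial and lateral canthi is deliberately ignored,
a known approximation of this scoring family.

Conventions: pixel coordinates are 0-based, origin top-left, x
rightward. Lateralities are anatomical; in an un-mirrored frontal
photograph the patient's right eye is the leftmost detection. Gaze
direction is supplied as metadata (`_gazeL`/`_gazeR` filename suffix or
a sidecar CSV), never inferred from the image.

## Detector

A single-stage anchor-based detector with joint landmark regression:

* **Backbone** — stride-2 convolutional stages (widths 8, 16, 32, 48,
  64); the last three stages feed a feature pyramid at strides 8, 16,
  32 via 1×1 lateral projections and nearest-neighbour top-down fusion.
* **Context modules** — per pyramid level, three parallel stacks of
  3×3 convolutions (receptive fields 3, 5, 7) concatenated back to the
  pyramid width, then ReLU.
* **Heads** — three 1×1 convolutions shared across levels emit, per
  anchor: two-class softmax logits, four box offsets, and six landmark
  offsets in the fixed order (lateral canthus, pupil center, medial
  canthus).
* **Loss** — per anchor `i`,

      L = L_cls(p_i, p_i*) + λ₁ p_i* L_box(t_i, t_i*) + λ₂ p_i* L_pts(l_i, l_i*)

  with softmax cross-entropy for classification and smooth-L1 (Huber)
  for both regressions on anchor-relative offsets (center shifts
  normalized by anchor size, log-scale width/height). Negative anchors
  contribute classification only; ignore-labelled anchors contribute
  nothing. Each head is averaged over its contributing anchors, so the
  reported components satisfy `total = cls + λ₁·box + λ₂·pts` exactly.
  No hard-example mining is used.
* **Assignment** — an anchor is positive when its best IoU reaches the
  positive threshold, negative below the negative threshold, ignored
  between; each ground truth additionally forces its argmax anchor
  positive.
* **Training** — SGD with momentum 0.9, weight decay 5·10⁻⁴, batch 4.
  The full-scale schedule runs 80 epochs: warm-up at 10⁻³ for 5 epochs,
  then 10⁻², divided by 10 at the start of epochs 41 and 51 ("after"
  a breakpoint means the next epoch). Inputs are grayscale,
  mean-subtracted with the training-set mean and scaled by 1/128 so
  gray levels enter at roughly unit amplitude.
* **Inference** — foreground scores are thresholded, boxes decoded and
  greedily NMS-suppressed (IoU 0.4), at most two detections kept, and
  laterality assigned by image position. Within each kept cluster the
  box and landmark regressions of all suppressed candidates are
  averaged weighted by score (cluster voting), which is markedly more
  stable than trusting the single top anchor.

Everything is plain NumPy: im2col + BLAS matmul convolutions with
hand-written backward passes, verified against finite differences to
~10⁻¹⁰ relative error.

## Augmentation

Training-time transforms run in a fixed order — random crop, aspect
padding, bounded random rotation, brightness, scaling to the input
size, mean subtraction — and every geometric step applies the *same*
affine map to pixels, boxes and landmarks (rotation uses one shared
matrix for resampling and coordinates, so they cannot drift apart).
Rotation draws an angle uniformly within ±40° about the image center
(edge-replicated border); if any landmark of any annotated eye leaves
the frame, the angle is redrawn up to 3 times, and if the last draw
still loses a landmark the rotation step is skipped for that sample.
"Usable" is read strictly: *every* landmark of *every* eye must remain
inside the image. Crops that would cut off a landmark are likewise
redrawn, falling back to no crop.

## Synthetic photographs

The generator emulates the capture protocol (frontal head-fixed
photographs, both eyes in frame, maximal left/right gaze): two almond
fissures — elliptical lid arcs meeting at the canthi, outlined by a
dark lid line — on a skin-toned background, a medial **caruncle** (the
fleshy nasal-corner body visible in real photographs; also the only
local cue that distinguishes the medial from the lateral corner of an
otherwise nearly symmetric fissure), and a dark iris/pupil disc whose
x-position encodes an exactly known canthal ratio. Per-subject geometry
(canthal width 62 ± 6 px, fissure height 30 ± 3 px, interocular
distance 110 ± 8 px, pupil radius 8 ± 1 px, canthal tilt ~2 px) varies
around defaults sized for a 256×128 px periocular canvas. Global
brightness jitter (±15 %) and additive Gaussian noise (σ = 3 gray
levels) make detection non-trivial; an optional epicanthal fold
occludes the medial corner photometrically without moving the
geometric ground truth.

Scores are planted by sampling the ratio uniformly *inside* the score's
quartile bucket with a 0.02 margin from every edge, so scoring the
ground-truth landmarks reproduces the planted score deterministically
(the closed loop is exact by construction and asserted for every
generated image).

What the simulator does **not** model: photorealistic texture, corneal
light reflexes, ptosis and lid-lifting, head tilt, vertical gaze,
demographic variation. Passing the recovery experiment therefore shows
that the detector/scoring/statistics chain is implemented correctly
and can be learned from images of this geometry — not that the trained
weights transfer to clinical photographs.

## Desk-scale calibration (the `tiny` profile)

The package default configuration keeps conventional values
(λ₁ = 0.25, λ₂ = 0.1, IoU bands 0.5/0.3, score threshold 0.5, two
anchor shapes per level, Huber β = 1). Training from scratch in a few
thousand SGD steps on 300 synthetic images is a different regime, and
the desk-scale profile recalibrates four things, each with a specific
failure it addresses:

* **Single anchor shape per level, IoU bands 0.55/0.45.** At inference
  the best-scoring anchor must carry trained regressors; with a wide
  ignore band the ranking winner regularly fell into untrained
  territory and produced arbitrary landmarks. The positive band is
  chosen to cover every anchor that can win, the ignore band kept
  narrow.
* **λ₁ = λ₂ = 1 and Huber β = 0.1.** The per-head average divides
  regression gradients by (positives × coordinates); with the
  conventional weights the effective step size never drives landmark
  errors below ~0.1 anchor units in the available steps. The sharp
  Huber transition keeps the gradient at full magnitude down to 0.1
  anchor units (~6 px), which is what pushes the pupil error to ~2–3 px.
* **Score threshold 0.05.** Without hard-example mining the softmax
  average is dominated by ~2,700 negatives per image against ~20
  positives, so even confident detections plateau near p ≈ 0.2. The
  two-eye protocol makes ranking (NMS + top-2) the operating rule; the
  threshold is only an abstention floor for empty or unusable frames.
* **24-epoch schedule** (warm-up 1 epoch at 10⁻³, base 10⁻², ÷10 at
  epochs 19 and 23): the 80-epoch schedule scaled to a run of ~5
  minutes on one CPU core. Profile augmentation is photometric only
  (brightness ±10 % + mean subtraction); the generator already varies
  brightness and noise, and the geometric pipeline is exercised by its
  own test suite.

With this profile (300 training / 60 held-out images, seed 1) the
held-out per-landmark MED is 1.4–2.7 px and end-to-end automatic
scores reach weighted κ ≈ 0.94 and Spearman ρ ≈ 0.97 against the
planted truth — the "high consistency" regime.

## Statistics

* **MED** — per (eye, landmark) group, the mean of per-image Euclidean
  distances between predicted and annotated coordinates; dispersion is
  reported both as the SD of per-image distances and as the SEM, since
  "mean ± dispersion" tables are ambiguous between the two.
* **Weighted kappa** — `κ = 1 − Σ(w·O)/Σ(w·E)` over the 4×4
  contingency table with marginal-product expectation; linear weights
  `w_ij = |i−j|` by default (natural for an ordinal scale with equal
  steps), quadratic available. If both raters are constant and
  identical, expected disagreement is zero and κ is defined as 1 with
  a warning. Bands: 1 complete agreement, [0.75, 1) high, [0.4, 0.75)
  moderate, (0, 0.4) low, 0 complete disagreement, < 0 below chance.
* **Spearman ρ** — Pearson correlation of tie-aware average ranks
  (via `scipy.stats.spearmanr`); undefined (reported explicitly) when
  either vector has zero rank variance.
* Significance testing (p-values) is out of scope: point estimates
  only.

All three are validated in the test suite against independent
brute-force oracles (explicit contingency-table loops, rank-then-
Pearson, scalar distance loops) and, for kappa, against
`sklearn.metrics.cohen_kappa_score`.

## Numerical and degenerate-input choices

* Zero canthal width raises a degenerate-geometry error; ratios are
  clamped at 0; negative ratios and out-of-range scores are rejected.
* Annotation files are written atomically (temp + rename) with sorted
  keys, so identical inputs give byte-identical files and interrupted
  runs never leave truncated output.
* All randomness flows through `numpy.random.Generator` seeded from the
  user-supplied seed (training derives independent child streams for
  weight init, data order and augmentation via `SeedSequence`); a fixed
  seed makes generation, training and inference bit-reproducible on a
  given machine.
* An image with no detection above the abstention floor yields
  `status=unscorable` rows; the run continues.
* With a single detection, laterality falls back to the image-midline
  rule (center-x < W/2 → patient-right).

## Known limitations

* The vertical component of ocular motility is not scored.
* The scoring rule ignores vertical canthal disparity (x-only).
* The synthetic domain is geometric, not photorealistic; recovery
  results bound implementation correctness, not clinical performance.
* Softmax confidences of the desk-scale detector are uncalibrated
  (ranking-based operation); calibrated probabilities would need
  balanced sampling or mining, which the loss deliberately omits.
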