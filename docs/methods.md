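# Methods

This note documents the models, parameter choices and numerical conventions
behind `cryopick`, and what its synthetic-data tests do and do not show about
real micrographs.

## Synthetic micrographs

`cryopick.synthetic` draws bright particles on a dark background
(`background_level` 0.2, `particle_intensity` 0.6, relative units), adds
bright irregular ice-like artifacts and optionally a linear illumination
gradient, then additive Gaussian noise. Particle shapes:

* **disc** — filled circle of diameter `particle_size`;
* **square** — axis-aligned filled square of side `particle_size`;
* **irregular** — union of 3–6 random overlapping ellipses inside the
  bounding size, a rough stand-in for ribosome-like projections.

Ice artifacts are unions of elongated bright ellipses (axes roughly
0.15–0.9 × particle size, intensity 1.2–1.5 × the particle level). They are
deliberately *not* disc-shaped: their role is to exercise false-positive
rejection, which requires them to be distinguishable in principle from
particles.

Centers are rejection-sampled (10 000-attempt cap, then an explicit placement
error) with a minimum separation (default 48 px for 28 px particles in a
360 × 360 field, i.e. non-overlapping, sparsely packed fields). SNR is defined
as var(clean signal)/var(noise); `target_snr` sets the noise standard
deviation from the measured clean-image variance. The default study condition
throughout the tests is **SNR 0.3 with 20 particles per 360² micrograph** —
well below visual detectability. `n_clipped_particles` places additional
particles within a quarter-size of the border so part of the shape is cut
off, emulating edge-truncated particles.

Everything is driven by one integer seed; identical spec + seed is
bit-identical.

**What this generator does not emulate:** contrast transfer function
oscillations, structured/correlated noise, carbon edges, particle overlap and
aggregation, intensity variation between particles, and realistic ice
texture. Passing the synthetic study therefore demonstrates the internal
consistency and noise robustness of the pipeline, not performance on real
EMPIAR data.

## Enhancement chain

Seven steps in fixed order: min–max normalization → percentile stretch
(1st/99th percentiles) → 256-bin global histogram equalization → adaptive
Wiener restoration (5 × 5 window, noise power = mean of local variances) →
CLAHE (clip limit 0.01, 8 × 8 tiles) → guided filter (radius 4, ε = 10⁻³,
self-guided) → grayscale opening + closing with a disc (radius 3). Each step
maps [0, 1] into [0, 1] and the output is re-clipped at every stage boundary
so composition is insensitive to range drift. The method defines the steps
but not their parameters; the defaults above are the standard values of each
filter's literature and are all exposed in `PreprocessParams`.

Degenerate inputs are defined explicitly: a constant image normalizes to
zeros and passes through equalization/CLAHE/Wiener unchanged; zero noise
power short-circuits the Wiener filter.

Training-time augmentation draws a Gaussian-mask SD uniformly from [0, 1] and
a mask size from {3, 5} (seeded), convolves the patch, and applies the guided
filter; SD → 0 degenerates to the identity kernel.

## Stage 1: unsupervised localization

* **Intensity clustering** — 1-D k-means (k = 2) on pixel intensity with
  deterministic quantile initialization (`n_init = 1`); the particle mask is
  the highest-mean cluster. Assignment depends on intensity only, so it is
  permutation-invariant by construction. Fewer than k distinct intensities is
  an error.
* **Superpixel variant** — SLIC over-segmentation (default 400 segments,
  compactness 0.1) followed by the same k-means on per-superpixel mean
  intensity; intended for irregular shapes whose intensity distribution is
  less bimodal.
* **Mask smoothing** — binary closing then opening with a disc of radius 2.
  The closing fills boundary concavities carved by noise; the opening removes
  thin tendrils that otherwise inflate the contour perimeter (and hence
  circularity) of genuine particles. Radius 2 cannot merge components
  separated by more than 4 px, far below the minimum particle separation.
* **Cleaning** — components smaller than `min_area` (default ¼ of the
  nominal particle area) or touching the border band are dropped; cleaning
  never increases the component count.

### Shape measurement conventions

* **Perimeter** is the step-length sum along the 8-connected outer contour
  (Moore tracing): axial steps count 1, diagonal steps √2; an isolated pixel
  has perimeter 1 by convention. This definition is frozen because
  circularity values are only reproducible relative to a fixed perimeter
  definition; the test suite checks it against an independently coded
  boundary walk to 10⁻⁹.
* **Feret diameters** project the four corners of every foreground pixel
  (via the convex hull) onto directions at 1° steps; an axis-aligned n × n
  square therefore measures exactly n along the axes and n√2 on the diagonal.
* **Circle detection** uses Hough-transform vote accumulation over the mask's
  edge pixels. Micrograph-level detection (`detect_circles_cht`) keeps
  normalized-vote maxima above 0.5 of the full circumference, deduplicated by
  center distance. Per-component perfect-circle *fitting* (`fit_circle_cht`)
  instead returns the global accumulator argmax with no vote threshold: the
  good/bad decision downstream is made by roundness and overlap, and a hard
  vote cutoff at component level silently discards most genuinely circular
  but noise-ragged masks.

## Stage 2: good/bad selection

* **Top views.** A component is good iff a circle was fitted, its
  circularity deviation |C − 1| lies within **2 ×** the batch-mean deviation
  |mean(C) − 1|, and its Jaccard overlap with the perfect circle rebuilt from
  the fit is ≥ 0.8. The band factor of 2 is a deliberate design choice: with
  a factor of 1 the batch-relative rule rejects the above-average half of
  even an all-good batch, because rasterized-disc deviations are strictly
  one-sided (C > 1). At factor 2 the roundness term acts as a gross-outlier
  filter (edge-clipped particles, fused masks, tendril artifacts) while the
  perfect-circle overlap does the fine discrimination. A half-disc clipped at
  the border overlaps its fitted circle at ≈ 0.5 and is always rejected.
* **Side views.** Components are square-like when the min/max Feret ratio
  falls in [0.6, 0.9] and the area reaches 0.8 × min-Feret². The ideal square
  ratio is 1/√2 ≈ 0.707; the upper bound is 0.9 rather than a tight 0.8
  because boundary raggedness at the study noise level inflates the measured
  min caliper of genuine squares to ≈ 0.76–0.88, while ideal discs measure
  ≈ 0.96–1.0 and remain excluded. Components whose max Feret exceeds 1.5 ×
  the batch median are removed as overlapped particles. Survivors are
  replaced by the perfect axis-aligned square built from their Feret minimum,
  centered on the centroid.
* **Irregular.** Good iff area ≥ 0.7 × batch mean area (rejects fragments)
  and the centroid lies in the central half of the extraction patch (rejects
  edge-cut particles).

Selection always partitions its input (good ∪ bad, no loss or duplication)
and is invariant to input order.

## Dataset generation

Good crops are taken from the *enhanced* micrograph — the classifier is
trained and applied on the same representation. Two consistency choices
matter for detection quality:

1. Training micrographs are rescaled with the same automatic rule used at
   test time, so training particles occupy the same fraction of the window
   (≈ 32/32 after up-scaling 28 px particles by 1.125) as test particles.
2. Crops are taken at the component centroid plus a uniform jitter of up to
   ± 4 px (half the default scan stride), so the classifier tolerates
   sliding-grid misalignment. A jitter-free dataset yields a slightly more
   accurate patch classifier but roughly halves detection recall.

Background crops are sampled to be disjoint from every detected component;
rejected components can be harvested as a fifth negative-detection class
(`include_negative=True`). In the synthetic study the four-class model
(three shapes + background) detects better than the five-class one — the
negative class overlaps the particle classes too heavily — mirroring the
class-ablation behavior reported for this family of methods.

Balancing: rotation augmentation (90/180/270°) when a class is short of the
target, then seeded subsampling to exactly the target. Split arithmetic:
test = n − floor(0.8 n), then validation = trainval − floor(0.8 · trainval);
at 1500 per class this gives exactly 960/240/300.

## Classifier

Layer chain and geometry are fixed by the published architecture; strides and
padding (4; pools stride 2; 'same' padding 2,1,1,1 on the later convs) are
the unique combination reproducing the printed feature-map sizes
55→27→27→13→13→13→13→6 from a 227 input. The output layer is a softmax over
the class count (the printed "1 × 1" output cannot carry a multi-class
cross-entropy). Activations are sigmoid, as specified by the method's
equations, with ReLU available as an option.

Implementation is numpy: im2col convolution, stride-tricks pooling (max by
default; the printed averaging formula is available as `pool_mode="mean"`),
manual backpropagation, summed cross-entropy with an L2 penalty and log floor
10⁻¹², and the η/N-scaled SGD update. Analytic gradients are checked against
central differences to 10⁻⁴ relative error.

Initialization: the printed uniform-[0, 1] scheme saturates sigmoid chains
and is kept only behind `init="unit"`; the default is Glorot-uniform with the
sigmoid gain of 4, which preserves signal variance layer to layer. The
network's preprocessing stage standardizes each input patch to zero mean and
unit variance. Both choices are what makes plain SGD on a sigmoid CNN
converge at all.

Reduced preset (`toy_arch`): 32×32×1 input, conv 8@5×5 p2 → pool 2 s2 →
conv 16@3×3 p1 → pool 2 s2 → FC 64 → softmax. Its training defaults
(`pipeline.TOY_TRAINING`: learning rate 0.5, per-epoch decay 0.9, batch 16,
20 epochs) were chosen for stable convergence of the sigmoid network on the
synthetic dataset; the published initial rate of 10⁻⁴ remains the
`TrainingConfig` default and is appropriate for the full-size preset. The
full Table-scale network is constructible and runnable but is not exercised
end to end in the test suite; all training runs use the reduced preset.

## Detection

Scaling selection: candidate factors are multiples of 0.125 (above 1 when
the average particle is smaller than the window, below 1 otherwise); the
chosen factor maximizes the rounded scaled particle size subject to it not
exceeding the window, with round-half-up rounding; when the smallest
up-factor already overshoots, no scaling is applied. This reproduces the
published decisions exactly: 320→0.625 (scaled 200), 94→2.375, 188→1.125
(scaled 212), 221→none (overshoot candidate 249).

Sliding-window stride defaults to window/4. Score-map cleaning joins
8-neighboring above-threshold grid positions whose scores differ by at most
0.2 (`closeness_tol`), drops regions larger than 2·(window/stride)² cells
(smeared false positives), and emits one candidate per region at its
maximum-score cell. NMS is greedy per class at IoU ≥ 0.3 with a deterministic
(score desc, x, y) tie rule, verified exactly against a quadratic reference.
Picking is per particle category — callers name the class(es) to pick, as
each dataset in practice is picked for its own projection class.

Default score threshold 0.5; all detection parameters live in `Config`
(plain-text `key = value` files).

## Evaluation

Matching is greedy one-to-one by ascending center distance within a radius
(default half the particle size), because ground truth in this field is
center coordinates; IoU-based matching of boxes is not used for detection
scoring. Precision, recall and F1 are standard; the accuracy variant with TP
alone in the numerator over TP+FP+TN+FN is provided verbatim as
`accuracy_paper` next to the conventional `accuracy_std`, since the former
follows the method's printed definition and the latter the textbook one. TN
is only meaningful for patch classification. PR curves sweep all distinct
scores; the area is the trapezoid over recall with an anchor at recall 0.

## Problem sizes in the test suite

The suite runs the full study at desk scale: 24 synthetic micrographs
(360², 20 particles each) for dataset generation, 200 samples per class,
the reduced network trained 20 epochs, and detection on three seeded
micrographs. One shared trained model (session fixture) backs the classifier,
detection and acceptance tests. The complete suite runs in a few minutes on
one CPU.

## Known limitations

* The unsupervised stage assumes bright particles on a darker background
  after enhancement; dark-on-light data must be inverted upstream.
* Square detection assumes roughly axis-aligned side views; the perfect
  square replacement is axis-aligned.
* Sparse, non-overlapping particles are assumed (the generator enforces a
  minimum separation); aggregated or touching particles would be merged by
  8-connectivity labeling and rejected by the shape rules rather than split.
* The score-map cleaning tolerance and region cutoff are heuristics; on real
  data they would need per-dataset adjustment via `Config`.
* Synthetic validation does not establish real-data accuracy (see the
  generator's non-goals above).
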