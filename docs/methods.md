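# Methods

## Scope and model

`molsnap` implements a multi-view image representation for QSAR
classification.  The pipeline is a pure function of (dataset, seed): a
molecule's SMILES is normalized (largest fragment, neutralized
protonation states where chemically possible), embedded once in 3D, and
rendered as a ball-and-stick raster from every orientation of a
three-axis rotation grid; an image classifier trained on the ensemble
produces per-image probabilities whose per-molecule median is the
molecule's activity score.  Classification metrics are computed at the
cutoff maximizing the Youden index on the test scores.

## Structure preparation

- Conformers come from RDKit's ETKDG distance-geometry embedding with
  MMFF relaxation (UFF fallback), hydrogens explicit, one conformer per
  molecule, seeded.  Any reasonable low-energy conformer satisfies the
  pipeline's contracts; downstream results can depend on the
  conformer, which is an acknowledged source of variation of the
  method itself — the multi-angle ensemble mitigates but does not
  remove it.
- Neutralization uses RDKit's Uncharger; ions that cannot be
  neutralized (e.g. quaternary ammonium) pass through with an
  `uncharged_failed` flag rather than being dropped.

## Rendering

Deterministic software rasterizer (numpy; PIL only encodes PNGs):

- Extrinsic rotations about the fixed world x, then y, then z axes,
  applied about the molecular centroid.  The grid's per-axis angle set
  for increment `a` is {0, a, 2a, ...} ∩ [0, 360); the grid is the
  Cartesian product (rx slowest, rz fastest), so its size is
  ceil(360/a)³ — the only property the printed image counts pin down.
- Orthographic projection.  The per-molecule zoom makes the bounding
  sphere (atom radii included) fill 1 − margin of the frame
  (margin 10%), so scale is identical at every orientation of one
  molecule but differs between molecules.
- Painter's algorithm over atom disks and bond capsules sorted by
  camera depth; Lambert-style shading; CPK palette (C gray, H white,
  O red, N blue, S yellow, Cl green, Br dark red, I purple, P orange,
  fallback magenta) on a black background.
- Ball radius is `sphere_scale` × covalent radius with
  `sphere_scale = 0.55`: small enough to keep sticks visible, large
  enough that a halogen ball spans several pixels at 64–96 px, which
  the image arm needs to see the signal.  Stick radius is 8% of the
  mean displayed bond length.  All values live in `RenderConfig`
  defaults so tests pin them.

## Split protocol and labels

- Labels: top ⌈q·n⌉ molecules by activity are positive; boundary ties
  break by input order for reproducibility.  Labeling is invariant
  under strictly monotone transforms of the activity.
- Rotating groups: 5 near-equal groups for Tra/Val/Test = 2:2:1
  (3 groups for 1:1:1); within a segmentation each group is Test once,
  and the remaining groups are assigned deterministically (next two in
  cyclic order train, the following two validate).  Groups are
  label-stratified — tiny validation sets can otherwise end up
  single-class — with a flag to disable stratification.
- The permutation null reshuffles the label multiset (seeded) before
  splitting, preserving class counts exactly.

## Image classifier

The backend contract is fit(train, validation, spec) → per-epoch
validation trace, plus per-image predict_proba; the model returned is
the checkpoint with minimum validation loss, and the six solver types
(NAG, AdaGrad, AdaDelta, Adam, RMSprop, SGD) are implemented as
standard update rules (momentum 0.9, rho 0.95, Adam 0.9/0.999).
Defaults mirror the tuned operating point: NAG, learning rate 0.0025,
batch 37, 30 epochs; the benchmark experiments in the test-suite and
acceptance script run at learning rate 0.01, the setting of the
headline and permutation comparisons.

The default backend, `SmallImageNet`, is a committee of three
one-hidden-layer (64 unit) softmax networks over fixed image features:

- the share of molecule (non-background) pixels whose chromaticity is
  nearest each clearly colored CPK anchor, with achromatic pixels
  (carbon gray / stick gray / hydrogen white — identical in
  chromaticity) split into three luminance bins, plus the molecule's
  pixel fraction of the frame and the mean frame color.  Normalizing
  shares over molecule pixels removes the per-molecule zoom, which
  otherwise dilutes every color fraction differently per molecule.
- features are standardized (mean and variance) with statistics from
  the training images only; plain mean-centering left the optimization
  poorly conditioned at these feature scales.
- committee members differ only in seeded initialization and batch
  order; probabilities are averaged.  Members restore their own
  min-validation-loss checkpoints; the reported trace is member 0's.

This backend is intentionally minimal — color statistics and coarse
shape are exactly where these renders carry signal — and it trains
deterministically on one CPU in seconds.  A convolutional network (or
any other model implementing the two-method contract) can be plugged
into `train_image_classifier` when finer spatial structure matters.

## Metrics

All formula metrics are computed from the confusion counts at the
Youden cutoff (prediction rule: score ≥ cutoff is positive; candidate
cutoffs are the observed scores; ties on J return the smallest).  MCC
uses the Matthews definition with the square root over the product of
the four marginals, making it the Pearson correlation of the binary
prediction/truth vectors and keeping it in [−1, 1]; a published variant
that omits the square root is dimensionally inconsistent and is not
implemented.  Zero-denominator metrics report 0 with a degeneracy flag
so round summaries never propagate NaN.  ROC AUC is the rank statistic
(ties half credit), identical to the trapezoidal area and to the
pairwise-comparison probability.  One-angle-vs-rest deltas carry Welch
t 95% intervals (the original analysis computed spreadsheet CIs with
an unstated method; Welch is the defensible default for unequal
variances); group comparisons use the Mann-Whitney U test, exact for
tie-free samples of at most 8 per group, otherwise the tie-corrected
normal approximation.

## Diagnostics

PCA is fitted on centered, unit-variance descriptor columns
(correlation-matrix PCA — descriptor units are arbitrary); constant
columns are dropped with a warning, and loading signs are fixed by
making each loading's largest-magnitude entry positive so fits are
row-order invariant.  DModX of an observation is
√(Σe²/(K − A)) with e the residual of the scaled observation after
projection on the A retained components; the SIMCA-style extra
1/(N − A − 1) normalization is not applied.  Training/test DModX
distributions are compared with the Mann-Whitney test.

## Synthetic benchmark

The generator emulates a ~200-compound screening library with a
positively skewed continuous activity:

- Grammar: alkane/ether/amine backbones of 2–10 heavy atoms,
  0–2 benzene rings, 0–3 substituents per ring from
  {Cl, Br, F, OH, NO2, OMe, Me} (ring-free molecules may carry chain
  substituents); candidates are canonicalized and deduplicated, and
  generation is deterministic per (n, seed).
- Activity = (0.45 + 0.30·rings + 0.75·halogens) · exp(0.50·Z),
  Z ~ N(0, 1).  Halogenated aromatics scoring high mirrors the
  chemistry of strong AhR activators, and the calibration reproduces
  the assay's reported scale (sample mean ≈ 1.5, SD ≈ 1.1–1.4 at
  n = 201); the weights were fixed from that distribution match alone.
- What it does *not* emulate: real pharmacophores, conformational
  activity cliffs, assay-specific artifacts, or descriptor
  distributions of vendor libraries.  Passing the benchmark
  demonstrates that the pipeline extracts a genuine visual
  structure-activity signal well above its permutation null — not that
  the accuracy level transfers to any particular real assay.

Benchmark problem sizes were chosen to keep a complete evaluation
(201 molecules × 27 images, five rounds, real + permuted) in the
minutes range on a single CPU: renders at 96 × 96 (halogen balls stay
several pixels wide), one split segmentation, 30 epochs.  At these
conditions the noiseless rule's ceiling is AUC ≈ 0.84–0.89 against the
noisy labels; the image arm reaches ≈ 0.75–0.82 across generator
seeds with permutation nulls at ≈ 0.43–0.53, and the descriptor
baselines (which see exact atom counts) land slightly above the image
arm at ≈ 0.83.

## Numerical and degenerate-input choices

- Youden ties → smallest qualifying cutoff; ±∞ cutoffs are accepted in
  `confusion` as the all-negative/all-positive degenerate rules.
- Median aggregation uses the mean-of-central-pair convention for even
  image counts and errors on molecules with zero images.
- Embedding failures and unparseable records are per-record errors;
  datasets are loss-accounted (n_in = n_out + n_errors), never
  silently truncated.
- Renders are byte-deterministic; training is deterministic up to the
  BLAS library's row-blocking (identical calls give identical results;
  duplicated rows inside one batch can differ by one ulp).
- `rotation_grid` rejects increments outside (0, 360]; `Orientation`
  angles live in [0, 360).

## Known limitations

- One conformer per molecule; conformer-dependent activity is out of
  scope.
- The default backend ignores fine spatial structure; tasks whose
  signal is geometric (not compositional) need a stronger plugged-in
  backend.
- CatBoost is an optional baseline arm and raises a clear error when
  the library is absent.
- The proprietary variable-cluster ranking that sometimes accompanies
  this diagnostic workflow is not implemented.
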