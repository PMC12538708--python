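# Methods

This note records the models behind `seedspread`, the conventions and
defaults that matter, and what the synthetic pipeline does and does not
establish about real seed imagery.

## Problem setting

A spreading device lays a mixture of imported soybeans and quarantine
weed seeds (*Ambrosia trifida*, *A. artemisiifolia*) in a single layer
on a light conveyor belt; an overhead camera captures 3840 × 2160 px
frames for detection and counting. Spreading quality is the controlling
variable: clumped or occluded seeds are undercounted. The package
quantifies spreading uniformity per frame, analyses designed
factor-screening experiments on the device, and simulates the imaging
chain so every statistical component can be validated end to end.

## Uniformity statistic

Each frame is reduced to N = 48 tile values (6 rows × 8 columns; tiles
of 480 × 360 px at full resolution): the fraction of seed-classified
pixels per tile. Global Moran's I is computed on these fractions with
binary contiguity weights:

- **Weights.** Queen (8-neighbour) contiguity is the default, rook
  (4-neighbour) available; weights are binary and symmetric with zero
  diagonal, boundary tiles simply have fewer neighbours. Because the
  statistic normalises by S0 = Σw_ij, no row standardisation is applied.
  The weight scheme is a convention of this package — lattice analyses
  commonly default to queen — and all weights are exposed in the result.
- **Statistic.** I = N·Σ_ij w_ij z_i z_j / (S0·Σ_i z_i²) with
  z = x − x̄. Values near +1 indicate clumping, near −1 regular
  alternation, near 0 spatial randomness (uniform spreading). The
  permutation-null expectation −1/(N−1) (= −0.0213 at N = 48) is
  attached to every result.
- **Inference (optional).** A two-sided permutation test on |I| with
  add-one correction, p = (1 + #{|I_perm| ≥ |I_obs|})/(1 + n_perm).
  This is an extension beyond descriptive scoring and is flagged as
  such by being absent unless requested.
- **Degenerate input.** If all tile values are equal the statistic is
  0/0. Because downstream interpretation rests on magnitudes, this is a
  hard error, never silently reported as 0.
- **Interpretation caveat.** On pixel-fraction tiles the statistic runs
  slightly positive relative to the count-based null even for random
  layouts: a seed straddling a tile boundary contributes foreground to
  two adjacent tiles, inducing short-range positive correlation. The
  effect is small (≈ +0.02 at the default geometry) and does not affect
  comparisons made at a fixed geometry.

## Segmentation

The chain mirrors common practice for high-contrast seed imagery:
optional unsharp-mask sharpening (per channel,
out = clip(in + amount·(in − gaussian_blur(in, radius)))), then HSV
thresholding — a pixel is seed iff H, S and V each fall in their
configured interval. Conventions: H, S, V all on [0, 1]; hue intervals
may wrap through 0. The shipped default intervals are tuned to the
synthetic palette (saturated warm seeds on a near-white belt) and are
deliberately not a general-purpose default: user imagery must pass
explicit thresholds. Sharpening is a practical denoising step for real
camera frames; on noiseless synthetic scenes it is a no-op for
uniformity scoring and is off by default in the pipeline.

Grid binning is exact bookkeeping: mask dimensions must divide the tile
size (partial tiles would bias the fractions, so non-divisible input is
an error), tiles are traversed row-major from the top-left — fixing the
neighbour structure the weights builder assumes — and integer per-tile
counts are kept alongside the fractions so that
Σ tiles counts = total foreground holds exactly.

## Scene simulation

The generator emulates single-layer seed scenes over the device's
operating range, from clumped to singulated:

- **Geometry.** A 384 × 216 mm virtual belt at 10 px/mm reproduces the
  3840 × 2160 px frame; both are configurable (tests and the pipeline
  score at 1.25–2.5 px/mm, which leaves per-tile statistics essentially
  unchanged while cutting rasterisation cost). The belt field of view in
  mm is a convention of this package, not a measured device property.
- **Seeds.** Filled rotated ellipses at the measured mean dimensions
  (soybean 7.65 × 6.52 mm; *A. trifida* 7.57 × 4.57 mm;
  *A. artemisiifolia* 3.22 × 2.84 mm), orientation uniform on [0, π),
  per-pixel Gaussian colour jitter around a class colour. Colours
  (warm yellow / mid brown / dark brown on near-white) are chosen for
  clean HSV separation, not photometric realism.
- **Placement processes.** `poisson`: uniform iid centres (complete
  spatial randomness). `hardcore`: dart throwing with a minimum pairwise
  centre distance — the idealised singulated output; sampling is
  grid-accelerated with a bounded attempt budget, and an infeasible
  packing raises rather than silently placing fewer seeds. `thomas`:
  Poisson cluster process (uniform parents, Gaussian offsets) — seed
  adhesion and pile-ups. Exact class counts can be fixed via
  `mix_counts` (class labels are randomly permuted over positions so
  weeds share the spatial pattern); otherwise the total is
  Poisson(intensity × area) with uniform class assignment.
- **Edges and overlap.** Centres are sampled inset by the largest
  semi-major axis so no seed is edge-clipped by default (a flag allows
  clipping). Overlap is permitted for poisson/thomas; the ground-truth
  mask is the union of footprints, so occlusion reduces mask area —
  intentionally, as on the device.
- **Randomness.** One seed per scene; placement, colour jitter and
  detection draw from sub-streams derived via `SeedSequence(seed,
  spawn_key=k)`, so a scene is bit-reproducible from its parameters and
  seed alone.
- **Detector model.** Each true seed is detected independently with
  per-class recall, relabelled through a confusion row; false positives
  are Poisson per image with uniform labels. This is a deliberately
  minimal stochastic stand-in that preserves exactly the statistical
  structure the counting metrics consume (per-class counts); it does
  not model localisation, NMS, or density-dependent failure.

## Screening analysis (Taguchi L18)

- **Design.** The packaged L18 array covers one 2-level factor (socket
  arrangement) and five 3-level factors (roller speed, motor speed, box
  inclination, chute inclination, belt type); per-factor balance (9 or
  6 runs per level) is enforced at construction.
- **Responses.** Each run carries replicate Moran's I observations (in
  the virtual experiment: one per generated scene, across three sample
  groups — soy only, +1 % *A. artemisiifolia*, +1 % *A. trifida*). The
  run-level response is the run mean; stability is summarised by the
  smaller-the-better S/N = −10·log10(mean Y²) dB, the right
  characteristic because the target value of I is zero. All-zero
  observations give +inf dB by continuity rather than an error.
- **Response table.** Level means of run means and level means of
  per-run S/N; delta = max − min per factor; dense ranks by descending
  delta with ties sharing the smaller rank (the layout standard
  response-table software prints).
- **ANOVA.** Per-factor SS_f = Σ_v n_v(ȳ_v − Ȳ)² with n_v runs per
  level; DOF = l − 1; MS = SS/DOF. The residual error is obtained by
  subtraction from the total run-level SS with
  DOF_err = 17 − 11 = 6 for the full six-factor L18; F = MS_f/MS_err
  and P is the upper tail of F(DOF_f, DOF_err). This residual-error
  construction is adopted because the six factors leave exactly six
  free degrees of freedom in an L18, giving every factor a common error
  term — and it reproduces the packaged device study's printed
  decomposition from its level summaries to within table rounding,
  which is the operative justification. No multiple-testing correction
  is applied; significance is read at a single 0.05 threshold.
- **Optimal levels.** Two explicit rules, reported side by side without
  adjudication: the mean rule picks argmin |level mean| (distribution
  closest to spatial randomness), the S/N rule picks argmax level S/N
  (most stable). On the packaged device summary the rules disagree on
  the two speed factors (50/250 vs 150/150 steps/s) — a real
  precision-versus-consistency trade-off, and the device study's own
  final configuration reflects engineering judgement beyond either
  rule, which is why this package reports both rather than a single
  winner.

## Counting metrics

Per class: accuracy = 100·min(detected, true)/true — overcounts earn no
credit above 100 %, making accuracy + leakage = 100 exactly — and
composition = 100·true/(all true seeds). The average accuracy is the
unweighted mean over classes. Published verification tables for such
devices do not always use arithmetic recoverable from their printed
counts; this package fixes one auditable definition and records the
composition denominator in the report. The protocol check validates the
spiking recipe (count ratio 5 ± 0.5 % weed per soybean; mass ratio
1 ± 0.05 %) and attaches the computed ratios either way.

## Virtual experiment

Factor levels reach the simulator through a declared knob map
(factor → level → parameter overrides, merged in design factor order).
The default map encodes the screening's physical finding: the conveyor
motor speed selects the layout regime (slow → Thomas clusters,
mid → hard-core singulation, fast → Poisson), the roller speed scales
throughput (×0.8/1.0/1.2), and the remaining factors are inert. Default
scene content is 280 soybeans per scene (+3 weed seeds, ≈1 % by count,
in the spiked groups) — a dense single layer at roughly 13 % belt
coverage — with a 10 mm singulation separation chosen inside the
hard-core feasibility limit at the highest throughput level. Per-scene
seeds derive from the master seed by counter (run, group, image), and
the manifest records every scene's seed so any output can be
regenerated independently.

## Validation strategy and problem sizes

The statistical claims are validated two ways: against independent
oracles (a double-loop evaluation of Moran's I, closed forms — the
checkerboard/rook value of exactly −1, the permutation mean −1/(N−1) —
explicit small-kernel convolution for the unsharp mask, binomial and
Poisson moments for the detector) and against the packaged device-study
level summaries, which the ANOVA/rank/optimal-level code must reproduce
to within table rounding (±0.5 %).

The simulator ordering check — mean Moran's I of clustered > random >
singulated layouts at matched counts — uses 280 seeds per scene, a
12 mm hard-core separation (≈1.5× seed length, emulating the roller's
socket-raster spacing), Thomas clusters with parent intensity
3×10⁻⁴ mm⁻² and offset sd 12 mm, 100 scenes per regime, scored at
1.25 px/mm. These sizes come from an explicit power analysis: per-scene
I has sd ≈ 0.07–0.10, the clustered regime sits ≈ +0.13, the singulated
regime ≈ −0.04 versus random ≈ +0.00, so 100 replicates separate each
adjacent pair by ≳4 Monte-Carlo standard errors. Weaker inhibition
(separation at seed length, 8 mm) produces a poisson–hardcore gap of
only ≈0.007 — physically present but unresolvable at practical
replicate counts, and inverted at high densities by the
boundary-straddle effect noted above; the 12 mm condition is the regime
where the qualitative ordering is a property of the physics rather than
of sampling noise.

## What passing tests do and do not show

The synthetic scenes have flat illumination, exact ellipse geometry,
known colours and no debris, so segmentation fidelity (IoU ≈ 1 against
ground truth) says the thresholding chain is implemented correctly, not
that the default thresholds transfer to camera imagery. Likewise the
detector model validates the metrics pipeline, not any real detector's
recall; and the virtual experiment validates the design analysis
machinery (effect recovery, null calibration), not the device's actual
factor effects — the packaged device-study summary carries those.
Physical verification accuracies, trained-model mAPs and wall-clock
detection times are hardware- and model-bound quantities that are out
of scope here.

## Known limitations

- Seeds are 2-D ellipses: no 3-D pose, no specularity, no motion blur,
  no touching-seed instance splitting (the mask is a union by design).
- The hard-core sampler is sequential (RSA-style) dart throwing: it
  cannot reach packings near the jamming limit and treats that as an
  explicit failure rather than retrying indefinitely.
- The thomas sampler resamples out-of-belt children, so very tight
  clusters near the border are slightly inward-biased.
- Moran's I is the only uniformity statistic; no local indicators,
  Geary's C or variogram alternatives.
- The permutation test treats tiles as exchangeable; it inherits the
  small positive bias of pixel-fraction tiles noted above.
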