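# Methods

`abmcal` calibrates spatial agent-based models (ABMs) of tumors to
images.  The pipeline has four stages, each a module:

1. **abm** — an off-lattice, center-based tumor–T-cell simulator
   producing cell tables;
2. **imaging** — reduction of any cell table (simulated or
   image-derived) to a fixed-size multi-channel "simplified image";
3. **representation** — contrastively trained convolutional networks
   projecting simplified images to 2-D, with the ensemble-averaged
   Euclidean distance between projections as a similarity metric;
4. **calibration** — Monte-Carlo training-set generation,
   nearest-neighbor narrowing of parameter bounds, and genetic-algorithm
   minimization of the embedding distance to a target image.

A fifth module, **fixtures**, generates every synthetic input the tests
and examples use.

## Agent-based model

Cells are points with a radius (default 10 µm, from a cell diameter of
20 µm) in a continuous 2-D domain.  The state holds four kinds:
`tumor_live`, `tumor_dead`, `tcell_active`, `tcell_suppressed`.
"Nearby" always means center distance ≤ 1.1 × (sum of radii)
(`interaction_radius_factor`, configurable).

Each step applies, in fixed order:

1. **Proliferation.** Each live tumor cell divides with probability
   `proliferation_prob` (default 0.025/step); the daughter is placed
   touching the parent at a uniform random angle, followed by a
   relaxation pass.
2. **PD-L1 update** (variant `ex1`). Live tumor cells with at least one
   T cell in range gain `pdl1_rate` of PD-L1, capped at `pdl1_max`.
   PD-L1 is interpreted directly as a per-step suppression probability.
3. **Recruitment and migration.** On average `recruitment_rate`
   (default 2/step) active T cells appear on a circle one cell diameter
   outside the tumor radius.  Active T cells move `migration_step`
   (default 10 µm) toward the tumor centroid, halting at radial
   coordinate (1 − `infiltration`) × R, where R is the current tumor
   radius; `infiltration` is dimensionless in (0, 1].
4. **Killing.** Each (active T cell, adjacent live tumor cell) pair
   fires with probability `kill_prob`.
5. **Suppression** (`ex1`). Each (live tumor cell, adjacent active
   T cell) pair fires with probability equal to the tumor cell's PD-L1.
   Suppressed T cells never move and never kill again.
6. **Death.** In `ex1`, killed tumor cells are removed.  In `ex2`
   (hypoxic-core variant, no PD-L1 dynamics) killed cells and
   spontaneous deaths become persistent `tumor_dead` cells; live tumor
   cells die with `basal_death_prob`, elevated to `hypoxic_death_prob`
   within `hypoxic_radius` of the initial tumor centroid (the hypoxic
   disc is static).
7. **Relaxation** (below).

Within each phase, all Bernoulli pair-draws are taken simultaneously
against the phase-start state.  A randomized per-agent sweep would
serve the same purpose (removing id-order bias); the synchronous rule
was chosen because it is order-free by construction and easier to
reason about when replaying seeds.

**Mechanics.** Overlaps are resolved by iterative pairwise relaxation:
overlapping cells are pushed apart along their center line, half the
overlap each (the full overlap if one partner is immovable — dead tumor
cells and suppressed T cells never move), with an over-relaxation
factor of 1.5 because plain half-pushes propagate through a dense
packing one cell layer per sweep.  Sweeps stop when the maximum overlap
falls below 5% of the cell radius, or after 50 sweeps; the candidate
pair list is rebuilt from a KD-tree every 4 sweeps with a 1.5× cutoff
margin, and convergence is only declared against a freshly built tree.
Coincident centers separate along a random direction.  Residual overlap
slightly above the tolerance is possible when the sweep cap binds.

**Determinism.** One `numpy` Generator per simulation, seeded
explicitly; candidate pair lists are sorted canonically before draws,
so a given (parameters, config, seed) reproduces the final cell table
bit for bit.  Tumor extinction is flagged on the output table, not an
error.

**Defaults and scale.** The only physical size anchor is the cell
diameter (20 µm).  The remaining fixed constants (80 steps, 80-µm
initial tumor radius, proliferation 0.025, recruitment 2/step,
migration 10 µm/step) were chosen once so that the nominal parameter
set — killing probability 0.02, infiltration 0.8, PD-L1 cap 0.01,
PD-L1 rate 5×10⁻⁵ — ends in a contested snapshot containing live tumor,
active and suppressed T cells within a fraction of a CPU-second per
run.  This is a desk-scale tumor (a few hundred cells, radius
~200–250 µm); consequences for what the tests show are discussed under
*Limitations*.

## Simplified images

`process` = `rasterize` → `crop_to_tumor` → `downsample` → channel
restriction.

* **rasterize.** Bin *i* covers [i·d, (i+1)·d) from the minimum cell
  coordinate, d = one cell diameter; rows index y (downward), columns
  x.  Presence channels are 0/1; continuous channels accumulate the
  per-bin **sum** of the property and are then scaled to max 1 (a
  density-times-intensity semantics; per-bin mean is a configuration
  away, and model values are not fluorescence intensities in any case).
* **crop_to_tumor.** Minimal bounding box over the declared tumor
  channels (live + dead where present), applied to all channels.  This
  removes absolute position and, with the resize below, absolute size.
* **downsample.** Exact area-weighted resampling to the target size
  (default 32×32): output bin values are overlap-weighted means of
  input bins, implemented as two row-stochastic weight matrices.  On
  integer factors this reduces to block averaging.  Non-square crops
  are resized anisotropically, so relative shape, not absolute scale or
  aspect, is compared — which is what makes fitting across spatial
  scales possible, at the price of making the image-to-simulation
  scaling an implicitly estimated quantity.  Upsampling is permitted
  but logged, since it aggregates nothing.
* Per-channel rescale to max 1 (empty channels stay 0), values clipped
  to [0, 1].

Exact invariances: translation (always), uniform scaling of coordinates
and cell diameter by a common factor, and mirroring when no cell sits
on a bin boundary (reflection flips the half-open binning, so boundary
ties may shift by one bin).

## Contrastive representation

Each encoder is a small convolutional network (three 3×3 stride-2
convolutions of widths 8/16/32, ReLU, then a dense head 64 → 2),
implemented directly in NumPy with im2col convolutions and manual
backpropagation; analytic gradients are verified against finite
differences in the test suite.  Biases are initialized at 0.01: with
zero biases a dead-ReLU path can collapse a projection to the exact
zero vector, which the loss rejects.

Training follows the SimCLR recipe: each batch image is augmented twice
by random dihedral transforms (flips, 90° rotations — no interpolation
artifacts), and the NT-Xent loss

  ℓᵢ = −log [ exp(sᵢ,ₚ₍ᵢ₎/τ) / Σ_{k≠i} exp(sᵢ,ₖ/τ) ]

is averaged over all 2N views, with s the cosine similarity and
τ = 0.5.  Optimization is Adam (lr 10⁻³).  Defaults: batch 64,
100 epochs; the desk-scale pipeline uses batch 32 and 120 epochs
because on ~100 images the loss plateaus near epoch 100.  Training is
bit-reproducible from its seed.

At inference the 2-D head output is used directly (no separate
representation layer is retained), and the comparison metric is the
**ensemble distance**: the mean over members of the Euclidean distance
between two images' projections.  Members share the data and differ by
seed only.  The metric is a pseudo-metric (symmetric, non-negative,
zero on identical inputs; being a mean of norms it also satisfies the
triangle inequality).

## Calibration

* **Training set.** Parameters are sampled uniformly over their widest
  plausible ranges (killing probability 0.001–0.1, infiltration
  0.05–1, PD-L1 cap 0.001–0.05, PD-L1 rate 10⁻⁵–2×10⁻⁴).  Each row is
  simulated (default 2 replicates; the desk-scale single-parameter
  pipeline uses 1, keeping its budget at ~100 simulations) with a seed
  derived from (master seed, row, replicate), so results are
  independent of execution order.  Failed simulations are recorded and
  excluded, never fatal.
* **Bound narrowing.** The target image and all training images are
  projected; the n closest training images (default 100, desk scale
  20; ties broken by index) define per-parameter min/max bounds.
  Narrowed bounds are then guaranteed to lie inside the sampled ranges.
  Manual overrides are possible but audit-logged.
* **Objective.** Simulate a candidate (one replicate, fresh seed per
  evaluation — the population, not repeated evaluation, averages the
  simulator noise), process it, return the ensemble distance to the
  target.  Degenerate candidates (e.g. tumor extinct, nothing to crop)
  return a penalty (10³) instead of raising.  A fixed-seed mode exists
  for identity checks (a target evaluated against its own generating
  run has distance exactly 0).
* **GA.** Tournament selection (k = 3), BLX-α blend crossover
  (α = 0.5, probability 0.9), per-gene Gaussian mutation (probability
  0.2, σ = 10% of the bound width) clipped to bounds, elitism 1 —
  hence a monotone non-increasing best trace.  Defaults: population
  300 (`ex1`) / 400 (`ex2`); the desk-scale pipeline uses 20×8.  All
  evaluated individuals are archived, and the result reports the
  best-fit parameters, the per-generation best/mean traces, the first
  generation within 5% of the final best ("plateau generation"), and a
  max/min/mean/CV summary of the 10 best evaluations — the spread of
  which indicates how constrained the fit is.

## Synthetic fixtures

* **Base simulation**: the `ex1` model at the nominal parameters — the
  self-fit target.
* **Ring tumor**: lattice-with-jitter placement of live/dead cells in a
  disc (default 5,500 µm diameter, dead core 1,175 µm — the same
  image-vs-simulation scale mismatch, roughly 2×, that the cross-scale
  processing is meant to absorb).  An optional mixing fraction flips
  labels near the core boundary to emulate live/dead stain overlap
  (default 0).  It emulates the *tabular output of segmentation*, not a
  micrograph: no intensity noise, no segmentation errors, no irregular
  tumor outline.
* **Family pairs**: two fixture families with within-family stochastic
  variation, for encoder separation tests.

All fixtures regenerate byte-identically from their manifest (generator
name, spec, seed, SHA-256 of the CSV).

Because every test input is synthetic, passing tests demonstrate the
*mechanics* of the method — processing invariances, embedding
separability, bound narrowing, optimizer behavior, and parameter
recovery on self-generated data.  They do not demonstrate segmentation
robustness, stain-specific intensity effects, or biological adequacy of
the two example models; the hypoxic-core variant in particular omits
most of the biology of the in-vitro systems it gestures at.

## Desk-scale acceptance problem

`scripts/acceptance.py` runs the single-parameter self-fit three times
(master seeds derived from `--seed`): base simulation at the nominal
row, 100 training simulations varying only the killing probability,
3 encoder members, narrowing to the 20 nearest, GA 20×8, and reports
the median best-fit killing probability.  At this scale the dominant
error source is simulator stochasticity: the target is one random
realization, and each GA evaluation is a single replicate, so the
best-of-many-noisy-draws estimator carries an irreducible spread of
roughly ±20–30% per run; the median over seeds is considerably tighter.
The full-scale configuration (10⁴ simulations, 50 members, GA 300+)
reduces both noise sources but is cluster-scale by design.

## Known limitations

* 2-D only; no vasculature, intracellular signaling, or CAR-T-specific
  biology.
* Single-timepoint fitting: the objective compares one snapshot; joint
  fitting to temporal data is out of scope.
* The relaxation cap can leave small residual overlaps in very dense
  packings.
* Top-10 spread is the only uncertainty surfaced; no posterior or
  confidence interval is attempted.
* Desk-scale tumors are ~10× smaller in cell count than the motivating
  experiments, which inflates realization noise in any recovered
  parameter.
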