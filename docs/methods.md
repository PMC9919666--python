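# Methods

## Problem setting

`covaudit` validates a deterministic black-box image classifier — the
motivating case is a convolutional network labeling 108×108 aerial soybean
tiles *healthy* (0) or *defoliated* (1), where a tile is defoliated when
strictly more than 10% of its pixels show defoliation. The package does not
contain or train such a network; it treats the model under validation as an
opaque function `image -> label` and supplies synthetic stand-ins so the
whole pipeline is testable without any external dataset.

## Surrogate distillation

The surrogate is a random forest trained on the black box's outputs.
Determinism of the black box means duplicate inputs always carry the same
label, so the training signal is noiseless; no label-noise handling exists
or is needed. The reference configuration is 20 trees with maximum depth
20; feature subsampling (`max_features="sqrt"`) and bootstrap resampling
follow the common classifier defaults and are exposed in `SurrogateConfig`
because they influence which features the forest can ever test.

Fitting delegates to scikit-learn, but fitted trees are converted into the
package's own node structure (`DecisionNode`: feature, threshold, children,
or leaf class probabilities). All tracing, classification, serialization
and coverage logic operates on that structure only, so the training backend
is swappable and the traced paths are auditable. Classification averages
per-tree leaf probability vectors and takes the argmax; an exact tie is
resolved to *defoliated*, the conservative choice for a pest alert (the
farmer is sent to look rather than reassured). Degenerate single-class
training returns all-leaf trees with a logged warning — the behavior one
wants when the black box never emits one of the classes.

"Used" features are defined per sample: the union over trees of the
feature indices tested on the root-to-leaf path the sample actually takes.
`node_visits` counts every internal-node test on those paths, so
`|used| ≤ node_visits ≤ n_trees·max_depth`. Forest-wide feature presence
(`attainable_features`) is tracked separately: it is the ceiling no test
set can exceed, and accumulation terminates against it (with a warning)
rather than against the full universe, which the forest may not span.

## Quantization

Pixel `(r, c)` of an `H×W` image maps to region `⌊rg/H⌋·g + ⌊cg/W⌋` of a
`g×g` grid. Proportional binning was chosen because it yields exactly `g`
near-equal bins per axis even when `g` does not divide the side (20 does
not divide 108); any tiling convention changes region boundaries by at most
one pixel row/column. The pixel level is represented as the identity
quantizer so all downstream code has one path. Feature indices are
row-major and 0-based everywhere.

## Coupon-collector bounds

`E[Y_n] = n·H_n` with `H_n` summed smallest-terms-first. Two readings of
"trial" bracket the image count for full coverage:

* **Lower bound** — trial = one node visit anywhere in the forest. Node
  features are highly non-uniform (every root feature is collected on the
  first visit), and non-uniform coupon probabilities only increase expected
  collection time, so the uniform expectation is a lower bound on trials.
  Trials convert to images by dividing by the empirical mean of
  `node_visits` per image and taking the ceiling — the only
  dataset-independent way to state the bound in image units; the divisor is
  reported alongside the bound.
* **Upper bound** — trial = one whole image, i.e. each image contributes
  on average one new feature; `n·H_n` is then already in image units. An
  alternative reading (exactly `n` images) exists but is not implemented:
  the formula-based reading is kept because it is the one consistent with
  treating image arrivals as uniform coupon draws.

With the ceiling applied only to the lower bound, `lower ≤ ⌈upper⌉`
whenever the divisor is ≥ 1 (at a divisor of exactly 1 the two coincide
after rounding).

## Random selection and minimal sets

`random_until_covered` draws images uniformly without replacement until the
attainable set is covered or the collection is exhausted. Pruning is
backward elimination in reverse selection order: an image is dropped when
every region it covers is covered by at least one other retained image.
This is deterministic given the draw order, guarantees a coverage-
preserving subset, and guarantees 1-minimality (no single retained image is
removable). Exact minimum set cover is NP-hard; a greedy
largest-marginal-gain cover (`greedy_cover`, ties broken by sample id) is
provided as an alternative and is verified optimal on small constructed
instances. The experiment sweep reports per quantization level the mean
random and mean minimal counts over `n_runs` independent runs (run `r`
seeded `seed + r`), the two bounds, and the percent decrease
`100·(random − minimal)/random` computed on the run means.

## Synthetic data generator

The generator emulates what matters to the method, not botanical realism:
single-channel tiles in [0, 1] with a brighter canopy (intensity 0.65), a
defoliation mask formed as a union of random disks (intensity 0.25),
Gaussian pixel noise (σ = 0.05), and the strict >10% labeling rule
evaluated on the retained ground-truth mask. Class balance is a parameter
(default 0.5) because the original survey's balance is not published.
Defoliated tiles target a mask fraction drawn from [0.14, 0.40]; healthy
tiles from [0, 0.08] with a hard cap at 0.095 so quantization noise can
never flip a label across the 10% line. Each tile draws from a
counter-derived substream of the master seed, so datasets are reproducible
and stable under reordering. Bias modes emulate acquisition artifacts:
`half_left`/`corner` confine every disk to one part of the frame (the
drone-always-on-the-same-side scenario), `shadow_gradient` tilts
illumination without moving blobs.

What the generator does **not** emulate: RGB radiometry, canopy texture,
perspective or registration error, and label noise from human annotators.
Passing tests therefore demonstrate the *mechanics* of the method —
fidelity measurement, tracing, coverage accounting, bounds and pruning —
under controlled conditions, not performance on real imagery.

Stand-in black boxes: `fraction_oracle` (the labeling rule itself, via mask
lookup), `region_restricted` (the same rule restricted to an informative
region; the defoliated fraction is computed over that region's pixels,
which keeps the threshold meaningful regardless of region size), and
`threshold_rule` (mean-intensity cutoff). All are deterministic by
construction.

## Benchmark problem sizes

Tests and the acceptance script run on a pinned benchmark of 2,000 tiles
of 16×16 pixels (1,400 train / 600 held out), which preserves every
qualitative feature of the full-size problem — feature universes larger
than any single decision path, incomplete pixel-level coverage, large
minimal-set reductions at fine quantization and none at coarse levels —
while keeping a full pipeline run in seconds. The spatial-bias scenario
pairs a `half_left` dataset with a left-half-restricted black box and reads
the missing-feature report at the 8×8 region level, where untouched
right-half regions separate cleanly from stray noise splits.

## Known limitations

* The lower bound assumes the empirical mean node visits per image is
  representative; heavy-tailed visit distributions make it loose.
* Backward elimination is 1-minimal, not globally minimal; the greedy
  alternative has the usual `ln n` set-cover guarantee only.
* The missing-feature bias signal at a fixed grid is seed-sensitive when
  deep trees overfit noise pixels; the traffic-weighted split distribution
  (`feature_visit_counts`) is the more robust diagnostic.
* Binary labels only; the structures generalize to more classes but the
  tie-break and label conventions here are binary.
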