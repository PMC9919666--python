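# covaudit

Tools for validating a **black-box crop-image classifier** — for example a
neural network that labels aerial soybean tiles *healthy* or *defoliated* —
when its internals cannot be inspected. `covaudit` answers four practical
questions for agronomists and digital-agriculture engineers:

1. How does the black box use the image? (distill it into an explainable
   random forest and trace decision paths)
2. How representative is the test set? (measure feature coverage against
   coupon-collector expectations)
3. Where should a farmer spot check the field? (a minimal set of images
   whose decision paths jointly exercise every feature)
4. Which images are missing? (features never used, ranked candidate
   additions)

## Method

A random forest (default: 20 trees, maximum depth 20) is trained on the
black box's *outputs* rather than ground truth. Because the black box is a
deterministic function, these labels are noiseless and the forest becomes a
surrogate whose **fidelity** — the fraction of inputs on which it matches
the black box — is directly measurable.

Unlike saliency maps, a forest states unambiguously which features it used:
for a sample *s*, a pixel feature *f* is *used* when some tree tests *f* at
an internal node on the root-to-leaf path *s* takes. Accumulating used
features over a test set gives a **coverage curve** over the universe of
`H·W` pixel features, or over a coarser `g×g` grid of regions (a region is
used when any of its pixels is; a 108×108 tile has 11,664 pixel features,
or 400 at `g = 20`).

How many images full coverage *should* take is bracketed by the coupon
collector problem. With `n` features and uniform draws the expected number
of trials is

    E[Y_n] = n · H_n,   H_n = Σ_{i=1..n} 1/i .

Treating each node visit as a trial gives a lower bound in image units
(divide by the mean node visits per image); treating each whole image as a
trial — one new feature per image — gives an upper bound. Finally, images
are drawn at random until coverage is complete and then pruned (backward
elimination) to a **minimal observation set**: a coverage-preserving subset
from which no single image can be removed. The pruned set is the farmer's
spot-check plan.

Everything runs on synthetic defoliation-like tiles generated by the
package itself (blob-structured masks, the strict ">10% defoliated" label
rule, optional spatial bias); any deterministic image → label function can
be plugged in as the black box.

## Worked example

```python
from covaudit import (GenConfig, SurrogateConfig, generate_field_images,
    make_blackbox, train_surrogate, trace_all, fidelity, make_quantizer,
    coverage_experiment, coupon_expectation)

cfg = GenConfig(n_images=2000, H=16, W=16, blob_radius_range=(2, 5), seed=0)
dataset = generate_field_images(cfg)
images = [img for img, _, _ in dataset]
masks = {img.id: mask for img, mask, _ in dataset}
blackbox = make_blackbox("fraction_oracle", {"masks": masks})
labels = blackbox.label_all(images)

forest = train_surrogate(images[:1400], labels[:1400], SurrogateConfig(seed=0))
print(f"held-out fidelity: {fidelity(forest, images[1400:], labels[1400:]):.3f}")

usages = {u.sample_id: u for u in trace_all(forest, images[1400:])}
quantizers = [make_quantizer(16, 16, g) for g in (4, 8)] + [make_quantizer(16, 16)]
for row in coverage_experiment(usages, forest, quantizers, n_runs=10, seed=0):
    print(f"n_features={row.n_features:4d}  random={row.mean_random:6.1f}  "
          f"minimal={row.mean_minimal:5.1f}  lower={row.lower_bound:3d}  "
          f"upper={row.upper_bound:7.1f}  decrease={row.pct_decrease:5.1f}%")

print(f"E[Y_n] at n=11664: {coupon_expectation(11664):.0f} trials")
```

Output:

```
held-out fidelity: 0.983
n_features=  16  random=   1.0  minimal=  1.0  lower=  1  upper=   54.1  decrease=  0.0%
n_features=  64  random=  97.4  minimal=  4.2  lower=  3  upper=  303.6  decrease= 95.7%
n_features= 256  random= 600.0  minimal= 18.6  lower= 13  upper= 1567.8  decrease= 96.9%
E[Y_n] at n=11664: 115958 trials
```

The surrogate reproduces the black box on 98.3% of held-out tiles. At the
coarse 4×4 view a single image already exercises every region, so pruning
cannot help; at finer quantizations random selection needs tens to hundreds
of images (at the pixel level it exhausts all 600 test images without
reaching every attainable feature — the logged warning) while the pruned
minimal set needs ~19, a >95% reduction in field visits. The last line is
the expected number of uniform trials to collect all 11,664 pixel features
of a full-size 108×108 tile — more than a 10,213-image test set can supply,
which is why region-level coverage matters in practice.

The same workflow is scriptable from the shell: `covaudit gen`,
`covaudit distill`, `covaudit coverage`, `covaudit bounds`,
`covaudit minset`, or end-to-end with `covaudit run --config run.yaml`.

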