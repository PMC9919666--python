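"""Coupon-collector expectations and bounds on images needed for coverage.

With n features to cover and uniform, independent draws, the expected number
of trials to see every feature at least once is

    E[Y_n] = n * H_n,    H_n = sum_{i=1..n} 1/i.

Two readings of "trial" bracket the number of *images* required:

* trial = one node visit anywhere in the forest -> a **lower** bound, because
  node features are far from uniformly likely (every root feature is seen on
  the very first visit), and non-uniform coupon probabilities only increase
  the expected trials. Node-visit trials convert to images by dividing by the
  empirical mean number of node visits per image.
* trial = one whole image, i.e. each new image contributes exactly one new
  feature on average -> an **upper** bound in image units directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def harmonic(n: int) -> float:
    """Partial harmonic sum H_n, accumulated smallest-terms-first."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(sum(1.0 / i for i in range(n, 0, -1)))


def coupon_expectation(n: int) -> float:
    """Expected uniform trials to collect all n coupons: n * H_n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * harmonic(n)


def upper_bound_images(n: int) -> float:
    """Expected images for full coverage if each image yields one new-feature
    trial: n * H_n, in image units."""
    return coupon_expectation(n)


def lower_bound_images(n: int, mean_visits_per_image: float) -> int:
    """Expected images if every node visit were a uniform trial.

    ``mean_visits_per_image`` is the empirical mean of
    ``FeatureUsage.node_visits`` over the dataset; the trial-count
    expectation is divided by it and rounded up to whole images.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_visits_per_image < 1:
        raise ValueError("mean_visits_per_image must be >= 1")
    return math.ceil(coupon_expectation(n) / mean_visits_per_image)


@dataclass(frozen=True)
class BoundsResult:
    """Expectation and image-unit bounds for an n-feature universe."""

    n: int
    expectation: float
    lower_bound_images: int
    upper_bound_images: float
    mean_visits_per_image: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "expectation": self.expectation,
            "lower_images": self.lower_bound_images,
            "upper_images": self.upper_bound_images,
            "mean_visits_per_image": self.mean_visits_per_image,
        }


def compute_bounds(n: int, mean_visits_per_image: float) -> BoundsResult:
    e = coupon_expectation(n)
    return BoundsResult(
        n=n,
        expectation=e,
        lower_bound_images=lower_bound_images(n, mean_visits_per_image),
        upper_bound_images=e,
        mean_visits_per_image=float(mean_visits_per_image),
    )
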