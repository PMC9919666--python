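"""Feature quantization and coverage accumulation.

Feature coverage asks: over a sequence of classified samples, which parts of
the input has the surrogate actually tested? At full resolution the feature
universe is every pixel (108x108 tiles -> 11,664 features); a farmer who
only cares whether each *region* of the image matters can coarsen the
universe to a g x g grid (g=20 -> 400 features). A region counts as used as
soon as any one of its pixels is used.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .surrogate import FeatureUsage, SurrogateForest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Quantizer:
    """Total, onto map from pixel features to region features.

    Pixel ``(r, c)`` maps to region ``floor(r*g/H)*g + floor(c*g/W)``: exactly
    ``g`` near-equal bins per axis even when ``g`` does not divide the image
    side (108 is not divisible by 20). The pixel level is the identity
    quantizer (``g=None``), so downstream code has a single code path.
    """

    H: int
    W: int
    g: int | None  # None => pixel level (identity)
    n_features: int
    mapping: np.ndarray  # length H*W, pixel index -> region index

    def quantize_pixels(self, pixel_indices: Iterable[int]) -> frozenset[int]:
        """Map a set of pixel feature indices to region feature indices."""
        n_pixels = self.H * self.W
        out = set()
        for p in pixel_indices:
            if not (0 <= p < n_pixels):
                raise ValueError(f"pixel index {p} out of range [0, {n_pixels})")
            out.add(int(self.mapping[p]))
        return frozenset(out)

    @property
    def label(self) -> str:
        return "pixel" if self.g is None else f"g{self.g}"


def make_quantizer(H: int, W: int, g: int | None = None) -> Quantizer:
    """Build a quantizer for an HxW image.

    ``g=None`` gives the pixel-level (identity) quantizer with ``H*W``
    features; otherwise ``1 <= g <= max(H, W)`` gives ``g**2`` region
    features.
    """
    if H < 1 or W < 1:
        raise ValueError("H and W must be >= 1")
    if g is None:
        mapping = np.arange(H * W, dtype=np.int64)
        return Quantizer(H=H, W=W, g=None, n_features=H * W, mapping=mapping)
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > max(H, W):
        raise ValueError(f"g={g} exceeds max image side {max(H, W)}")
    rows = np.arange(H)
    cols = np.arange(W)
    row_bin = (rows * g) // H
    col_bin = (cols * g) // W
    mapping = (row_bin[:, None] * g + col_bin[None, :]).ravel().astype(np.int64)
    return Quantizer(H=H, W=W, g=g, n_features=g * g, mapping=mapping)


def quantize_usage(usage: FeatureUsage, q: Quantizer) -> frozenset[int]:
    """Region features touched by a sample: a region is used iff at least
    one of its constituent pixels is on the sample's decision paths."""
    return q.quantize_pixels(usage.used)


@dataclass(frozen=True)
class CoverageCurve:
    """Cumulative coverage over an ordered sample sequence.

    ``counts[k]`` is the number of distinct region features used by the
    first ``k+1`` samples; non-decreasing by construction.
    """

    sample_ids: tuple[str, ...]
    counts: tuple[int, ...]
    covered: frozenset[int]
    n_features: int

    @property
    def n_steps(self) -> int:
        return len(self.sample_ids)

    @property
    def is_full(self) -> bool:
        return len(self.covered) == self.n_features


def accumulate_coverage(
    usages: Sequence[FeatureUsage], q: Quantizer
) -> CoverageCurve:
    """Union quantized usage over samples in order, recording the curve."""
    covered: set[int] = set()
    ids: list[str] = []
    counts: list[int] = []
    for u in usages:
        covered |= quantize_usage(u, q)
        ids.append(u.sample_id)
        counts.append(len(covered))
    return CoverageCurve(
        sample_ids=tuple(ids),
        counts=tuple(counts),
        covered=frozenset(covered),
        n_features=q.n_features,
    )


def attainable_features(forest: SurrogateForest, q: Quantizer) -> frozenset[int]:
    """Regions containing at least one pixel feature present anywhere in the
    forest's internal nodes.

    No dataset can cover more than this set: a feature the forest never
    tests can never appear on a decision path. Coverage accumulation
    terminates against this ceiling.
    """
    return q.quantize_pixels(forest.all_node_features())


@dataclass(frozen=True)
class MissingReport:
    """Uncovered features, split by whether the forest could ever use them."""

    missing: frozenset[int]
    attainable_missing: frozenset[int] | None = None
    unattainable: frozenset[int] | None = None


def missing_features(
    curve: CoverageCurve, q: Quantizer, forest: SurrogateForest | None = None
) -> MissingReport:
    """Features of the universe not covered by the curve.

    With a forest, the missing set is split into "uncovered but attainable"
    (more/better images could cover them) and "unattainable by this forest"
    (no image can).
    """
    missing = frozenset(range(q.n_features)) - curve.covered
    if forest is None:
        return MissingReport(missing=missing)
    attainable = attainable_features(forest, q)
    return MissingReport(
        missing=missing,
        attainable_missing=missing & attainable,
        unattainable=missing - attainable,
    )


def suggest_additions(
    missing: frozenset[int] | set[int],
    candidates: Sequence[FeatureUsage],
    q: Quantizer,
) -> list[tuple[str, int]]:
    """Rank candidate images by how many missing features each would cover.

    Returns ``(sample_id, n_missing_covered)`` pairs, descending by count,
    ties broken by lexicographic sample id; candidates covering nothing
    missing are omitted.
    """
    missing = frozenset(missing)
    scored = []
    for cand in candidates:
        gain = len(quantize_usage(cand, q) & missing)
        if gain > 0:
            scored.append((cand.sample_id, gain))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def write_coverage_csv(curve: CoverageCurve, path: str | Path) -> None:
    """`step,sample_id,covered,n_features` rows, one per accumulated sample."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "sample_id", "covered", "n_features"])
        for k, (sid, cnt) in enumerate(zip(curve.sample_ids, curve.counts), start=1):
            writer.writerow([k, sid, cnt, curve.n_features])
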