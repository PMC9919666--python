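"""Random-until-covered selection, minimal spot-check sets, and the
quantization-sweep experiment.

The workflow mirrors how a farmer would build a spot-check plan: randomly
select classified images until every (region) feature has been used at least
once, then prune the selection so that no image can be dropped without
losing coverage. The pruned set is the list of field locations to visit.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bounds import compute_bounds
from .coverage import Quantizer, attainable_features, quantize_usage
from .datagen import Image
from .surrogate import FeatureUsage, SurrogateForest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """An ordered image selection and the region coverage it achieved."""

    selected: tuple[str, ...]
    covered: frozenset[int]
    terminated_full: bool

    @property
    def n_random(self) -> int:
        return len(self.selected)


def random_until_covered(
    usages: Mapping[str, FeatureUsage] | Sequence[FeatureUsage],
    q: Quantizer,
    seed: int,
    attainable: frozenset[int] | None = None,
) -> SelectionResult:
    """Draw images uniformly without replacement until coverage is complete.

    The stopping target is the attainable set (features the forest can ever
    use); if that is a strict subset of the universe a warning is logged,
    since full-universe coverage is then impossible. If the collection is
    exhausted first, ``terminated_full`` is False.
    """
    usage_list = list(usages.values()) if isinstance(usages, Mapping) else list(usages)
    if not usage_list:
        raise ValueError("empty usage collection")
    target = frozenset(range(q.n_features)) if attainable is None else attainable
    if len(target) < q.n_features:
        logger.warning(
            "attainable set (%d) is a strict subset of the universe (%d); "
            "stopping at attainable coverage",
            len(target),
            q.n_features,
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(usage_list))
    covered: set[int] = set()
    selected: list[str] = []
    for idx in order:
        u = usage_list[idx]
        selected.append(u.sample_id)
        covered |= quantize_usage(u, q)
        if covered >= target:
            return SelectionResult(
                selected=tuple(selected),
                covered=frozenset(covered),
                terminated_full=True,
            )
    return SelectionResult(
        selected=tuple(selected), covered=frozenset(covered), terminated_full=False
    )


def prune_to_minimal(
    selection: SelectionResult,
    usages: Mapping[str, FeatureUsage],
    q: Quantizer,
) -> SelectionResult:
    """Backward elimination to a 1-minimal, coverage-preserving subset.

    Scans the selected images in reverse selection order and drops any image
    whose removal leaves the covered set unchanged. The result is a subset
    of the input with identical coverage from which no single image can be
    removed; deterministic given the input order.
    """
    region_sets = {sid: quantize_usage(usages[sid], q) for sid in selection.selected}
    # Multiplicity of each covered feature across the current selection.
    counts: dict[int, int] = {}
    for sid in selection.selected:
        for f in region_sets[sid]:
            counts[f] = counts.get(f, 0) + 1
    kept = list(selection.selected)
    for sid in reversed(selection.selected):
        if all(counts[f] > 1 for f in region_sets[sid]):
            kept.remove(sid)
            for f in region_sets[sid]:
                counts[f] -= 1
    covered = frozenset().union(*(region_sets[sid] for sid in kept)) if kept else frozenset()
    assert covered == selection.covered
    return SelectionResult(
        selected=tuple(kept),
        covered=covered,
        terminated_full=selection.terminated_full,
    )


def greedy_cover(
    usages: Mapping[str, FeatureUsage],
    q: Quantizer,
    target: frozenset[int],
) -> SelectionResult:
    """Greedy set cover: repeatedly pick the image with the largest marginal
    gain (ties by sample id) until the target set is covered or no image
    helps. An alternative to backward elimination when a small set matters
    more than faithfulness to the random draw."""
    region_sets = {sid: quantize_usage(u, q) for sid, u in usages.items()}
    covered: set[int] = set()
    selected: list[str] = []
    remaining = set(target)
    while remaining:
        best_sid, best_gain = None, 0
        for sid in sorted(region_sets):
            gain = len(region_sets[sid] & remaining)
            if gain > best_gain:
                best_sid, best_gain = sid, gain
        if best_sid is None:
            break
        selected.append(best_sid)
        covered |= region_sets[best_sid]
        remaining -= region_sets[best_sid]
    return SelectionResult(
        selected=tuple(selected),
        covered=frozenset(covered),
        terminated_full=covered >= target,
    )


def percent_decrease(n_random: int, n_minimal: int) -> float:
    """Percent reduction of the minimal set relative to random selection."""
    if n_random <= 0:
        raise ValueError("n_random must be > 0")
    if n_minimal > n_random or n_minimal < 0:
        raise ValueError("need 0 <= n_minimal <= n_random")
    return 100.0 * (n_random - n_minimal) / n_random


@dataclass(frozen=True)
class ExperimentRow:
    """One quantization level of the sweep: random vs minimal vs bounds."""

    n_features: int
    mean_random: float
    mean_minimal: float
    lower_bound: int
    upper_bound: float
    pct_decrease: float


def coverage_experiment(
    usages: Mapping[str, FeatureUsage],
    forest: SurrogateForest,
    quantizers: Sequence[Quantizer],
    n_runs: int = 10,
    seed: int = 0,
) -> list[ExperimentRow]:
    """Sweep quantization levels; average random/minimal counts over runs.

    Per level: ``n_runs`` independent random-until-covered draws (run ``r``
    seeded ``seed + r`` for auditability), each pruned to a minimal set;
    coupon-collector bounds use the universe size and the empirical mean
    node visits per image. Rows are sorted by ``n_features`` ascending.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    mean_visits = float(np.mean([u.node_visits for u in usages.values()]))
    rows = []
    for q in sorted(quantizers, key=lambda q: q.n_features):
        attainable = attainable_features(forest, q)
        n_rand, n_min = [], []
        for r in range(n_runs):
            sel = random_until_covered(usages, q, seed=seed + r, attainable=attainable)
            pruned = prune_to_minimal(sel, usages, q)
            n_rand.append(sel.n_random)
            n_min.append(pruned.n_random)
        b = compute_bounds(q.n_features, max(1.0, mean_visits))
        mean_random = float(np.mean(n_rand))
        mean_minimal = float(np.mean(n_min))
        rows.append(
            ExperimentRow(
                n_features=q.n_features,
                mean_random=mean_random,
                mean_minimal=mean_minimal,
                lower_bound=b.lower_bound_images,
                upper_bound=b.upper_bound_images,
                pct_decrease=percent_decrease_mean(mean_random, mean_minimal),
            )
        )
    return rows


def percent_decrease_mean(mean_random: float, mean_minimal: float) -> float:
    """percent_decrease on (possibly fractional) run averages."""
    if mean_random <= 0:
        raise ValueError("mean_random must be > 0")
    return 100.0 * (mean_random - mean_minimal) / mean_random


def write_experiment_csv(rows: Sequence[ExperimentRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["n_features", "mean_random", "mean_minimal", "lower_bound", "upper_bound", "pct_decrease"]
        )
        for r in rows:
            writer.writerow(
                [
                    r.n_features,
                    f"{r.mean_random:.6f}",
                    f"{r.mean_minimal:.6f}",
                    r.lower_bound,
                    f"{r.upper_bound:.6f}",
                    f"{r.pct_decrease:.6f}",
                ]
            )


def export_spot_checks(
    minimal: SelectionResult,
    images: Mapping[str, Image],
    surrogate_labels: Mapping[str, int] | None = None,
    blackbox_labels: Mapping[str, int] | None = None,
) -> list[dict]:
    """Build the spot-check manifest for a minimal selection.

    One row per selected image — id, field location (blank when the image
    carries none), surrogate label and black-box label — ordered row-major
    by field location, location-less images last by id.
    """

    def sort_key(sid: str):
        loc = images[sid].field_location if sid in images else None
        return (0, loc[0], loc[1], sid) if loc is not None else (1, 0, 0, sid)

    rows = []
    for sid in sorted(minimal.selected, key=sort_key):
        loc = images[sid].field_location if sid in images else None
        rows.append(
            {
                "id": sid,
                "row": loc[0] if loc else "",
                "col": loc[1] if loc else "",
                "surrogate_label": (surrogate_labels or {}).get(sid, ""),
                "blackbox_label": (blackbox_labels or {}).get(sid, ""),
            }
        )
    return rows


def write_spot_checks_csv(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["id", "row", "col", "surrogate_label", "blackbox_label"]
        )
        writer.writeheader()
        writer.writerows(rows)
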