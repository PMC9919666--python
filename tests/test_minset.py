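"""Random-until-covered selection, minimal-set pruning, and the experiment
table."""

import itertools

import numpy as np
import pytest

from covaudit import (
    FeatureUsage,
    Image,
    coverage_experiment,
    export_spot_checks,
    greedy_cover,
    make_quantizer,
    percent_decrease,
    prune_to_minimal,
    quantize_usage,
    random_until_covered,
)


def usage(sid, pixels, visits=None):
    return FeatureUsage(
        sample_id=sid,
        used=frozenset(pixels),
        node_visits=visits if visits is not None else len(pixels),
    )


def brute_force_min_cover(usages, q, target):
    """Smallest subset of usages whose quantized union covers target.

    Exhaustive over all subsets; only for instances of about a dozen images.
    """
    region_sets = {u.sample_id: quantize_usage(u, q) for u in usages}
    ids = sorted(region_sets)
    best = None
    for k in range(len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            covered = frozenset().union(*(region_sets[s] for s in combo)) if combo else frozenset()
            if covered >= target:
                return set(combo)
    return best


class TestRandomUntilCovered:
    def test_single_relevant_feature_stops_immediately(self):
        q = make_quantizer(1, 4)
        usages = [usage(f"s{i}", {0}) for i in range(5)]
        sel = random_until_covered(usages, q, seed=0, attainable=frozenset({0}))
        assert sel.n_random == 1 and sel.terminated_full

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            random_until_covered([], make_quantizer(1, 4), seed=0)

    def test_exhaustion_reports_partial_coverage(self):
        q = make_quantizer(1, 4)
        usages = [usage("a", {0}), usage("b", {1})]
        sel = random_until_covered(usages, q, seed=0)
        assert not sel.terminated_full
        assert sel.covered == frozenset({0, 1})
        assert sel.n_random == 2

    def test_attainable_subset_warns_and_stops_early(self, caplog):
        q = make_quantizer(1, 4)
        usages = [usage("a", {0}), usage("b", {1})]
        import logging

        with caplog.at_level(logging.WARNING):
            sel = random_until_covered(
                usages, q, seed=0, attainable=frozenset({0, 1})
            )
        assert "strict subset" in caplog.text
        assert sel.terminated_full

    def test_reproducible_given_seed(self):
        q = make_quantizer(1, 8)
        rng = np.random.default_rng(4)
        usages = [usage(f"s{i}", set(rng.integers(0, 8, size=2))) for i in range(30)]
        a = random_until_covered(usages, q, seed=17)
        b = random_until_covered(usages, q, seed=17)
        assert a == b

    def test_one_feature_per_image_matches_coupon_expectation(self):
        """When every drawn image contributes a single uniform feature, the
        mean stopping count reproduces the n=10 coupon-collector mean."""
        from covaudit import coupon_expectation

        n = 10
        q = make_quantizer(1, n)
        rng = np.random.default_rng(2024)
        pool = [usage(f"s{i:05d}", {int(rng.integers(0, n))}) for i in range(4000)]
        stops = np.array(
            [random_until_covered(pool, q, seed=r).n_random for r in range(200)],
            dtype=float,
        )
        se = stops.std(ddof=1) / np.sqrt(len(stops))
        assert abs(stops.mean() - coupon_expectation(n)) <= 2 * se


class TestPruneToMinimal:
    def _check_minimal(self, pruned, region_sets):
        """1-minimality: dropping any kept image loses some covered feature."""
        kept = list(pruned.selected)
        for sid in kept:
            rest = frozenset().union(
                *(region_sets[s] for s in kept if s != sid)
            ) if len(kept) > 1 else frozenset()
            assert rest != pruned.covered

    def test_single_image_covering_everything(self):
        q = make_quantizer(1, 4)
        usages = {u.sample_id: u for u in [usage("a", {0, 1, 2, 3}), usage("b", {0})]}
        sel = random_until_covered(usages, q, seed=1)
        pruned = prune_to_minimal(sel, usages, q)
        assert pruned.selected == ("a",)
        assert pruned.covered == sel.covered

    def test_duplicate_usage_images_are_dropped(self):
        q = make_quantizer(1, 4)
        usages = {
            "a": usage("a", {0, 1}),
            "b": usage("b", {0, 1}),
            "c": usage("c", {2, 3}),
        }
        sel = random_until_covered(usages, q, seed=0)
        pruned = prune_to_minimal(sel, usages, q)
        assert len(pruned.selected) == 2
        assert pruned.covered == frozenset({0, 1, 2, 3})

    def test_redundant_pair_removed_and_optimal_by_brute_force(self):
        q = make_quantizer(1, 8)
        pool = {
            "A": usage("A", {0, 1, 2, 3}),
            "B": usage("B", {4, 5, 6, 7}),
            "C": usage("C", {0, 4}),
            "D": usage("D", {1, 5}),
        }
        sel = random_until_covered(pool, q, seed=3)
        assert sel.terminated_full
        pruned = prune_to_minimal(sel, pool, q)
        assert set(pruned.selected) == {"A", "B"}
        optimal = brute_force_min_cover(
            pool.values(), q, frozenset(range(8))
        )
        assert len(pruned.selected) == len(optimal)

    def test_subset_coverage_and_minimality_on_benchmark(self, benchmark):
        q = make_quantizer(16, 16, 4)
        from covaudit import attainable_features

        att = attainable_features(benchmark.forest, q)
        region_sets = {
            sid: quantize_usage(u, q) for sid, u in benchmark.usage_map.items()
        }
        for seed in range(3):
            sel = random_until_covered(benchmark.usage_map, q, seed=seed, attainable=att)
            pruned = prune_to_minimal(sel, benchmark.usage_map, q)
            assert set(pruned.selected) <= set(sel.selected)
            assert pruned.covered == sel.covered
            self._check_minimal(pruned, region_sets)


class TestGreedyCover:
    def test_matches_brute_force_on_small_instances(self):
        q = make_quantizer(1, 12)
        rng = np.random.default_rng(8)
        for trial in range(5):
            pool = {
                f"s{i}": usage(f"s{i}", set(rng.integers(0, 12, size=4)))
                for i in range(10)
            }
            target = frozenset().union(*(u.used for u in pool.values()))
            greedy = greedy_cover(pool, q, target)
            optimal = brute_force_min_cover(pool.values(), q, target)
            assert greedy.terminated_full
            assert len(greedy.selected) <= 1.5 * len(optimal)


class TestPercentDecrease:
    @pytest.mark.parametrize(
        "n_random,n_minimal,expected",
        [(100, 100, 0.0), (100, 50, 50.0), (50, 3, 94.0)],
    )
    def test_arithmetic(self, n_random, n_minimal, expected):
        assert percent_decrease(n_random, n_minimal) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease(0, 0)
        with pytest.raises(ValueError):
            percent_decrease(5, 6)


class TestCoverageExperiment:
    def test_single_run_row_matches_direct_computation(self, benchmark):
        from covaudit import attainable_features

        q = make_quantizer(16, 16, 2)
        rows = coverage_experiment(
            benchmark.usage_map, benchmark.forest, [q], n_runs=1, seed=5
        )
        att = attainable_features(benchmark.forest, q)
        sel = random_until_covered(benchmark.usage_map, q, seed=5, attainable=att)
        pruned = prune_to_minimal(sel, benchmark.usage_map, q)
        assert rows[0].n_features == 4
        assert rows[0].mean_random == sel.n_random
        assert rows[0].mean_minimal == pruned.n_random

    def test_minimal_never_exceeds_random_and_rows_sorted(self, benchmark):
        quantizers = [
            make_quantizer(16, 16, g) for g in (2, 4, 8)
        ] + [make_quantizer(16, 16)]
        rows = coverage_experiment(
            benchmark.usage_map, benchmark.forest, quantizers, n_runs=3, seed=0
        )
        assert [r.n_features for r in rows] == sorted(r.n_features for r in rows)
        for row in rows:
            assert row.mean_minimal <= row.mean_random
            assert row.pct_decrease >= 0.0
            assert row.lower_bound >= 1


class TestSpotCheckManifest:
    def _images(self, with_locations=True):
        out = {}
        for i, sid in enumerate(["a", "b", "c"]):
            loc = (i // 2, i % 2) if with_locations else None
            out[sid] = Image(
                id=sid, pixels=np.full((2, 2), 0.5), field_location=loc
            )
        return out

    def test_empty_selection_gives_empty_manifest(self):
        from covaudit import SelectionResult

        rows = export_spot_checks(
            SelectionResult(selected=(), covered=frozenset(), terminated_full=False),
            self._images(),
        )
        assert rows == []

    def test_rows_match_selection_and_are_field_ordered(self):
        from covaudit import SelectionResult

        sel = SelectionResult(
            selected=("c", "a", "b"), covered=frozenset({0}), terminated_full=True
        )
        rows = export_spot_checks(
            sel, self._images(), surrogate_labels={"a": 0}, blackbox_labels={"a": 1}
        )
        assert [r["id"] for r in rows] == ["a", "b", "c"]  # row-major field order
        assert rows[0]["surrogate_label"] == 0 and rows[0]["blackbox_label"] == 1

    def test_missing_locations_leave_columns_empty(self):
        from covaudit import SelectionResult

        sel = SelectionResult(
            selected=("b", "a"), covered=frozenset(), terminated_full=False
        )
        rows = export_spot_checks(sel, self._images(with_locations=False))
        assert [r["id"] for r in rows] == ["a", "b"]
        assert rows[0]["row"] == "" and rows[0]["col"] == ""
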