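"""Window scan, cluster/hotspot calls, naming, chance false-positive rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaqtl import (
    DetectionConfig,
    detect_clusters,
    detect_hotspots,
    estimate_false_positive_rate,
    scan_windows,
)

from conftest import placed_records


def brute_force_regions(positions, window, min_count):
    """Independent oracle: enumerate every anchored window, union-find merge."""
    x = sorted(positions)
    n = len(x)
    sets = []
    for i in range(n):
        members = {j for j in range(n) if x[i] <= x[j] <= x[i] + window}
        if len(members) >= min_count:
            sets.append(members)
    merged: list[set] = []
    for s in sets:
        acc = set(s)
        rest = []
        for t in merged:
            if acc & t:
                acc |= t
            else:
                rest.append(t)
        merged = rest + [acc]
    return sorted(
        (min(x[j] for j in s), max(x[j] for j in s), tuple(sorted(s))) for s in merged
    )


def as_triples(regions):
    return sorted((s, e, tuple(m)) for s, e, m in regions)


class TestScanWindows:
    def test_four_points_in_one_window(self):
        assert scan_windows([1, 3, 5, 18], 20, 4) == [(1.0, 18.0, [0, 1, 2, 3])]

    def test_below_threshold_yields_nothing(self):
        assert scan_windows([1, 3, 5], 20, 4) == []

    def test_two_separated_groups(self):
        regions = scan_windows([0, 2, 4, 6, 50, 52, 54, 56], 20, 4)
        assert as_triples(regions) == [
            (0.0, 6.0, (0, 1, 2, 3)),
            (50.0, 56.0, (4, 5, 6, 7)),
        ]

    def test_empty_input(self):
        assert scan_windows([], 20, 4) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            scan_windows([5, 1, 3], 20, 2)

    def test_members_partition_across_regions(self):
        rng = np.random.default_rng(11)
        x = np.sort(rng.uniform(0, 200, 40))
        regions = scan_windows(x, 15, 3)
        seen = [i for _, _, members in regions for i in members]
        assert len(seen) == len(set(seen))

    @given(
        positions=st.lists(
            st.floats(0, 120, allow_nan=False, allow_infinity=False),
            min_size=0, max_size=12,
        ),
        window=st.floats(1, 40),
        min_count=st.integers(2, 5),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, positions, window, min_count):
        x = sorted(positions)
        assert as_triples(scan_windows(x, window, min_count)) == brute_force_regions(
            x, window, min_count
        )


class TestDetectClusters:
    def test_four_qtl_of_four_traits_form_one_cluster(self):
        recs = placed_records("c1", [2, 7, 12, 18], ["FS", "FL", "Micro", "BW"])
        (call,) = detect_clusters(recs)
        assert call.name == "c1-cluster-1"
        assert call.n_qtl == 4 and call.n_traits == 4

    def test_single_trait_group_is_not_a_cluster(self):
        recs = placed_records("c1", [2, 4, 6, 8, 10], ["Micro"])
        assert detect_clusters(recs) == []
        # ... but it is a hotspot candidate
        assert len(detect_hotspots(recs)) == 1

    def test_two_planted_groups_well_apart_give_two_clusters(self):
        recs = placed_records("c5", [10, 12, 14, 16], ["FS", "FL"]) + placed_records(
            "c5", [70, 72, 74, 76], ["Micro", "VW"]
        )
        calls = detect_clusters(recs)
        assert [c.name for c in calls] == ["c5-cluster-1", "c5-cluster-2"]
        assert calls[0].start >= 10 - 20 and calls[0].end <= 16 + 20
        assert calls[1].start >= 70 - 20 and calls[1].end <= 76 + 20

    def test_calls_invariant_to_input_order(self):
        recs = placed_records("c1", [2, 7, 12, 18, 60, 63, 66, 69], ["FS", "FL", "Micro"])
        forward = detect_clusters(recs)
        backward = detect_clusters(list(reversed(recs)))
        assert [(c.name, c.start, c.end, c.n_qtl) for c in forward] == [
            (c.name, c.start, c.end, c.n_qtl) for c in backward
        ]

    def test_ci_overlap_membership_admits_wide_ci_neighbours(self):
        core = placed_records("c1", [10, 12, 14, 16], ["FS", "FL"], ci_half=1.0)
        # far outside any qualifying window, but its CI reaches into the call
        wide = placed_records("c1", [45], ["VW"], ci_half=30.0)
        point_call = detect_clusters(core + wide)[0]
        ci_call = detect_clusters(core + wide, DetectionConfig(membership="ci-overlap"))[0]
        assert point_call.n_qtl == 4
        assert ci_call.n_qtl == 5


class TestDetectHotspots:
    def test_single_trait_filter(self):
        recs = placed_records("c1", [2, 6, 10, 14], ["Micro"]) + placed_records(
            "c1", [8], ["FS"]
        )
        (call,) = detect_hotspots(recs)
        assert call.trait == "Micro" and call.n_qtl == 4

    def test_three_qtl_below_default_threshold(self):
        recs = placed_records("c16", [1, 3, 5], ["VW"])
        assert detect_hotspots(recs) == []

    def test_separated_groups_named_in_order(self):
        # three VW groups on c16 with > window gaps, then two on c23
        recs = (
            placed_records("c16", [0, 5, 10, 15, 20], ["VW"])
            + placed_records("c16", [45, 48, 51, 54, 57, 60, 63], ["VW"])
            + placed_records("c16", [90, 94, 98, 102], ["VW"])
            + placed_records("c23", [0, 4, 8, 12, 16, 21], ["VW"], study="s2")
            + placed_records("c23", [60, 64, 68, 72], ["VW"], study="s2")
        )
        calls = detect_hotspots(recs)
        assert [c.name for c in calls] == [
            "c16-VW-Hotspot-1",
            "c16-VW-Hotspot-2",
            "c16-VW-Hotspot-3",
            "c23-VW-Hotspot-4",
            "c23-VW-Hotspot-5",
        ]
        assert [c.n_qtl for c in calls] == [5, 7, 4, 6, 4]

    def test_hotspots_lie_within_joint_density_clusters(self):
        rng = np.random.default_rng(5)
        positions = np.sort(
            np.concatenate([rng.normal(20, 3, 8), rng.normal(90, 3, 8)])
        ).clip(0)
        recs = placed_records("c3", positions, ["Micro", "Micro", "FS"])
        hotspots = detect_hotspots(recs)
        clusters = detect_clusters(recs, DetectionConfig(min_traits=1))
        assert hotspots, "expected at least one hotspot in this geometry"
        for h in hotspots:
            assert any(
                c.chromosome == h.chromosome and c.start <= h.end and h.start <= c.end
                for c in clusters
            )


class TestFalsePositiveRate:
    def test_impossible_below_min_cluster(self):
        assert estimate_false_positive_rate(3, 100.0) == 0.0

    def test_certain_when_window_covers_chromosome(self):
        cfg = DetectionConfig(window=200.0)
        assert estimate_false_positive_rate(4, 100.0, cfg) == 1.0

    def test_deterministic_given_seed(self):
        cfg = DetectionConfig(fpr_reps=2000, seed=77)
        a = estimate_false_positive_rate(10, 100.0, cfg)
        b = estimate_false_positive_rate(10, 100.0, cfg)
        assert a == b

    def test_matches_independent_scan_based_estimate(self):
        cfg = DetectionConfig(fpr_reps=20_000, seed=123)
        est = estimate_false_positive_rate(10, 100.0, cfg)
        # independent route: per-replicate uniform draws checked with scan_windows
        rng = np.random.default_rng(4242)
        reps = 4000
        hits = sum(
            bool(scan_windows(np.sort(rng.uniform(0, 100, 10)), 20.0, 4))
            for _ in range(reps)
        )
        p = hits / reps
        se = np.sqrt(p * (1 - p) / reps + est * (1 - est) / cfg.fpr_reps)
        assert abs(est - p) <= 3 * se

    def test_monotone_in_window_count_and_threshold(self):
        cfg = lambda **kw: DetectionConfig(fpr_reps=20_000, seed=9, **kw)
        assert estimate_false_positive_rate(
            10, 100.0, cfg(window=10.0)
        ) <= estimate_false_positive_rate(10, 100.0, cfg(window=30.0))
        assert estimate_false_positive_rate(
            8, 100.0, cfg()
        ) <= estimate_false_positive_rate(14, 100.0, cfg())
        assert estimate_false_positive_rate(
            10, 100.0, cfg(min_cluster=6)
        ) <= estimate_false_positive_rate(10, 100.0, cfg(min_cluster=4))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"window": 0.0},
            {"min_cluster": 1},
            {"min_traits": 0},
            {"membership": "fuzzy"},
        ],
    )
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            DetectionConfig(**kw)
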