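"""sp_detection: kernel sum, sync events, co-firing graph, scope labels."""

import numpy as np
import pytest

from ninsync import (
    EventTrain,
    build_sp_graph,
    classify_sp_scope,
    detect_sync_events,
    epanechnikov,
    kernel_sum,
)


def make_train(cid, onsets, region="CBL"):
    onsets = np.asarray(onsets, dtype=float)
    return EventTrain(cid, region, np.sort(onsets), np.ones(onsets.size))


# ---------------------------------------------------------------- oracles

def brute_kernel_sum(trains, grid, h):
    S = np.zeros_like(grid)
    for tr in trains:
        for t0 in tr.onsets:
            for i, g in enumerate(grid):
                if abs(g - t0) <= h:
                    S[i] += 1.0 - ((g - t0) / h) ** 2
    return S


def brute_pair_counts(events, trains):
    counts = {}
    cells = [tr.cell_id for tr in trains]
    by_id = {tr.cell_id: tr.onsets for tr in trains}
    for ev in events:
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                a_in = np.any((by_id[a] >= ev.t0) & (by_id[a] < ev.t1))
                b_in = np.any((by_id[b] >= ev.t0) & (by_id[b] < ev.t1))
                if a_in and b_in:
                    key = tuple(sorted((a, b)))
                    counts[key] = counts.get(key, 0) + 1
    return counts


class TestEpanechnikov:
    def test_closed_form(self):
        h = 0.1
        assert epanechnikov(0.0, h) == 1.0
        assert epanechnikov(h, h) == 0.0
        assert epanechnikov(-h, h) == 0.0
        assert epanechnikov(h / 2, h) == pytest.approx(0.75)

    def test_integral_four_thirds_h(self):
        h = 0.1
        t = np.linspace(-2 * h, 2 * h, 100001)
        integral = np.trapezoid(epanechnikov(t, h), t)
        assert integral == pytest.approx(4 * h / 3, rel=1e-6)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            epanechnikov(0.0, 0.0)


class TestKernelSum:
    def test_single_onset_is_kernel(self):
        series = kernel_sum([make_train("a", [5.0])], h_s=0.1, dt_s=0.01,
                            duration_s=10.0)
        k = int(round(5.0 / 0.01))
        assert series.S[k] == pytest.approx(1.0)
        assert series.S.max() == pytest.approx(1.0)

    def test_superposition(self):
        trains = [make_train("a", [5.0]), make_train("b", [5.0])]
        series = kernel_sum(trains, duration_s=10.0)
        assert series.S.max() == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        trains = [
            make_train(f"c{i}", np.sort(rng.uniform(0, 20, size=10)))
            for i in range(10)
        ]
        series = kernel_sum(trains, h_s=0.1, dt_s=0.02, duration_s=20.0)
        oracle = brute_kernel_sum(trains, series.grid_ts, 0.1)
        np.testing.assert_allclose(series.S, oracle, atol=1e-9)

    def test_resolution_guard(self):
        with pytest.raises(ValueError, match="dt_s"):
            kernel_sum([make_train("a", [1.0])], h_s=0.1, dt_s=0.05)

    def test_empty_list_error(self):
        with pytest.raises(ValueError, match="empty"):
            kernel_sum([])

    def test_nonnegative_and_threshold_above_mean(self):
        series = kernel_sum([make_train("a", [1.0, 2.0, 3.0])], duration_s=5.0)
        assert np.all(series.S >= 0)
        assert series.threshold > series.mu


class TestSyncEvents:
    def test_no_onsets_no_events(self):
        series = kernel_sum([make_train("a", [])], duration_s=5.0)
        assert detect_sync_events(series, [make_train("a", [])]) == []

    def test_planted_ensemble_recovered(self, rng):
        fire_times = np.arange(2.0, 30.0, 3.0)
        trains = [
            make_train(f"c{i}", fire_times + rng.normal(0, 0.005, fire_times.size))
            for i in range(6)
        ]
        series = kernel_sum(trains, duration_s=32.0)
        events = detect_sync_events(series, trains)
        assert len(events) == fire_times.size
        for ev in events:
            assert len(ev.participants) == 6

    def test_half_open_boundary(self):
        # a cell whose only onset sits exactly at the interval end t1 is
        # not a participant
        trains = [make_train("a", [5.0]), make_train("b", [5.0]),
                  make_train("c", [5.0]), make_train("edge", [9.0])]
        series = kernel_sum(trains, duration_s=10.0)
        events = detect_sync_events(series, trains)
        assert len(events) >= 1
        ev = events[0]
        probe = make_train("probe", [ev.t1])
        series2 = kernel_sum(trains + [probe], duration_s=10.0)
        events2 = detect_sync_events(series2, trains + [probe])
        matching = [e for e in events2 if abs(e.t0 - ev.t0) < 0.05]
        if matching and np.isclose(matching[0].t1, ev.t1):
            assert "probe" not in matching[0].participants


class TestSpGraph:
    def _events_from(self, trains, duration):
        series = kernel_sum(trains, duration_s=duration)
        return detect_sync_events(series, trains)

    def test_min_co_boundary(self):
        # pair sharing 4 events -> edge present but not an SP;
        # 5 shared events -> SP (the >= 5 rule is boundary-inclusive)
        for n_shared, expect_sp in [(4, False), (5, True)]:
            times = np.arange(1.0, 1.0 + n_shared)
            trains = [make_train("a", times), make_train("b", times)]
            events = self._events_from(trains, times.max() + 1)
            g = build_sp_graph(events, trains, min_co=5)
            assert g.has_edge("a", "b")
            assert g["a"]["b"]["co_count"] == n_shared
            assert g["a"]["b"]["sp_flag"] is expect_sp

    def test_matches_brute_force(self, rng):
        trains = [
            make_train(f"c{i}", np.sort(rng.uniform(0, 20, size=6)),
                       region="CBL" if i < 4 else "CTX")
            for i in range(8)
        ]
        events = self._events_from(trains, 20.0)
        g = build_sp_graph(events, trains)
        oracle = brute_pair_counts(events, trains)
        got = {
            tuple(sorted((a, b))): d["co_count"]
            for a, b, d in g.edges(data=True)
        }
        assert got == oracle

    def test_multiple_onsets_count_once(self):
        # one cell firing twice inside a sync event still counts once
        trains = [make_train("a", [5.0, 5.03]), make_train("b", [5.01]),
                  make_train("c", [5.02])]
        events = self._events_from(trains, 10.0)
        g = build_sp_graph(events, trains, min_co=1)
        assert g["a"]["b"]["co_count"] == 1

    def test_shift_invariance(self, rng):
        trains = [
            make_train(f"c{i}", np.sort(rng.uniform(0, 20, size=8)))
            for i in range(5)
        ]
        def co_counts(shift):
            shifted = [
                make_train(tr.cell_id, tr.onsets + shift) for tr in trains
            ]
            events = self._events_from(shifted, 20.0 + shift)
            g = build_sp_graph(events, shifted, min_co=1)
            return {
                tuple(sorted((a, b))): d["co_count"]
                for a, b, d in g.edges(data=True)
            }
        assert co_counts(0.0) == co_counts(7.0)

    def test_min_co_monotonicity(self, rng):
        trains = [
            make_train(f"c{i}", np.sort(rng.uniform(0, 30, size=15)))
            for i in range(6)
        ]
        events = self._events_from(trains, 30.0)
        def sp_edges(min_co):
            g = build_sp_graph(events, trains, min_co=min_co)
            return {
                (a, b) for a, b, d in g.edges(data=True) if d["sp_flag"]
            }
        e2, e3, e5 = sp_edges(2), sp_edges(3), sp_edges(5)
        assert e5 <= e3 <= e2


class TestScope:
    def test_single_region_no_across(self):
        times = np.arange(1.0, 9.0)
        trains = [make_train(c, times, region="CBL") for c in "abc"]
        series = kernel_sum(trains, duration_s=10.0)
        g = build_sp_graph(detect_sync_events(series, trains), trains)
        scope = classify_sp_scope(g)
        assert scope.n_across == 0
        assert scope.n_within.get("CBL", 0) == 3

    def test_bipartite_ensemble_all_across(self):
        times = np.arange(1.0, 9.0)
        trains = [make_train("a1", times, "CBL"), make_train("b1", times, "CTX")]
        series = kernel_sum(trains, duration_s=10.0)
        g = build_sp_graph(detect_sync_events(series, trains), trains)
        scope = classify_sp_scope(g)
        assert scope.n_across == 1
        assert scope.n_within == {}
        assert scope.participation_across == {"CBL": 1.0, "CTX": 1.0}

    def test_participation_in_unit_interval(self, default_session):
        _, (tm, _, _, truth) = default_session
        trains = [
            EventTrain(cid, reg, truth.onsets[cid],
                       np.ones(truth.onsets[cid].size))
            for cid, reg in zip(tm.cell_ids, tm.region)
        ]
        series = kernel_sum(trains, duration_s=tm.duration_s)
        g = build_sp_graph(detect_sync_events(series, trains), trains)
        scope = classify_sp_scope(g)
        for d in (scope.participation_within, scope.participation_across):
            for v in d.values():
                assert 0.0 <= v <= 1.0
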