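"""Wave connectivity rule, component reconstruction and spread area."""

import numpy as np
import pandas as pd
import pytest

import calwave as cw
from calwave.wave import WaveParams, build_wave, connectivity_predicate, wave_area


def _cells(centers, r=5.0, px=1.0, field=(600, 600)):
    return cw.CellMap(np.asarray(centers, dtype=float), r, px, field)


def _peaks(times_by_cell):
    rows = []
    for cid, times in times_by_cell.items():
        for t in np.atleast_1d(times):
            rows.append(
                {"cell_id": cid, "peak_frame": int(round(t * 2)),
                 "peak_time_s": float(t), "amplitude": 1.4}
            )
    return pd.DataFrame(rows)


class TestPredicate:
    def test_within_lag_and_distance_connected(self):
        cells = _cells([[0.0, 0.0], [15.0, 0.0]])  # 1.5 cell sizes apart
        peaks = _peaks({0: 10.0, 1: 13.0})
        assert connectivity_predicate(0, 1, peaks, cells)

    def test_lag_exactly_four_seconds_not_connected(self):
        cells = _cells([[0.0, 0.0], [15.0, 0.0]])
        peaks = _peaks({0: 10.0, 1: 14.0})
        assert not connectivity_predicate(0, 1, peaks, cells)

    def test_peakless_cell_connects_to_nothing(self):
        cells = _cells([[0.0, 0.0], [5.0, 0.0]])
        peaks = _peaks({0: 10.0})
        assert not connectivity_predicate(0, 1, peaks, cells)

    def test_distance_rule(self):
        # cell size 10 um, multiplier 2.5 -> cutoff 25 um, strict
        peaks = _peaks({0: 10.0, 1: 10.5})
        assert connectivity_predicate(0, 1, peaks, _cells([[0, 0], [24.9, 0]]))
        assert not connectivity_predicate(
            0, 1, peaks, _cells([[0, 0], [25.0, 0]])
        )

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        cells = _cells(rng.uniform(0, 100, (6, 2)))
        peaks = _peaks({i: rng.uniform(0, 30) for i in range(5)})
        for a in range(6):
            for b in range(6):
                assert connectivity_predicate(
                    a, b, peaks, cells
                ) == connectivity_predicate(b, a, peaks, cells)

    def test_closest_pair_of_peaks_used(self):
        cells = _cells([[0.0, 0.0], [10.0, 0.0]])
        peaks = _peaks({0: [10.0, 100.0], 1: [50.0, 102.0]})
        assert connectivity_predicate(0, 1, peaks, cells)


class TestBuildWave:
    def test_chain_fully_recovered(self):
        # 5 cells in a line, 2 cell sizes apart, successive lags 1 s
        cells = _cells([[20.0 * i, 0.0] for i in range(5)])
        peaks = _peaks({i: 10.0 + i for i in range(5)})
        result = build_wave(cells, peaks, 0)
        assert result.member_cell_ids == frozenset(range(5))
        assert result.n_cells == 5

    def test_disconnected_cluster_reported_as_spontaneous(self):
        cells = _cells(
            [[0.0, 0.0], [15.0, 0.0], [300.0, 300.0], [315.0, 300.0]]
        )
        peaks = _peaks({0: 10.0, 1: 11.0, 2: 100.0, 3: 101.0})
        result = build_wave(cells, peaks, 0)
        assert result.member_cell_ids == frozenset({0, 1})
        assert result.spontaneous_clusters == [frozenset({2, 3})]

    def test_stimulated_without_peak_gives_empty_wave(self):
        cells = _cells([[0.0, 0.0], [15.0, 0.0], [30.0, 0.0]])
        peaks = _peaks({1: 10.0, 2: 11.0})
        with pytest.warns(UserWarning, match="no detected peak"):
            result = build_wave(cells, peaks, 0)
        assert result.n_cells == 0
        assert result.spontaneous_clusters == [frozenset({1, 2})]

    def test_site_resolves_to_nearest_cell(self):
        cells = _cells([[0.0, 0.0], [30.0, 0.0]])
        peaks = _peaks({0: 10.0, 1: 11.0})
        result = build_wave(cells, peaks, (2.0, 1.0))
        assert result.stimulated_cell_id == 0

    def test_distant_site_rejected(self):
        cells = _cells([[0.0, 0.0]])
        peaks = _peaks({0: 10.0})
        with pytest.raises(ValueError, match="refusing"):
            build_wave(cells, peaks, (50.0, 50.0))

    def test_matches_bfs_oracle_on_random_instances(self):
        # brute-force BFS over the full predicate adjacency matrix
        rng = np.random.default_rng(7)
        for trial in range(5):
            n = int(rng.integers(50, 200))
            cells = _cells(rng.uniform(0, 400, (n, 2)))
            peaked = rng.random(n) < 0.6
            peaks = _peaks(
                {i: rng.uniform(0, 60) for i in range(n) if peaked[i]}
            )
            if not peaked[0]:
                peaks = pd.concat(
                    [peaks, _peaks({0: 30.0})], ignore_index=True
                )
            params = WaveParams()
            adj = np.zeros((n, n), dtype=bool)
            for a in range(n):
                for b in range(a + 1, n):
                    if connectivity_predicate(a, b, peaks, cells, params):
                        adj[a, b] = adj[b, a] = True
            seen = {0}
            frontier = [0]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in np.nonzero(adj[u])[0]:
                        if v not in seen:
                            seen.add(int(v))
                            nxt.append(int(v))
                frontier = nxt
            result = build_wave(cells, peaks, 0, params)
            assert result.member_cell_ids == frozenset(seen)

    def test_enlarging_parameters_never_shrinks_wave(self):
        rng = np.random.default_rng(9)
        cells = _cells(rng.uniform(0, 200, (60, 2)))
        peaks = _peaks({i: rng.uniform(0, 40) for i in range(60)})
        base = build_wave(cells, peaks, 0, WaveParams(2.0, 2.0))
        wider = build_wave(cells, peaks, 0, WaveParams(3.0, 2.0))
        farther = build_wave(cells, peaks, 0, WaveParams(2.0, 3.0))
        assert base.member_cell_ids <= wider.member_cell_ids
        assert base.member_cell_ids <= farther.member_cell_ids


class TestWaveArea:
    def test_empty_wave_zero_area(self):
        cells = _cells([[0.0, 0.0]])
        result = cw.WaveResult(frozenset(), 0, 0.0, None)
        assert wave_area(result, cells) == 0.0

    def test_single_cell_disk_area(self):
        cells = _cells([[50.0, 50.0]], r=10.0)
        result = cw.WaveResult(frozenset({0}), 1, 0.0, 0)
        assert wave_area(result, cells) == pytest.approx(np.pi * 100.0)

    def test_square_minkowski_closed_form(self):
        # 4 members at the corners of a 100 um square, r = 10 um:
        # 100^2 + 4*100*10 + pi*10^2
        cells = _cells(
            [[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]], r=10.0
        )
        result = cw.WaveResult(frozenset(range(4)), 4, 0.0, 0)
        assert wave_area(result, cells) == pytest.approx(
            10000.0 + 4000.0 + np.pi * 100.0
        )

    def test_collinear_members_segment_formula(self):
        # hull degenerates to a 60 um segment: 2*60*r + pi r^2
        cells = _cells([[0.0, 0.0], [30.0, 0.0], [60.0, 0.0]], r=5.0)
        result = cw.WaveResult(frozenset(range(3)), 3, 0.0, 0)
        assert wave_area(result, cells) == pytest.approx(
            600.0 + np.pi * 25.0
        )

    def test_disk_union_method(self):
        cells = _cells([[0.0, 0.0], [100.0, 0.0]], r=5.0)
        result = cw.WaveResult(frozenset({0, 1}), 2, 0.0, 0)
        area = wave_area(result, cells, method="disks")
        assert area == pytest.approx(2 * np.pi * 25.0, rel=1e-3)
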