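"""Temporal std projection, nucleus segmentation, ΔF/F₀ and clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from svim.activity import (ActivityTable, Ellipsoid, SegmentationParams,
                           cluster_traces, detect_evoked, extract_dff,
                           segment_neurons, std_projection)
from svim.errors import ParameterError
from svim.stacks import GridSpec, TimeSeriesStack, VolumeStack


def _series(values, dt=1.0, vox=(2.0, 1.0, 1.0)):
    return TimeSeriesStack(np.asarray(values, dtype=float), dt, vox)


class TestStdProjection:
    def test_constant_series_projects_to_zero(self):
        s = _series(np.ones((5, 3, 4, 4)))
        assert not std_projection(s).values.any()

    def test_alternating_voxel_hand_computation(self):
        # 0,2,0,2 over 4 frames: sample std = 1.1547
        vals = np.zeros((4, 1, 1, 1))
        vals[1::2] = 2.0
        out = std_projection(_series(vals))
        assert out.values[0, 0, 0] == pytest.approx(1.1547, abs=1e-4)

    def test_matches_brute_force_per_voxel(self):
        rng = np.random.default_rng(0)
        vals = rng.random((10, 5, 5, 5))
        out = std_projection(_series(vals)).values
        brute = np.empty((5, 5, 5))
        for z in range(5):
            for y in range(5):
                for x in range(5):
                    v = vals[:, z, y, x]
                    brute[z, y, x] = np.sqrt(((v - v.mean()) ** 2).sum() / (len(v) - 1))
        np.testing.assert_allclose(out, brute, atol=1e-10)

    def test_seconds_window_selects_inclusive_frames(self):
        # t = 1..100 s at 1 volume/s uses exactly frames 1..100 (100 frames)
        vals = np.zeros((102, 1, 1, 1))
        vals[101] = 100.0  # outside the window: must not contribute
        vals[0] = 50.0     # outside the window: must not contribute
        out = std_projection(_series(vals), t_window=(1.0, 100.0))
        assert out.values[0, 0, 0] == 0.0

    def test_single_frame_window_rejected(self):
        with pytest.raises(ParameterError):
            std_projection(_series(np.ones((5, 2, 2, 2))), t_window=(1.0, 1.0))


class TestSegmentation:
    def test_recovers_planted_nuclei_without_false_positives(self, nuclei_phantom):
        series, truth = nuclei_phantom
        cells = segment_neurons(std_projection(series), SegmentationParams())
        det = np.array([c.center for c in cells])
        matched = sum(np.linalg.norm(det - c, axis=1).min() <= 3.0
                      for c in truth.centers)
        false_pos = sum(np.linalg.norm(truth.centers - d, axis=1).min() > 3.0
                        for d in det)
        assert matched >= 48
        assert false_pos == 0

    def test_empty_volume_gives_empty_list(self):
        vol = VolumeStack(np.zeros((8, 16, 16)), (2.5, 1.25, 1.25))
        assert segment_neurons(vol, SegmentationParams()) == []

    def test_two_nuclei_within_lateral_diameter_suppressed_to_one(self):
        grid = GridSpec((16, 48, 48), (2.5, 1.25, 1.25))
        vol = grid.empty()
        sig = np.array([10.0, 5.0, 5.0]) / 2.3548
        from svim.phantoms import _render_blob
        _render_blob(vol.values, grid, (0.0, 0.0, -1.5), sig)
        _render_blob(vol.values, grid, (0.0, 0.0, 1.5), sig)  # 3 um apart
        cells = segment_neurons(vol, SegmentationParams(threshold=0.1))
        assert len(cells) == 1

    def test_descending_score_order(self, nuclei_phantom):
        series, _ = nuclei_phantom
        cells = segment_neurons(std_projection(series), SegmentationParams())
        scores = [c.score for c in cells]
        assert scores == sorted(scores, reverse=True)


class TestExtractDff:
    def test_constant_series_gives_zero_traces(self):
        vals = np.full((20, 8, 16, 16), 50.0)
        s = _series(vals, vox=(2.5, 1.25, 1.25))
        ells = [Ellipsoid((10.0, 0.0, 0.0), 10.0, 5.0, 1.0)]
        for method in ("rolling_percentile", "global_percentile"):
            table = extract_dff(s, ells, method)
            assert table.valid[0]
            np.testing.assert_allclose(table.dff[0], 0.0, atol=1e-12)

    def test_step_trace_normalised_by_prestep_baseline(self):
        vals = np.full((40, 8, 16, 16), 100.0)
        vals[20:] = 150.0
        s = _series(vals, vox=(2.5, 1.25, 1.25))
        ells = [Ellipsoid((10.0, 0.0, 0.0), 10.0, 5.0, 1.0)]
        table = extract_dff(s, ells, "pre_onset_mean", onset_frame=20)
        np.testing.assert_allclose(table.dff[0][:20], 0.0, atol=1e-12)
        np.testing.assert_allclose(table.dff[0][20:], 0.5, atol=1e-12)

    def test_mask_on_empty_background_flagged_invalid(self):
        vals = np.zeros((10, 8, 32, 32))
        vals[:, 4, 16, 16] = 1000.0  # bright elsewhere; mask region ~ 0
        s = _series(vals, vox=(2.5, 1.25, 1.25))
        ells = [Ellipsoid((2.5, -10.0, -10.0), 10.0, 5.0, 1.0)]
        table = extract_dff(s, ells)
        assert not table.valid[0]
        assert np.isfinite(table.dff).all()


def _table(dff):
    n = len(dff)
    return ActivityTable(centers=np.zeros((n, 3)), dff=np.asarray(dff, float),
                         valid=np.ones(n, bool), scores=np.ones(n),
                         frame_interval=1.0)


class TestClustering:
    def _planted(self, noise=0.02, n=40, T=120):
        tr = np.zeros((n, T))
        tr[:n // 2, 20:30] = 1.0
        tr[n // 2:, 60:] = 2.0
        rng = np.random.default_rng(5)
        return tr + noise * rng.standard_normal(tr.shape)

    def test_two_planted_groups_recovered_exactly(self):
        tbl = cluster_traces(_table(self._planted()), 2, seed=5)
        truth = np.array([0] * 20 + [1] * 20)
        assert adjusted_rand_score(truth, tbl.cluster) == 1.0

    def test_k_of_one_rejected(self):
        with pytest.raises(ParameterError):
            cluster_traces(_table(self._planted()), 1, seed=0)

    def test_same_seed_same_labels(self):
        a = cluster_traces(_table(self._planted()), 3, seed=7).cluster
        b = cluster_traces(_table(self._planted()), 3, seed=7).cluster
        np.testing.assert_array_equal(a, b)

    def test_identical_traces_collapse_to_single_cluster(self):
        tbl = cluster_traces(_table(np.ones((5, 30))), 2, seed=0)
        assert set(tbl.cluster) == {0}


class TestEvoked:
    def test_planted_responsive_subgroup_flagged(self):
        tr = 0.01 * np.random.default_rng(1).standard_normal((100, 150))
        tr[70:, 100:] += 1.0  # 30 cells respond to the light at frame 100
        tbl = cluster_traces(_table(tr), 2, seed=3)
        tbl = detect_evoked(tbl, 100)
        responders = np.zeros(100, bool)
        responders[70:] = True
        np.testing.assert_array_equal(tbl.evoked, responders)

    def test_no_responsive_cells_no_flag(self):
        tr = 0.01 * np.random.default_rng(2).standard_normal((20, 80))
        tbl = cluster_traces(_table(tr), 2, seed=3)
        tbl = detect_evoked(tbl, 40)
        assert not tbl.evoked.any()

    def test_all_cells_responsive_flags_only_max_increase_cluster(self):
        tr = 0.01 * np.random.default_rng(3).standard_normal((40, 100))
        tr[:20, 50:60] += 1.0  # transient responders: small sustained increase
        tr[20:, 50:] += 2.0    # sustained responders: the max-increase group
        tbl = cluster_traces(_table(tr), 2, seed=1)
        tbl = detect_evoked(tbl, 50)
        flagged_clusters = set(tbl.cluster[tbl.evoked])
        assert len(flagged_clusters) == 1
        assert tbl.evoked[20:].all() and not tbl.evoked[:20].any()
        assert len(tbl.cluster_scores) == 2  # others reported with scores

    def test_onset_at_final_frame_rejected(self):
        tbl = cluster_traces(_table(self_tr := np.random.default_rng(0).random((10, 20))), 2, seed=0)
        with pytest.raises(ParameterError):
            detect_evoked(tbl, 19)


def test_pipeline_recovers_planted_active_cells_end_to_end(nuclei_phantom):
    """std projection -> segmentation -> dF/F0 recovers >= 95% of planted
    active cells with transient-bearing traces."""
    series, truth = nuclei_phantom
    cells = segment_neurons(std_projection(series), SegmentationParams())
    table = extract_dff(series, cells, "global_percentile")
    assert table.valid.sum() >= 0.95 * truth.n
    # extracted traces show the planted transients: positive peaks well above
    # baseline for matched cells
    peaks = table.dff.max(axis=1)
    assert (peaks[table.valid] > 0.1).mean() >= 0.95
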