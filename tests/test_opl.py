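"""Segmentation, tracking and population half-life statistics."""
import itertools
import numpy as np
import pytest
from scipy import stats

from protflux import (
    OPLSimParams,
    RunConfig,
    compare_halflife_distributions,
    gen_opl_stack,
    population_halflives,
    segment_cells,
    track_cells,
)


def exact_ks_two_sample(a, b):
    """Brute-force two-sample KS: enumerate all assignments of the pooled
    sample into groups of sizes (n1, n2) and count splits with D >= D_obs."""
    a, b = np.sort(a), np.sort(b)
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size

    def ks_d(x, y):
        grid = np.sort(np.concatenate([x, y]))
        cx = np.searchsorted(x, grid, side="right") / x.size
        cy = np.searchsorted(y, grid, side="right") / y.size
        return np.max(np.abs(cx - cy))

    d_obs = ks_d(a, b)
    total = extreme = 0
    idx = np.arange(pooled.size)
    for combo in itertools.combinations(idx, n1):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(combo)] = True
        d = ks_d(np.sort(pooled[sel]), np.sort(pooled[~sel]))
        total += 1
        extreme += d >= d_obs - 1e-12
    return d_obs, extreme / total


class TestSegmentation:
    def test_blank_frame_empty(self):
        assert segment_cells(np.zeros((64, 64))) == []

    def test_recovers_planted_blobs(self):
        params = OPLSimParams(n_cells=5, field_shape=(256, 256), seed=21)
        stack, truth = gen_opl_stack(params)
        rois = segment_cells(stack.green[0], RunConfig(), red_frame=stack.red[0])
        assert len(rois) == 5
        planted = truth[truth.frame == 0][["row", "col"]].to_numpy()
        for roi in rois:
            dists = np.hypot(planted[:, 0] - roi.centroid[0],
                             planted[:, 1] - roi.centroid[1])
            assert dists.min() < 2.0

    def test_small_objects_excluded(self):
        frame = np.zeros((64, 64))
        frame[10:20, 10:20] = 100.0  # 100 px, above min_area
        frame[40:42, 40:42] = 100.0  # 4 px, below min_area
        rois = segment_cells(frame, RunConfig(min_area_px=20))
        assert len(rois) == 1
        assert rois[0].area_px == 100


class TestTracking:
    def test_static_cell_full_track(self):
        params = OPLSimParams(n_cells=1, drift_px_per_frame=0.0,
                              field_shape=(128, 128), seed=22)
        stack, _ = gen_opl_stack(params)
        tracks = track_cells(stack)
        assert len(tracks) == 1
        assert tracks[0].n_valid == stack.n_frames

    def test_drifting_cells_keep_identity(self):
        params = OPLSimParams(n_cells=2, drift_px_per_frame=2.0,
                              field_shape=(256, 256), seed=23)
        stack, truth = gen_opl_stack(params)
        tracks = track_cells(stack)
        assert len(tracks) == 2
        # each track's centroid path must follow one planted cell throughout
        for tr in tracks:
            errs = []
            for cid in truth.cell_id.unique():
                path = truth[truth.cell_id == cid].sort_values("frame")
                err = [
                    np.hypot(r.centroid[0] - row.row, r.centroid[1] - row.col)
                    for r, (_, row) in zip(tr.rois, path.iterrows())
                    if r is not None
                ]
                errs.append(np.max(err))
            assert min(errs) < 2.0  # consistently near exactly one truth path

    def test_vanishing_cell_flagged_short(self):
        params = OPLSimParams(n_cells=1, drift_px_per_frame=0.0,
                              field_shape=(128, 128), seed=24)
        stack, _ = gen_opl_stack(params)
        # erase the cell after frame 3 by replacing frames with background
        bg = np.full_like(stack.red[0], 100.0)
        for f in range(4, stack.n_frames):
            stack.green[f] = bg
            stack.red[f] = bg
        tracks = track_cells(stack, RunConfig(min_timepoints=5))
        assert len(tracks) == 1
        assert tracks[0].n_valid == 4
        assert tracks[0].is_short


class TestPopulation:
    def test_parameter_recovery_at_scale(self):
        params = OPLSimParams(n_cells=150, field_shape=(900, 900), seed=25)
        stack, truth = gen_opl_stack(params)
        pop = population_halflives(track_cells(stack))
        est_median = np.median(pop.t_half_values)
        assert est_median == pytest.approx(20.0, rel=0.10)

    def test_qc_exclusions_counted(self):
        params = OPLSimParams(n_cells=5, field_shape=(256, 256),
                              drift_px_per_frame=0.0, seed=26)
        stack, _ = gen_opl_stack(params)
        # freeze the red channel: cells present but non-decaying
        for f in range(1, stack.n_frames):
            stack.red[f] = stack.red[0]
        pop = population_halflives(track_cells(stack))
        assert len(pop.passed) == 0
        assert pop.qc_counts.get("non_decaying", 0) + pop.qc_counts.get(
            "poor_fit", 0
        ) == len(pop.estimates)


class TestDistributionComparison:
    def test_self_comparison(self):
        a = np.array([10.0, 12.0, 15.0, 20.0])
        res = compare_halflife_distributions(a, a)
        assert res["D"] == 0.0
        assert res["p"] == 1.0

    def test_disjoint_supports(self):
        a = np.arange(1.0, 11.0)
        res = compare_halflife_distributions(a, a + 100.0)
        assert res["D"] == 1.0
        assert res["delta_mean_h"] == pytest.approx(100.0)

    def test_exact_p_matches_enumeration(self, rng):
        """n1 = n2 = 10: the KS p equals full enumeration of the null."""
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(0, 1, 10)
        res = compare_halflife_distributions(a, b)
        _, p_exact = exact_ks_two_sample(a, b)
        assert res["p"] == pytest.approx(p_exact, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_halflife_distributions([], [1.0])
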