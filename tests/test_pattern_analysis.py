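import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

from poredirection.errors import ConfigurationError, DegenerateROIError
from poredirection.image_io import ImageStack
from poredirection.pattern_analysis import (
    CellROI,
    RegionalTrace,
    extract_traces,
    partition_rows,
    region_intensity,
    smooth_trace,
    track_cells,
)

from conftest import truth_to_trace


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def brute_force_regions(frame, mask, field_axis, anode_side):
    """Independent oracle: row-mean-of-means computed pixel by pixel."""
    axis = 1 if field_axis == "x" else 0
    coords = sorted(
        {(x if axis == 1 else y) for y, x in zip(*np.nonzero(mask))}
    )
    if anode_side == "high":
        coords = coords[::-1]
    row_means = []
    for c in coords:
        vals = [
            frame[y, x]
            for y, x in zip(*np.nonzero(mask))
            if (x if axis == 1 else y) == c
        ]
        row_means.append(np.mean(vals))
    n = len(coords)
    k = n // 3
    return (
        float(np.mean(row_means[:k])),
        float(np.mean(row_means[k : n - k])),
        float(np.mean(row_means[n - k :])),
    )


# masks drawn as random blobs with at least 3 occupied rows
@st.composite
def random_masks(draw):
    h = draw(st.integers(8, 24))
    w = draw(st.integers(8, 24))
    mask = draw(
        npst.arrays(bool, (h, w), elements=st.booleans())
    )
    # ensure at least 4 occupied columns and rows by stamping a small block
    y0 = draw(st.integers(0, h - 5))
    x0 = draw(st.integers(0, w - 5))
    mask[y0 : y0 + 5, x0 : x0 + 5] = True
    return mask


class TestPartitionRows:
    def test_nine_rows_split_evenly(self):
        mask = disc_mask((20, 20), (10, 10), 4.2)  # spans 9 columns
        groups = partition_rows(mask, "x", "low")
        assert (len(groups.anode), len(groups.middle), len(groups.cathode)) == (3, 3, 3)

    def test_fifty_rows_split_16_18_16(self):
        # ~50 rows of pixels per cell, split by the one-third rule with
        # the remainder going to the middle group
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:15, 5:55] = True  # 50 columns along x
        groups = partition_rows(mask, "x", "low")
        assert (len(groups.anode), len(groups.middle), len(groups.cathode)) == (16, 18, 16)

    def test_four_rows_split_1_2_1(self):
        # oracle: exhaustive enumeration of the remainder rule for R=4
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 1:5] = True
        groups = partition_rows(mask, "x", "low")
        assert (len(groups.anode), len(groups.middle), len(groups.cathode)) == (1, 2, 1)

    def test_anode_side_high_reverses_order(self):
        mask = np.zeros((8, 10), dtype=bool)
        mask[2:6, 1:7] = True
        low = partition_rows(mask, "x", "low")
        high = partition_rows(mask, "x", "high")
        assert set(low.anode) == set(high.cathode)
        assert set(low.cathode) == set(high.anode)

    def test_degenerate_roi(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[:, 2] = True  # one column only
        with pytest.raises(DegenerateROIError):
            partition_rows(mask, "x", "low")

    @settings(max_examples=60, deadline=None)
    @given(mask=random_masks(), field_axis=st.sampled_from(["x", "y"]),
           anode_side=st.sampled_from(["low", "high"]))
    def test_partition_invariants(self, mask, field_axis, anode_side):
        groups = partition_rows(mask, field_axis, anode_side)
        rows = groups.all_rows
        axis = 1 if field_axis == "x" else 0
        occupied = set(np.nonzero(mask.any(axis=1 - axis))[0].tolist())
        # true partition: union covers all occupied rows, no duplicates
        assert set(rows) == occupied
        assert len(rows) == len(occupied)
        # equal polar groups; middle absorbs the remainder (at most 2 extra)
        assert len(groups.anode) == len(groups.cathode)
        assert 0 <= len(groups.middle) - len(groups.anode) <= 2


class TestRegionIntensity:
    def test_uniform_frame(self, circular_mask):
        frame = np.full(circular_mask.shape, 7.0)
        groups = partition_rows(circular_mask, "x", "low")
        assert region_intensity(frame, circular_mask, groups) == pytest.approx((7, 7, 7))

    def test_row_mean_of_means_not_pooled_mean(self):
        # two anode rows with means 1 and 3 but very different pixel counts
        mask = np.zeros((10, 12), dtype=bool)
        mask[4, 0] = True  # row x=0: single pixel, value 1
        mask[2:8, 1] = True  # row x=1: six pixels, value 3
        mask[4, 2:6] = True  # middle/cathode filler rows
        frame = np.zeros((10, 12))
        frame[4, 0] = 1.0
        frame[2:8, 1] = 3.0
        groups = partition_rows(mask, "x", "low")
        anode, _, _ = region_intensity(frame, mask, groups)
        assert anode == pytest.approx(2.0)  # pooled mean would be 20/7

    def test_gradient_ordering_and_brute_force(self, circular_mask):
        frame = np.tile(np.arange(40, dtype=float), (40, 1))  # increases with x
        groups = partition_rows(circular_mask, "x", "low")
        result = region_intensity(frame, circular_mask, groups)
        assert result[0] < result[1] < result[2]
        oracle = brute_force_regions(frame, circular_mask, "x", "low")
        assert result == pytest.approx(oracle)

    @settings(max_examples=30, deadline=None)
    @given(mask=random_masks(), field_axis=st.sampled_from(["x", "y"]),
           seed=st.integers(0, 2**31))
    def test_agrees_with_brute_force_on_random_masks(self, mask, field_axis, seed):
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 100, size=mask.shape)
        groups = partition_rows(mask, field_axis, "low")
        result = region_intensity(frame, mask, groups)
        oracle = brute_force_regions(frame, mask, field_axis, "low")
        assert result == pytest.approx(oracle)

    def test_mirror_equivariance(self, circular_mask):
        rng = np.random.default_rng(3)
        frame = rng.uniform(0, 100, size=circular_mask.shape)
        frame[~circular_mask] = 0.0
        groups = partition_rows(circular_mask, "x", "low")
        a, m, c = region_intensity(frame, circular_mask, groups)
        flipped = frame[:, ::-1]
        fmask = circular_mask[:, ::-1]
        fgroups = partition_rows(fmask, "x", "low")
        fa, fm, fc = region_intensity(flipped, fmask, fgroups)
        assert (fa, fm, fc) == pytest.approx((c, m, a))


def uniform_stack(frames, **kwargs):
    defaults = dict(frame_interval=0.1, pixel_size=0.5, field_axis="x",
                    anode_side="low", pulse_time=0.25)
    defaults.update(kwargs)
    return ImageStack(frames=frames, **defaults)


class TestTrackCells:
    def test_stationary_cell(self):
        frames = np.zeros((10, 32, 32))
        mask = disc_mask((32, 32), (16, 16), 6)
        frames[:, mask] = 500.0
        stack = uniform_stack(frames)
        tracks = track_cells(stack, [CellROI(0, 0, mask)])
        centroids = tracks[0].centroids()
        assert np.max(np.abs(centroids - centroids[0])) < 1e-9

    def test_moving_cell_recovered(self):
        n = 12
        frames = np.zeros((n, 48, 48))
        for i in range(n):
            frames[i][disc_mask((48, 48), (10 + i, 20), 5)] = 800.0
        stack = uniform_stack(frames)
        tracks = track_cells(stack, [CellROI(0, 0, disc_mask((48, 48), (10, 20), 5))])
        centroids = tracks[0].centroids()
        truth = np.array([(10 + i, 20.0) for i in range(n)])
        assert np.max(np.abs(centroids - truth)) < 0.5

    def test_two_cells_no_identity_swap(self):
        frames = np.zeros((8, 64, 64))
        m1 = disc_mask((64, 64), (16, 16), 5)
        m2 = disc_mask((64, 64), (16, 56), 5)  # 40 px apart
        frames[:, m1] = 600.0
        frames[:, m2] = 600.0
        stack = uniform_stack(frames)
        tracks = track_cells(stack, [CellROI(0, 0, m1), CellROI(1, 0, m2)])
        assert tracks[0].centroids()[-1][1] == pytest.approx(16, abs=1)
        assert tracks[1].centroids()[-1][1] == pytest.approx(56, abs=1)

    def test_blank_frames_fall_back_to_seed_mask(self):
        frames = np.zeros((5, 32, 32))
        mask = disc_mask((32, 32), (16, 16), 6)
        stack = uniform_stack(frames, pulse_time=10.0)
        tracks = track_cells(stack, [CellROI(0, 0, mask)])
        for roi in tracks[0].rois:
            np.testing.assert_array_equal(roi.mask, mask)


class TestExtractTraces:
    def test_uniform_stack_constant_traces(self):
        frames = np.full((6, 32, 32), 300.0)
        mask = disc_mask((32, 32), (16, 16), 6)
        stack = uniform_stack(frames, pulse_time=100.0)  # no baseline frames
        tracks = track_cells(stack, [CellROI(0, 0, mask)])
        traces = extract_traces(stack, tracks, baseline=False)
        for region in ("anode", "middle", "cathode"):
            np.testing.assert_allclose(traces[0].region(region), 300.0)

    def test_symmetric_scenario_small_asymmetry(self, symmetric_truth):
        trace = truth_to_trace(symmetric_truth)
        cell_mean = np.mean(
            [trace.anode, trace.middle, trace.cathode], axis=0
        )
        scale = max(cell_mean.max(), 1e-12)
        assert np.max(np.abs(trace.anode - trace.cathode)) <= 0.02 * scale

    def test_anode_scenario_ordering(self, anode_truth, linear_curve):
        from poredirection.synthetic_data import render_stack

        stack = render_stack(anode_truth, linear_curve)
        tracks = track_cells(stack, [CellROI(0, 0, anode_truth.mask)])
        traces = extract_traces(stack, tracks, curve=linear_curve)
        tr = traces[0]
        config = anode_truth.config
        window = (tr.times >= config.pulse_time + 0.3) & (
            tr.times <= config.pulse_time + 10.0
        )
        assert np.all(tr.anode[window] > tr.middle[window])
        assert np.all(tr.middle[window] > tr.cathode[window])

    def test_baseline_subtraction_zeroes_prepulse(self, anode_truth, linear_curve):
        from poredirection.synthetic_data import render_stack

        stack = render_stack(anode_truth, linear_curve)
        tracks = track_cells(stack, [CellROI(0, 0, anode_truth.mask)])
        traces = extract_traces(stack, tracks, curve=linear_curve, baseline=True)
        pre = traces[0].times < anode_truth.config.pulse_time
        assert np.allclose(traces[0].anode[pre], 0.0, atol=1e-9)

    def test_dye_mismatch_rejected(self, anode_truth, linear_curve):
        from poredirection.calibration import CalibrationCurve
        from poredirection.synthetic_data import render_stack

        stack = render_stack(anode_truth, linear_curve)
        wrong = CalibrationCurve(dye_name="calcein", slope=1.0, intercept=0.0)
        tracks = track_cells(stack, [CellROI(0, 0, anode_truth.mask)])
        with pytest.raises(ConfigurationError):
            extract_traces(stack, tracks, curve=wrong)


class TestSmoothTrace:
    def test_constant_preserved(self):
        series = np.full(50, 4.2)
        np.testing.assert_allclose(smooth_trace(series, 11), series)

    def test_quadratic_reproduced_exactly(self):
        t = np.arange(60, dtype=float)
        series = 0.3 * t**2 - 2.0 * t + 5.0
        np.testing.assert_allclose(smooth_trace(series, 11), series, rtol=1e-10)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(7)
        series = rng.normal(size=500)
        smoothed = smooth_trace(series, 11)
        assert smoothed.var() < series.var()

    @pytest.mark.parametrize("window", [4, 1, 999])
    def test_bad_windows(self, window):
        with pytest.raises(ConfigurationError):
            smooth_trace(np.zeros(20), window)


class TestRegionalTraceInvariants:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            RegionalTrace(0, np.arange(3.0), np.zeros(3), np.zeros(2), np.zeros(3))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ConfigurationError):
            RegionalTrace(0, np.array([0.0, 0.2, 0.1]), np.zeros(3), np.zeros(3),
                          np.zeros(3))
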