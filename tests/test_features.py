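"""Temporal features and topographic map rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsmap.features import (ChannelLayout, FeatureCatalog, MapRenderer,
                              build_feature_set, interval_kurtosis,
                              interval_mean, interval_skewness, interval_slope,
                              render_map, temporal_raw_image, value_at_timepoint)
from nirsmap.hrf import task_response

FS = 8.138


def _ramp_epoch(n=732):
    # y(t) = t seconds, per sample
    return (np.arange(n) / FS)[None, :]


class TestTimepoint:
    def test_index_convention(self):
        epoch = np.arange(732, dtype=float)[None, :]
        # t = 5 s at 8.138 Hz -> sample round(40.69) = 41
        assert value_at_timepoint(epoch, 5.0, FS)[0] == 41

    def test_constant_series(self):
        epoch = np.full((3, 732), 2.5)
        for t in (5, 35, 65):
            np.testing.assert_array_equal(value_at_timepoint(epoch, t, FS), 2.5)

    def test_out_of_epoch_rejected(self):
        with pytest.raises(ValueError):
            value_at_timepoint(np.zeros((1, 732)), 95.0, FS)


class TestIntervalStatistics:
    def test_mean_of_ramp_is_midpoint(self):
        m = interval_mean(_ramp_epoch(), 5.0, 25.0, FS)[0]
        assert m == pytest.approx(15.0, abs=1 / FS)

    def test_mean_linearity_and_constants(self):
        epoch = np.full((2, 732), 1.7)
        np.testing.assert_allclose(interval_mean(epoch, 5, 65, FS), 1.7)
        np.testing.assert_allclose(interval_mean(-epoch, 5, 65, FS), -1.7)

    def test_slope_of_exact_line(self):
        epoch = 0.5 * _ramp_epoch() + 2.0
        assert interval_slope(epoch, 20.0, 60.0, FS)[0] == pytest.approx(0.5)

    def test_slope_of_constant_is_zero(self):
        assert interval_slope(np.full((1, 732), 3.0), 5, 15, FS)[0] == pytest.approx(0.0)

    def test_slope_matches_polyfit_on_noisy_line(self):
        rng = np.random.default_rng(0)
        y = 0.3 * (np.arange(732) / FS) + rng.standard_normal(732)
        ours = interval_slope(y[None, :], 20, 60, FS)[0]
        i0, i1 = round(20 * FS), round(60 * FS)
        t = np.arange(i0, i1 + 1) / FS
        oracle = np.polyfit(t, y[i0 : i1 + 1], 1)[0]
        assert ours == pytest.approx(oracle, rel=1e-9)

    def test_skewness_zero_for_symmetric_samples(self):
        # whole window covers full periods of a symmetric value multiset
        epoch = np.tile([-2.0, -1.0, 0.0, 1.0, 2.0], 150)[None, :]
        assert interval_skewness(epoch, 0.0, 749.0, 1.0)[0] == pytest.approx(
            0.0, abs=1e-12)

    def test_kurtosis_of_two_point_symmetric_values(self):
        # m4 = m2 = 1 for values in {-1, +1} -> kurtosis exactly 1
        epoch = np.tile([-1.0, 1.0], 366)[None, :]
        assert interval_kurtosis(epoch, 0.0, 731.0, 1.0)[0] == pytest.approx(1.0)

    def test_kurtosis_of_gaussian_draws_is_three(self):
        rng = np.random.default_rng(0)
        n = 10**6
        x = rng.standard_normal(n)[None, :]
        k = interval_kurtosis(x, 0.0, float(n - 1), 1.0)[0]
        assert k == pytest.approx(3.0, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            interval_skewness(np.ones((1, 732)), 5, 65, FS)

    def test_noiseless_response_slope_signs(self):
        resp = task_response(FS)[None, :]
        assert interval_slope(resp, 5, 15, FS)[0] > 0       # initial rise
        assert interval_slope(resp, 60, 70, FS)[0] < 0      # post-task fall
        # plateau: near zero relative to the rise slope
        plateau = abs(interval_slope(resp, 20, 60, FS)[0])
        rise = interval_slope(resp, 5, 15, FS)[0]
        assert plateau < 0.05 * rise


class TestLayout:
    def test_default_layout_is_valid(self, layout):
        assert layout.n_channels == 48
        assert len(set(layout.channel_ids)) == 48
        assert (layout.positions >= 0).all() and (layout.positions <= 1).all()

    def test_csv_round_trip(self, tmp_path, layout):
        path = tmp_path / "layout.csv"
        layout.to_csv(path)
        loaded = ChannelLayout.from_csv(path)
        np.testing.assert_allclose(loaded.positions, layout.positions)
        assert loaded.channel_ids == layout.channel_ids

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            ChannelLayout(channel_ids=("a", "b"),
                          positions=np.array([[0.5, 0.5], [0.5, 0.5]]))


class TestRenderMap:
    def test_constant_field_renders_constant(self, layout):
        grid = render_map(np.full(48, 4.0), layout, out_size=50)
        np.testing.assert_allclose(grid, 4.0, rtol=1e-12)
        scaled = render_map(np.full(48, 4.0), layout, out_size=50, scale=(0.0, 8.0))
        np.testing.assert_allclose(scaled, 0.5, rtol=1e-10)

    def test_interpolation_identity_at_channel_pixels(self):
        # positions chosen exactly on pixel centres of a 101-grid
        ids = tuple(f"c{i}" for i in range(4))
        pos = np.array([[0.2, 0.2], [0.8, 0.2], [0.2, 0.8], [0.8, 0.8]])
        layout = ChannelLayout(channel_ids=ids, positions=pos)
        values = np.array([1.0, 2.0, 3.0, 4.0])
        grid = render_map(values, layout, out_size=101)
        for (x, y), v in zip(pos, values):
            row = int(round((1 - y) * 100))
            col = int(round(x * 100))
            assert grid[row, col] == pytest.approx(v, abs=1e-9)

    def test_plane_reproduced_inside_hull(self, layout):
        alpha, beta = 2.0, -1.3
        values = alpha * layout.positions[:, 0] + beta * layout.positions[:, 1]
        renderer = MapRenderer(layout, out_size=80)
        grid = renderer.render(values)
        xs = np.linspace(0, 1, 80)
        ys = np.linspace(1, 0, 80)
        expected = alpha * xs[None, :] + beta * ys[:, None]
        # check strictly interior pixels (inside the hull, linear precision)
        interior = renderer.weights.getnnz(axis=1) == 3
        mask = interior.reshape(80, 80)
        np.testing.assert_allclose(grid[mask], expected[mask], atol=1e-6)

    def test_monotone_in_channel_values(self, layout):
        rng = np.random.default_rng(5)
        values = rng.standard_normal(48)
        base = render_map(values, layout, out_size=40)
        bumped = values.copy()
        bumped[17] += 1.0
        raised = render_map(bumped, layout, out_size=40)
        assert (raised - base >= -1e-12).all()

    def test_input_validation(self, layout):
        with pytest.raises(ValueError):
            render_map(np.zeros(10), layout)
        bad = np.zeros(48)
        bad[0] = np.nan
        with pytest.raises(ValueError):
            render_map(bad, layout)
        with pytest.raises(ValueError):
            render_map(np.zeros(48), layout, scale=(1.0, 1.0))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 47), st.floats(0.1, 5.0))
def test_property_raising_any_channel_never_lowers_pixels(channel, delta):
    layout = ChannelLayout.default_48()
    values = np.zeros(48)
    base = render_map(values, layout, out_size=30)
    values[channel] += delta
    raised = render_map(values, layout, out_size=30)
    assert (raised - base >= -1e-12).all()


class TestFeatureCatalog:
    def test_default_names(self):
        names = FeatureCatalog().names()
        assert len(names) == 13 + 2 + 3 + 1 + 1
        assert "timepoint_15" in names
        assert "slope_20_60" in names
        assert "kurtosis_5_65" in names

    def test_unknown_feature_raises_with_catalog(self):
        with pytest.raises(KeyError):
            FeatureCatalog().compute("median_5_65", np.zeros((1, 732)), FS)


class TestTemporalRaw:
    def test_shape_and_row_broadcast(self):
        img = temporal_raw_image(np.linspace(0, 1, 732), out_size=50)
        assert img.shape == (50, 50)
        np.testing.assert_allclose(img[0], img[-1])
        assert img[0, 0] == pytest.approx(0.0)
        assert img[0, -1] == pytest.approx(1.0)


class TestBuildFeatureSet:
    def test_sample_counts_and_labels(self, strong_epochs, strong_cohort, layout):
        fset = build_feature_set(strong_epochs, strong_cohort.groups, FS,
                                 "n_back", layout,
                                 feature_names=["slope_20_60", "mean_5_65"],
                                 out_size=32)
        # subjects x trials images per feature
        n = len(strong_cohort.subjects) * 3
        assert fset.images["slope_20_60"].shape == (n, 32, 32)
        assert fset.labels.sum() == 4 * 3  # impaired subjects x trials

    def test_empty_roi_gives_zero_temporal_samples(self, strong_epochs,
                                                   strong_cohort, layout):
        roi = {k: np.array([], dtype=int) for k in strong_epochs}
        fset = build_feature_set(strong_epochs, strong_cohort.groups, FS,
                                 "n_back", layout, feature_names=["mean_5_65"],
                                 roi_channels=roi, out_size=16)
        assert fset.temporal.shape[0] == 0
        assert fset.images["mean_5_65"].shape[0] > 0

    def test_temporal_sample_count_matches_roi_total(self, strong_epochs,
                                                     strong_cohort, layout):
        rng = np.random.default_rng(0)
        roi = {k: rng.choice(48, size=rng.integers(1, 5), replace=False)
               for k in strong_epochs}
        fset = build_feature_set(strong_epochs, strong_cohort.groups, FS,
                                 "n_back", layout, feature_names=["mean_5_65"],
                                 roi_channels=roi, out_size=16)
        assert fset.temporal.shape[0] == sum(len(v) for v in roi.values())

    def test_features_ignore_group_relabeling(self, strong_epochs,
                                              strong_cohort, layout):
        flipped = {s: ("control" if g == "impaired" else "impaired")
                   for s, g in strong_cohort.groups.items()}
        a = build_feature_set(strong_epochs, strong_cohort.groups, FS, "n_back",
                              layout, feature_names=["slope_20_60"], out_size=16)
        b = build_feature_set(strong_epochs, flipped, FS, "n_back",
                              layout, feature_names=["slope_20_60"], out_size=16)
        np.testing.assert_array_equal(a.images["slope_20_60"],
                                      b.images["slope_20_60"])
        np.testing.assert_array_equal(a.labels, 1 - b.labels)
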