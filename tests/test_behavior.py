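"""Rating preprocessing: resampling, normalization, ISC, HRF, taper smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import arousalcpm as ac
from arousalcpm.behavior import hrf_kernel, taper_weights


def make_spec(n_tr=4, tr_s=1.5, window_tr=3, **kw):
    return ac.DatasetSpec(tr_s=tr_s, segment_tr=(n_tr,), window_tr=window_tr, **kw)


def events(rows):
    return pd.DataFrame(rows, columns=["rater_id", "time_s", "value"])


def make_panel(z_rows):
    z_rows = np.asarray(z_rows, dtype=float)
    return ac.RaterPanel(rater_ids=[f"r{i}" for i in range(len(z_rows))],
                         raw=z_rows.copy(), z=z_rows)


class TestResample:
    def test_constant_rating(self):
        with pytest.warns(UserWarning, match="constant"):
            panel = ac.resample_ratings(events([("a", 0.0, 13), ("b", 0.0, 13)]),
                                        make_spec())
        np.testing.assert_array_equal(panel.raw, np.full((2, 4), 13.0))

    def test_step_change_lands_at_interval_end(self):
        logs = events([("a", 0.0, 10), ("a", 3.1, 20), ("b", 0.0, 10), ("b", 3.1, 20)])
        panel = ac.resample_ratings(logs, make_spec(n_tr=4, tr_s=1.5))
        np.testing.assert_array_equal(panel.raw[0], [10, 10, 20, 20])

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            ac.resample_ratings(events([]), make_spec())

    def test_late_events_ignored_with_warning(self):
        logs = events([("a", 0.0, 10), ("a", 99.0, 25), ("b", 0.0, 12), ("b", 1.0, 14)])
        with pytest.warns(UserWarning, match="movie end"):
            panel = ac.resample_ratings(logs, make_spec(n_tr=4, tr_s=1.5))
        assert panel.raw[0].max() == 10

    def test_crop_excludes_trs(self):
        logs = events([("a", 0.0, 10), ("a", 3.1, 20), ("b", 0.0, 11), ("b", 2.0, 21)])
        panel = ac.resample_ratings(logs, make_spec(n_tr=4, tr_s=1.5, crop_tr=(0,)))
        assert panel.raw.shape == (2, 3)
        np.testing.assert_array_equal(panel.raw[0], [10, 20, 20])


class TestNormalize:
    def test_three_point_example(self):
        np.testing.assert_allclose(ac.normalize_and_concat([[1, 2, 3]]), [-1, 0, 1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ac.normalize_and_concat([[5, 5, 5]])

    def test_segments_z_scored_jointly(self):
        got = ac.normalize_and_concat([[1, 2], [3, 4]])
        x = np.array([1, 2, 3, 4.0])
        np.testing.assert_allclose(got, (x - 2.5) / x.std(ddof=1))
        assert abs(x.std(ddof=1) - 1.2910) < 1e-4

    def test_idempotent(self):
        x = np.random.default_rng(0).standard_normal(50)
        once = ac.zscore(x)
        np.testing.assert_allclose(ac.zscore(once), once, atol=1e-12)


class TestGroupAverage:
    def test_identical_and_symmetric(self):
        z = ac.zscore(np.arange(6.0))
        np.testing.assert_allclose(ac.group_average(make_panel([z, z])), z)
        np.testing.assert_allclose(ac.group_average(make_panel([z, -z])), np.zeros(6),
                                   atol=1e-15)

    def test_hand_mean(self):
        rows = [[1.0, 2, 3], [2, 3, 4], [6, 1, 2]]
        np.testing.assert_allclose(ac.group_average(make_panel(rows)),
                                   np.mean(rows, axis=0))

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            ac.group_average(make_panel([[1.0, 2, 3]]))


class TestIsc:
    def test_identical_raters_summary_near_one(self):
        z = ac.zscore(np.sin(np.arange(60) / 5))
        res = ac.leave_one_out_isc(make_panel([z] * 4), n_perm=200, seed=0)
        assert res.mean_r > 0.999
        np.testing.assert_allclose(res.per_rater_r, 1.0, atol=1e-9)

    def test_shared_signal_detected(self):
        rng = np.random.default_rng(2)
        latent = ac.generate_latent_state(300, 8, seed=2)
        rows = [ac.zscore(latent + 0.7 * rng.standard_normal(300)) for _ in range(10)]
        res = ac.leave_one_out_isc(make_panel(rows), n_perm=10000, seed=1)
        assert res.mean_r > 0
        assert res.p <= 0.001

    def test_white_noise_panel_near_zero(self):
        """Independent raters: summary near 0; the sign-flip test usually retains
        the null, though it is known to be liberal because the leave-one-out
        correlations share the group mean and are therefore positively dependent,
        which independent sign flips do not capture."""
        hits, biases = 0, []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            rows = [ac.zscore(rng.standard_normal(150)) for _ in range(8)]
            res = ac.leave_one_out_isc(make_panel(rows), n_perm=300, seed=rep)
            hits += res.p > 0.05
            biases.append(res.mean_r)
        assert hits >= 35
        assert abs(np.mean(biases)) < 0.05

    def test_too_few_raters(self):
        z = ac.zscore(np.arange(5.0))
        with pytest.raises(ValueError):
            ac.leave_one_out_isc(make_panel([z, z]))


class TestIscSampleSize:
    def test_identical_raters_have_zero_spread(self):
        z = ac.zscore(np.arange(30.0))
        out = ac.isc_vs_samplesize(make_panel([z] * 6), sizes=[3, 6], n_boot=50, seed=0)
        assert np.allclose(out["sd_z_isc"], 0.0)

    def test_spread_shrinks_with_panel_size(self):
        rng = np.random.default_rng(3)
        latent = ac.generate_latent_state(200, 8, seed=3)
        rows = [ac.zscore(latent + rng.standard_normal(200)) for _ in range(25)]
        out = ac.isc_vs_samplesize(make_panel(rows), sizes=[3, 25], n_boot=200, seed=0)
        assert out.loc[out["size"] == 25, "sd_z_isc"].item() < \
            out.loc[out["size"] == 3, "sd_z_isc"].item()

    def test_deterministic_and_validated(self):
        z = ac.zscore(np.arange(20.0))
        panel = make_panel([z + i for i in range(4)])
        a = ac.isc_vs_samplesize(panel, sizes=[2, 4], n_boot=20, seed=5)
        b = ac.isc_vs_samplesize(panel, sizes=[2, 4], n_boot=20, seed=5)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            ac.isc_vs_samplesize(panel, sizes=[1], n_boot=10, seed=0)


class TestHrf:
    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(ac.convolve_hrf(np.zeros(40), 1.0), np.zeros(40))

    def test_impulse_response_peaks_near_five_seconds(self):
        impulse = np.zeros(40)
        impulse[0] = 1.0
        out = ac.convolve_hrf(impulse, 1.0)
        kernel = hrf_kernel(1.0)
        np.testing.assert_allclose(out[: len(kernel)], kernel)
        np.testing.assert_allclose(out[len(kernel):], 0.0, atol=1e-15)
        assert abs(int(np.argmax(out)) - 5) <= 1

    def test_superposition(self):
        a = np.zeros(60)
        b = np.zeros(60)
        a[3] = 1.0
        b[20] = 2.0
        np.testing.assert_allclose(ac.convolve_hrf(a + b, 1.5),
                                   ac.convolve_hrf(a, 1.5) + ac.convolve_hrf(b, 1.5),
                                   atol=1e-12)


class TestTaperSmooth:
    spec = make_spec(n_tr=60, tr_s=1.0, window_tr=15)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(ac.taper_smooth(np.full(60, 3.3), self.spec),
                                   np.full(60, 3.3))

    def test_linear_ramp_interior_unchanged(self):
        ramp = np.arange(60.0)
        out = ac.taper_smooth(ramp, self.spec)
        np.testing.assert_allclose(out[10:-10], ramp[10:-10], atol=1e-9)

    def test_boundary_pulled_inward(self):
        ramp = np.arange(60.0)
        out = ac.taper_smooth(ramp, self.spec)
        assert out[0] > ramp[0]      # start pulled up toward the interior
        assert out[-1] < ramp[-1]    # end pulled down

    def test_weights_sum_to_one_everywhere(self):
        for center in (0, 1, 30, 59):
            _, w = taper_weights(center, self.spec, 60)
            assert abs(w.sum() - 1) < 1e-12

    @settings(max_examples=20, deadline=None)
    @given(a=st.floats(-3, 3), b=st.floats(-5, 5))
    def test_commutes_with_affine_maps(self, a, b):
        x = np.sin(np.arange(60) / 4)
        lhs = ac.taper_smooth(a * x + b, self.spec)
        rhs = a * ac.taper_smooth(x, self.spec) + b
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_window_longer_than_series(self):
        with pytest.raises(ValueError):
            ac.taper_smooth(np.arange(5.0), self.spec)


class TestValenceSegments:
    spec = make_spec(n_tr=4, tr_s=1.0, window_tr=3)

    def test_threshold_examples(self):
        raw = np.array([12, 14, 13, 15.0])
        pos_idx, _ = ac.extract_valence_segments(
            np.tile(raw, 10), self.spec, "positive")
        raw4 = raw
        idx_pos = np.flatnonzero(raw4 > 13)
        idx_neg = np.flatnonzero(raw4 < 13)
        np.testing.assert_array_equal(idx_pos, [1, 3])
        np.testing.assert_array_equal(idx_neg, [0])
        # on the full tiled series the same TRs recur with period 4
        assert set(pos_idx % 4) == {1, 3}

    def test_neutral_excluded_from_both(self):
        raw = np.full(20, 13.0)
        for mode in ("positive", "negative"):
            idx, series = ac.extract_valence_segments(raw, self.spec, mode)
            assert idx.size == 0 and series.size == 0

    def test_partition(self):
        rng = np.random.default_rng(4)
        raw = rng.integers(1, 26, size=80).astype(float)
        pos, _ = ac.extract_valence_segments(raw, self.spec, "positive")
        neg, _ = ac.extract_valence_segments(raw, self.spec, "negative")
        assert len(set(pos) & set(neg)) == 0
        assert set(pos) | set(neg) <= set(range(80))
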