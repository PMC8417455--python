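"""Morphology feature transforms, moments and per-epoch feature records."""
import numpy as np
import pytest

from phfa import compute_epoch_features, moments, normalize
from phfa.features import (
    FEATURE_IDS,
    curvature,
    feature_columns,
    first_difference,
    line_length,
    rectify,
    records_to_frame,
    teager,
)


class TestNormalize:
    def test_hand_case_sample_sd(self):
        # sample (n-1) sd of {1,2,3} is exactly 1
        np.testing.assert_allclose(normalize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_zero_mean_unit_sd(self, rng):
        y = normalize(rng.standard_normal(10_000) * 7 + 3)
        assert abs(y.mean()) < 1e-9
        assert abs(y.std(ddof=1) - 1.0) < 1e-9

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(1000)
        np.testing.assert_allclose(normalize(3.7 * x + 11.0), normalize(x), atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize(np.full(100, 2.0))


class TestOperators:
    FS_KHZ = 4.096

    def test_constant_input_zero_transforms(self):
        y = np.full(100, 3.0)
        assert np.all(line_length(y, self.FS_KHZ) == 0.0)
        assert np.all(curvature(y, self.FS_KHZ) == 0.0)
        assert np.all(teager(y, self.FS_KHZ) == 0.0)

    def test_output_lengths(self, rng):
        y = rng.standard_normal(100)
        assert rectify(y).shape == (100,)
        assert line_length(y, self.FS_KHZ).shape == (99,)
        assert curvature(y, self.FS_KHZ).shape == (98,)
        assert teager(y, self.FS_KHZ).shape == (98,)

    def test_teager_constant_on_sinusoid(self):
        # closed form: for y_j = A sin(w j + phi), y_j^2 - y_{j+1} y_{j-1} = A^2 sin^2 w
        j = np.arange(4096)
        y = np.sqrt(2.0) * np.sin(np.pi * j / 16)
        expected = 2.0 * np.sin(np.pi / 16) ** 2 * self.FS_KHZ**2
        np.testing.assert_allclose(teager(y, self.FS_KHZ), expected, atol=1e-9)

    def test_line_length_alternating(self):
        y = np.where(np.arange(64) % 2 == 0, 1.0, -1.0)
        np.testing.assert_allclose(line_length(y, self.FS_KHZ), 2.0 * 4.096)

    def test_line_length_is_rectified_difference(self, rng):
        y = rng.standard_normal(500)
        np.testing.assert_allclose(
            line_length(y, self.FS_KHZ), np.abs(first_difference(y, self.FS_KHZ))
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            curvature(np.array([1.0, 2.0]), self.FS_KHZ)


class TestMoments:
    def test_hand_case(self):
        mean, sd, skew, kurt = moments(np.array([1.0, 2.0, 3.0, 4.0]))
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.sqrt(1.25 * 4 / 3))
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.64)

    def test_symmetric_zero_skew(self):
        v = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        assert moments(v)[2] == pytest.approx(0.0, abs=1e-12)

    def test_normal_kurtosis_three(self):
        v = np.random.default_rng(7).standard_normal(1_000_000)
        assert moments(v)[3] == pytest.approx(3.0, abs=0.1)

    def test_permutation_invariance(self, rng):
        v = rng.lognormal(size=200_000)  # heavy-tailed stresses the summation
        a = np.array(moments(v))
        b = np.array(moments(rng.permutation(v)))
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            moments(np.full(10, 1.0))


class TestEpochFeatures:
    def test_feature_grid_size(self, rng):
        rec = compute_epoch_features([rng.standard_normal(10_000)], 4096.0)
        assert rec.valid
        assert sorted(rec.values) == sorted(FEATURE_IDS)
        assert len(feature_columns(2)) == 38
        assert len(feature_columns(3)) == 57

    def test_teager_tone_f4_closed_form(self):
        # normalized 128 Hz tone at 4096 Hz: mean Teager = 2 sin^2(pi/16) fS^2
        j = np.arange(32 * 4096)
        x = np.sqrt(2.0) * np.sin(np.pi * j / 16)
        rec = compute_epoch_features([x], 4096.0)
        expected = 10 * np.log10(2.0 * np.sin(np.pi / 16) ** 2 * 4.096**2)
        assert rec.values["f4"] == pytest.approx(expected, abs=1e-3)

    def test_symmetric_signal_zero_skew_feature(self):
        j = np.arange(65_536)
        x = np.sin(2 * np.pi * j / 64)
        rec = compute_epoch_features([x], 4096.0)
        assert rec.values["f10"] == pytest.approx(0.0, abs=1e-6)

    def test_amplitude_invariance_except_f5(self, rng):
        x = rng.standard_normal(50_000)
        a = 37.5
        r1 = compute_epoch_features([x], 4096.0)
        r2 = compute_epoch_features([a * x], 4096.0)
        for fid in FEATURE_IDS:
            if fid == "f5":
                assert r2.values[fid] - r1.values[fid] == pytest.approx(
                    10 * np.log10(a), abs=1e-6
                )
            else:
                assert r2.values[fid] == pytest.approx(r1.values[fid], abs=1e-6)

    def test_segment_pooling_matches_unsplit(self, rng):
        # splitting an epoch at an interior point loses only the <=2 boundary
        # differences per cut; features must agree to well under 1e-3 dB
        x = rng.standard_normal(200_000)
        whole = compute_epoch_features([x], 4096.0)
        split = compute_epoch_features([x[:81_003], x[81_003:]], 4096.0)
        for fid in FEATURE_IDS:
            assert split.values[fid] == pytest.approx(
                whole.values[fid], abs=1e-3
            ), fid

    def test_sampling_rate_normalization(self):
        # the same band-limited continuous signal sampled at fs and 2fs gives
        # nearly identical line-length means thanks to the fS factor
        dur = 8.0
        recs = {}
        for fs in (4096.0, 8192.0):
            t = np.arange(int(dur * fs)) / fs
            x = np.sin(2 * np.pi * 128.0 * t)
            recs[fs] = compute_epoch_features([x], fs)
        assert recs[8192.0].values["f2"] == pytest.approx(
            recs[4096.0].values["f2"], abs=0.05
        )

    def test_min_sample_floor(self):
        rec = compute_epoch_features(
            [np.random.default_rng(0).standard_normal(100)],
            4096.0,
            nominal_n=1000,
        )
        assert not rec.valid
        assert "usable samples" in rec.reason

    def test_constant_signal_flagged(self):
        rec = compute_epoch_features([np.full(10_000, 5.0)], 4096.0)
        assert not rec.valid and "degenerate" in rec.reason

    def test_excess_kurtosis_convention_configurable(self, rng):
        # heavy-tailed (Laplace) signal: kurt ~ 6, excess ~ 3, both loggable
        x = rng.laplace(size=200_000)
        r_p = compute_epoch_features([x], 4096.0, kurtosis="pearson")
        r_e = compute_epoch_features([x], 4096.0, kurtosis="excess")
        assert r_p.values["f15"] == pytest.approx(10 * np.log10(6.0), abs=0.5)
        assert r_e.values["f15"] == pytest.approx(10 * np.log10(3.0), abs=0.7)

    def test_excess_kurtosis_of_normal_flagged_invalid(self, rng):
        # excess kurtosis of near-normal data can be <= 0: log argument invalid
        x = np.sin(np.arange(100_000) * 0.37)  # platykurtic (kurt < 3)
        rec = compute_epoch_features([x], 4096.0, kurtosis="excess")
        assert not rec.valid and "non-positive" in rec.reason

    def test_records_to_frame_flags_invalid(self, rng):
        good = compute_epoch_features([rng.standard_normal(10_000)], 4096.0)
        bad = compute_epoch_features([np.full(10_000, 1.0)], 4096.0)
        frame = records_to_frame([good, bad])
        assert frame["valid"].tolist() == [True, False]
        assert frame.loc[1, "f1":"f19"].isna().all()
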