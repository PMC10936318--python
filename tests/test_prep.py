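"""Upsampling, alignment, smoothing, derivative features, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sockgait as sg


class TestUpsample:
    def test_midpoints_of_a_line(self):
        np.testing.assert_allclose(sg.upsample_linear([1.0, 3.0]), [1, 2, 3, 3])

    def test_constant_preserved(self):
        np.testing.assert_allclose(sg.upsample_linear([5.0, 5.0, 5.0]), np.full(6, 5.0))

    def test_originals_at_even_indices(self, rng):
        x = rng.standard_normal(50)
        up = sg.upsample_linear(x)
        assert len(up) == 100
        np.testing.assert_array_equal(up[0::2], x)

    def test_quadratic_chord_error(self):
        # midpoint of a chord of t^2 overestimates by exactly (dt/2)^2
        t = np.arange(20.0)
        up = sg.upsample_linear(t**2)
        inserted = up[1:-1:2]
        true = ((t[:-1] + t[1:]) / 2.0) ** 2
        np.testing.assert_allclose(inserted - true, 0.25, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(sg.DegenerateInputError):
            sg.upsample_linear([1.0])


class TestEstimateLag:
    def test_identical_channels_zero_lag(self, rng):
        x = rng.standard_normal(500)
        assert sg.estimate_lag(x, x, 50) == 0

    def test_constant_channel_raises(self, rng):
        with pytest.raises(sg.AlignmentUndefinedError):
            sg.estimate_lag(np.ones(100), rng.standard_normal(100), 10)

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(400)
        y = np.roll(x, 7) + 0.01 * rng.standard_normal(400)
        assert sg.estimate_lag(x, y, 30) == -sg.estimate_lag(y, x, 30)

    def test_recovers_injected_lag_on_trial(self, clean_trial):
        pfx = sg.upsample_linear(clean_trial.srs["PFX"])
        lag = sg.estimate_lag(pfx, clean_trial.mocap["FLX"], 200)
        assert lag == clean_trial.truth.lag

    def test_max_lag_validation(self, rng):
        with pytest.raises(sg.DegenerateInputError):
            sg.estimate_lag(rng.standard_normal(10), rng.standard_normal(10), 10)


class TestApplyLag:
    def test_zero_lag_identity_lengths(self, rng):
        a = {"x": rng.standard_normal(100)}
        b = {"y": rng.standard_normal(100)}
        ao, bo, start = sg.apply_lag(a, b, 0)
        assert len(ao["x"]) == len(bo["y"]) == 100 and start == 0

    def test_positive_lag_trims_to_990(self, rng):
        a = {"x": rng.standard_normal(1000)}
        b = {"y": rng.standard_normal(1000)}
        ao, bo, start = sg.apply_lag(a, b, 10)
        assert len(ao["x"]) == len(bo["y"]) == 990

    def test_roundtrip_residual_lag_zero(self, clean_trial):
        pfx = sg.upsample_linear(clean_trial.srs["PFX"])
        lag = sg.estimate_lag(pfx, clean_trial.mocap["FLX"], 200)
        ao, bo, _ = sg.apply_lag({"PFX": pfx}, dict(clean_trial.mocap), lag)
        assert sg.estimate_lag(ao["PFX"], bo["FLX"], 200) == 0

    def test_excessive_lag_raises(self):
        with pytest.raises(sg.DegenerateInputError):
            sg.apply_lag({"x": np.arange(5.0)}, {"y": np.arange(5.0)}, 5)


class TestSavitzkyGolay:
    def test_low_degree_polynomials_pass_through(self, rng):
        t = np.linspace(0, 1, 200)
        for deg in (0, 3, 5):
            x = np.polyval(rng.standard_normal(deg + 1), t)
            sm = sg.sg_smooth(x)
            np.testing.assert_allclose(sm[15:-15], x[15:-15], atol=1e-8)

    def test_local_least_squares_oracle(self, rng):
        """Interior smoothed values equal an explicit degree-5 local fit."""
        x = rng.standard_normal(120)
        sm = sg.sg_smooth(x, 31, 5)
        for i in (15, 47, 80, 104):
            w = x[i - 15:i + 16]
            coef = np.polyfit(np.arange(-15, 16), w, 5)
            assert sm[i] == pytest.approx(np.polyval(coef, 0), abs=1e-8)

    def test_linearity(self, rng):
        x, y = rng.standard_normal((2, 100))
        lhs = sg.sg_smooth(2.5 * x - 1.5 * y)
        rhs = 2.5 * sg.sg_smooth(x) - 1.5 * sg.sg_smooth(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_validation(self):
        with pytest.raises(sg.ConfigError):
            sg.sg_smooth(np.zeros(100), window=30)
        with pytest.raises(sg.ConfigError):
            sg.sg_smooth(np.zeros(100), window=5, polyorder=5)
        with pytest.raises(sg.DegenerateInputError):
            sg.sg_smooth(np.zeros(10), window=31)


class TestDerivativeFeatures:
    def test_constant_gives_zero_derivatives(self):
        f = sg.derivative_features(np.full((4, 50), 3.0))
        assert f.shape == (12, 50)
        np.testing.assert_allclose(f[4:], 0.0, atol=1e-12)

    def test_ramp_gives_constant_slope(self):
        x = np.tile(0.5 * np.arange(60.0), (4, 1))
        f = sg.derivative_features(x)
        np.testing.assert_allclose(f[4:8], 0.5, atol=1e-12)
        np.testing.assert_allclose(f[8:12], 0.0, atol=1e-12)

    def test_sine_derivative_within_taylor_bound(self):
        dt = 0.02
        t = np.arange(0, 4, dt)
        x = np.tile(np.sin(t), (4, 1))
        f = sg.derivative_features(x)
        interior = slice(1, -1)
        err = np.abs(f[4, interior] / dt - np.cos(t[interior]))
        assert err.max() < dt**2  # central difference is O(dt^2)


class TestScaler:
    def test_self_fit_statistics(self, rng):
        x = rng.standard_normal((3, 500)) * 4 + 7
        sc = sg.ChannelScaler.fit([x], ("a", "b", "c"))
        z = sc.transform(x)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_inverse_roundtrip(self, rng):
        x = rng.standard_normal((2, 300)) * 3 - 2
        sc = sg.ChannelScaler.fit([x], ("u", "v"))
        np.testing.assert_allclose(sc.inverse(sc.transform(x)), x, atol=1e-9)

    def test_zero_variance_names_channel(self, rng):
        x = np.vstack([rng.standard_normal(100), np.zeros(100)])
        with pytest.raises(sg.ConfigError, match="dead"):
            sg.ChannelScaler.fit([x], ("alive", "dead"))


@given(T=st.integers(10, 5000))
@settings(max_examples=40, deadline=None)
def test_split_ranges_cover_and_order(T):
    s = sg.split_ranges(T)
    assert s["train"][0] == 0 and s["test"][1] == T
    assert s["train"][1] == s["val"][0] and s["val"][1] == s["test"][0]


def test_train_range_normalized_to_unit_stats(clean_aligned):
    import copy

    trial = copy.deepcopy(clean_aligned)
    [t], _ = sg.normalize_trials([trial])
    tr = slice(*t.split["train"])
    np.testing.assert_allclose(t.features[:, tr].mean(axis=1), 0.0, atol=1e-6)
    np.testing.assert_allclose(t.features[:, tr].std(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(t.targets[:, tr].mean(axis=1), 0.0, atol=1e-6)
    np.testing.assert_allclose(t.targets[:, tr].std(axis=1), 1.0, atol=1e-6)


def test_preprocess_is_deterministic(noisy_trial):
    a = sg.preprocess_trial(noisy_trial)
    b = sg.preprocess_trial(noisy_trial)
    assert np.array_equal(a.features, b.features)
    assert np.array_equal(a.targets, b.targets)
    assert a.lag_applied == b.lag_applied
    assert a.segments == b.segments


def test_preprocess_recovers_lag_and_clean_trial_unflagged(clean_aligned, clean_trial):
    assert clean_aligned.lag_applied == clean_trial.truth.lag
    assert all(c.qc_status == "clean" for c in clean_aligned.prefilter_cycles)
    assert clean_aligned.segments == [(0, clean_aligned.T)]
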