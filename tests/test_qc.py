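"""Interval bounds, outlier-cycle flagging, and cycle excision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sockgait as sg
from sockgait.config import OUTLIER_MECHANISMS
from sockgait.prep import TARGET_NAMES


def _make_cycles(starts_ends):
    return [sg.GaitCycle(a, b) for a, b in starts_ends]


class TestIntervalBounds:
    def test_scale_one_is_identity(self):
        ib = sg.IntervalBounds(-3.0, 7.0)
        assert ib.scale(1.0) == ib

    @given(k1=st.floats(0.1, 20), k2=st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None)
    def test_scale_monotone_nesting(self, k1, k2):
        ib = sg.IntervalBounds(-2.0, 5.0)
        lo, hi = sorted((k1, k2))
        a, b = ib.scale(lo), ib.scale(hi)
        assert b.lower <= a.lower <= a.upper <= b.upper

    def test_inverted_bounds_raise(self):
        with pytest.raises(sg.ConfigError):
            sg.IntervalBounds(1.0, 0.0)


class TestComputeIB:
    def test_identical_cycles_give_min_max(self):
        x = np.tile(np.array([0.0, 10.0, 2.0, -1.0]), 5)
        cycles = _make_cycles([(i * 4, (i + 1) * 4) for i in range(5)])
        ib = sg.compute_ib(cycles, x)
        assert ib.lower == -1.0 and ib.upper == 10.0

    def test_four_cycle_quantile_oracle(self):
        # minima {0,1,2,3}, maxima {10,11,12,13}; linear-interp quartiles
        chunks = [np.array([m, M]) for m, M in zip([0, 1, 2, 3], [10, 11, 12, 13])]
        x = np.concatenate(chunks).astype(float)
        cycles = _make_cycles([(2 * i, 2 * i + 2) for i in range(4)])
        ib = sg.compute_ib(cycles, x)
        assert ib.lower == pytest.approx(0.75)
        assert ib.upper == pytest.approx(12.25)

    def test_zero_cycles_raise(self):
        with pytest.raises(sg.DegenerateInputError):
            sg.compute_ib([], np.zeros(10))


class TestFlagCycle:
    def _setup(self, rng, n_cycles=10, period=100):
        t = np.arange(n_cycles * period)
        base = 10 * np.sin(2 * np.pi * t / period)
        targets = np.vstack([base, 0.5 * base])
        cycles = _make_cycles([(i * period, (i + 1) * period) for i in range(n_cycles)])
        ibs = {n: sg.compute_ib(cycles, targets[i]) for i, n in enumerate(TARGET_NAMES)}
        return targets, cycles, ibs

    def test_clean_cycle_clean_verdict(self, rng):
        targets, cycles, ibs = self._setup(rng)
        assert sg.flag_cycle(cycles[3], targets, ibs) == ("clean", "none")

    def test_forced_mean_shift(self, rng):
        targets, cycles, ibs = self._setup(rng)
        targets = targets.copy()
        c = cycles[2]
        targets[0, c.start:c.end] += 40.0  # 3 IB spans about +-30 deg here
        status, crit = sg.flag_cycle(c, targets, ibs)
        assert status == "outlier" and crit == "mean_shift"

    def test_flags_depend_only_on_optical_channels(self, noisy_trial):
        """Perturbing the stretch channels never changes a QC verdict."""
        a = sg.preprocess_trial(noisy_trial)
        pert = noisy_trial.copy()
        r = np.random.default_rng(0)
        for k in ("PFX", "DFX", "INV", "EVR"):
            pert.srs[k] = pert.srs[k] + 0.3 * r.standard_normal(len(pert.srs[k]))
        b = sg.preprocess_trial(pert, lag_override=a.lag_applied)
        flags_a = [(c.qc_status, c.qc_criterion) for c in a.prefilter_cycles]
        flags_b = [(c.qc_status, c.qc_criterion) for c in b.prefilter_cycles]
        assert flags_a == flags_b

    def test_15ib_nested_inside_3ib_10pct_clause(self):
        """Any sample outside 15 IB is also outside 3 IB (nested fences)."""
        ib = sg.IntervalBounds(-4.0, 6.0)
        x = np.linspace(-200, 200, 2001)
        out15 = ib.scale(15).outside(x)
        out3 = ib.scale(3).outside(x)
        assert np.all(out3[out15])


class TestInjectedOutlierRecovery:
    @pytest.mark.parametrize("mechanism", OUTLIER_MECHANISMS)
    def test_each_mechanism_detected(self, mechanism):
        t = sg.simulate_trial(sg.SyntheticConfig(
            speed=0.89, duration=90.0, seed=11, lag=10, noise_frac=0.05
        ))
        t = sg.inject_outlier_cycles(t, {mechanism: 0.15}, seed=50)
        at = sg.preprocess_trial(t)
        labels = t.truth.cycle_labels
        flagged = inj = 0
        for c, lab in zip(at.prefilter_cycles, labels):
            if lab == mechanism:
                inj += 1
                flagged += c.qc_status == "outlier"
        assert inj > 0 and flagged / inj >= 0.95

    def test_filtered_streams_contain_no_labelled_outlier_samples(self):
        t = sg.simulate_trial(sg.SyntheticConfig(
            speed=0.89, duration=90.0, seed=12, lag=0, noise_frac=0.02
        ))
        t = sg.inject_outlier_cycles(t, {"mean_shift": 0.2}, seed=3)
        at = sg.preprocess_trial(t)
        # every kept cycle is clean, and total removed length matches flags
        removed = sum(
            len(c) for c in at.prefilter_cycles if c.qc_status == "outlier"
        )
        total = sum(len(c) for c in at.prefilter_cycles)
        assert at.T == total - removed
        assert all(c.qc_status == "clean" for c in at.cycles)


class TestFilterTrial:
    def _streams(self, T):
        return {"a": np.arange(2.0 * T).reshape(2, T), "b": np.arange(float(T))[None]}

    def test_zero_flagged_is_identity(self):
        streams = self._streams(400)
        cycles = _make_cycles([(0, 100), (100, 250), (250, 400)])
        out, kept, segs = sg.filter_trial(streams, cycles)
        for k in streams:
            np.testing.assert_array_equal(out[k], streams[k])
        assert segs == [(0, 400)]

    def test_removed_length_arithmetic(self):
        streams = self._streams(10_000)
        bounds = [(i * 250, (i + 1) * 250) for i in range(40)]
        cycles = _make_cycles(bounds)
        cycles[7].qc_status = "outlier"
        cycles[7].qc_criterion = "excursion"
        out, kept, segs = sg.filter_trial(streams, cycles)
        assert all(v.shape[-1] == 9_750 for v in out.values())
        assert len(segs) == 2  # one excision -> two contiguous spans

    def test_idempotent(self):
        streams = self._streams(600)
        cycles = _make_cycles([(0, 200), (200, 400), (400, 600)])
        cycles[1].qc_status = "outlier"
        cycles[1].qc_criterion = "mean_shift"
        out1, kept1, segs1 = sg.filter_trial(streams, cycles)
        out2, kept2, segs2 = sg.filter_trial(out1, kept1)
        for k in out1:
            np.testing.assert_array_equal(out1[k], out2[k])
        assert segs2 == [(0, out1["b"].shape[-1])]

    def test_all_flagged_raises(self):
        streams = self._streams(200)
        cycles = _make_cycles([(0, 100), (100, 200)])
        for c in cycles:
            c.qc_status = "outlier"
            c.qc_criterion = "excursion"
        with pytest.raises(sg.EmptyTrialError):
            sg.filter_trial(streams, cycles)

    def test_non_partitioning_cycles_raise(self):
        with pytest.raises(sg.ConfigError):
            sg.filter_trial(self._streams(300), _make_cycles([(0, 100), (150, 300)]))
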