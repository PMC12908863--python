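"""Epoching and evoked-response metrics (AUC, t90, undershoot, maps)."""

import numpy as np
import pytest

from wfoi.errors import InvalidArgumentError
from wfoi.metrics import (
    NOT_RECOVERED,
    EpochMatrix,
    StimulusProtocol,
    behaviour_split,
    cumulative_map,
    epoch_extract,
    recovery_time_t90,
    response_auc,
    undershoot_auc,
)


@pytest.fixture
def proto():
    # 4 pulses of 200 ms at 1 Hz -> train duration 3.2 s
    return StimulusProtocol.regular(10.0, 20.0, 3)


class TestStimulusProtocol:
    def test_train_duration_formula(self):
        p = StimulusProtocol([0.0], pulses_per_train=4,
                             pulse_duration_s=0.2, pulse_rate_hz=1.0)
        assert p.train_duration_s == pytest.approx(3.2)

    def test_single_pulse_duration(self):
        p = StimulusProtocol([0.0], pulses_per_train=1, pulse_duration_s=0.5)
        assert p.train_duration_s == pytest.approx(0.5)

    def test_regular_onsets(self):
        p = StimulusProtocol.regular(10.0, 20.0, 21)
        assert p.n_trains == 21
        np.testing.assert_allclose(p.train_onsets, 10.0 + 20.0 * np.arange(21))

    def test_nonmonotone_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StimulusProtocol([10.0, 5.0])

    def test_overlapping_trains_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StimulusProtocol([0.0, 2.0])  # interval < 3.2 s duration


class TestEpochExtract:
    def test_known_trace_alignment(self, proto):
        ts = np.arange(0.0, 70.0, 0.1)
        trace = np.zeros_like(ts)
        for onset in proto.train_onsets:
            trace[np.isclose(ts, onset + 1.0)] = 5.0  # spike 1 s after onset
        em = epoch_extract(trace, ts, proto, window=(2.0, 15.0))
        assert em.n_trials == 3
        i = int(np.argmin(np.abs(em.time_s - 1.0)))
        np.testing.assert_allclose(em.data[:, i], 5.0)
        assert em.time_s[0] == pytest.approx(-2.0)
        assert em.time_s[-1] == pytest.approx(15.0)

    def test_baseline_subtraction(self, proto):
        ts = np.arange(0.0, 70.0, 0.1)
        trace = np.full_like(ts, 3.3)
        em = epoch_extract(trace, ts, proto)
        np.testing.assert_allclose(em.data, 0.0, atol=1e-12)
        em2 = epoch_extract(trace, ts, proto, baseline_subtract=False)
        np.testing.assert_allclose(em2.data, 3.3)

    def test_offrecord_trains_dropped(self):
        proto = StimulusProtocol.regular(5.0, 20.0, 4)
        ts = np.arange(0.0, 60.0, 0.1)  # last train at 65 s off record
        em = epoch_extract(np.zeros_like(ts), ts, proto, window=(2.0, 10.0))
        assert em.n_trials == 3
        assert em.dropped_trials == [3]

    def test_labels_follow_kept_trials(self):
        proto = StimulusProtocol.regular(5.0, 20.0, 3)
        ts = np.arange(0.0, 48.0, 0.1)
        labels = ["rest", "locomotion", "rest"]
        em = epoch_extract(np.zeros_like(ts), ts, proto, window=(2.0, 10.0),
                           labels=labels)
        assert em.dropped_trials == [2]
        assert list(em.labels) == ["rest", "locomotion"]


class TestResponseAuc:
    def test_rectangle(self):
        t = np.arange(-2.0, 10.0, 0.01)
        row = np.where((t >= 0) & (t <= 4), 2.0, 0.0)
        assert response_auc(row, t, (0.0, 4.0)) == pytest.approx(8.0, abs=0.05)

    def test_triangle(self):
        t = np.linspace(0.0, 2.0, 201)
        row = np.where(t <= 1.0, t, 2.0 - t)  # unit triangle, area 1
        assert response_auc(row, t, (0.0, 2.0)) == pytest.approx(1.0, rel=1e-6)

    def test_matches_scipy_on_sine(self):
        from scipy.integrate import trapezoid
        t = np.linspace(0.0, 10.0, 500)
        row = np.sin(t)
        sel = (t >= 1.0) & (t <= 8.0)
        assert response_auc(row, t, (1.0, 8.0)) == pytest.approx(
            trapezoid(row[sel], t[sel]))

    def test_additivity_over_adjacent_windows(self, rng):
        t = np.arange(0.0, 10.0, 0.5)
        row = rng.normal(size=t.shape)
        total = response_auc(row, t, (0.0, 10.0 - 0.5))
        left = response_auc(row, t, (0.0, 5.0))
        right = response_auc(row, t, (5.0, 10.0 - 0.5))
        assert total == pytest.approx(left + right, rel=1e-10)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            response_auc(np.zeros(10), np.arange(10.0), (0.0, 20.0))


class TestRecoveryT90:
    def _proto(self):
        return StimulusProtocol([0.0])  # duration 3.2 s

    def test_exponential_decay_analytic(self):
        """A exp(-t/tau) after peak at offset: t90 = tau ln 10."""
        proto = self._proto()
        tau = 2.0
        t = np.arange(-2.0, 30.0, 0.001)
        offs = proto.train_duration_s
        row = np.where(t < offs, np.clip(t, 0, None) / offs,
                       np.exp(-(t - offs) / tau))
        got = recovery_time_t90(row, t, proto)
        assert got == pytest.approx(tau * np.log(10.0), abs=0.01)

    def test_linear_interpolation_between_samples(self):
        proto = self._proto()
        # coarse grid: crossing of 0.1*peak falls between samples
        t = np.array([-1.0, 0.0, 3.2, 4.2, 5.2])
        row = np.array([0.0, 0.0, 1.0, 0.5, 0.05])
        # crossing of 0.1 between 4.2 (0.5) and 5.2 (0.05): frac = 0.4/0.45
        want = 4.2 + (0.5 - 0.1) / (0.5 - 0.05) * 1.0 - 3.2
        assert recovery_time_t90(row, t, proto) == pytest.approx(want)

    def test_never_recovered_sentinel(self):
        proto = self._proto()
        t = np.arange(-1.0, 10.0, 0.1)
        row = np.where(t >= 0, 1.0, 0.0)  # step that never decays
        assert recovery_time_t90(row, t, proto) == NOT_RECOVERED

    def test_no_peak_sentinel(self):
        proto = self._proto()
        t = np.arange(-1.0, 10.0, 0.1)
        row = 0.001 * np.ones_like(t)
        assert np.isnan(recovery_time_t90(row, t, proto, noise_floor=0.01))

    def test_negative_deflections_use_magnitude(self):
        proto = self._proto()
        tau = 1.5
        t = np.arange(-1.0, 30.0, 0.001)
        offs = proto.train_duration_s
        row = -np.where(t < offs, np.clip(t, 0, None) / offs,
                        np.exp(-(t - offs) / tau))
        assert recovery_time_t90(row, t, proto) == pytest.approx(
            tau * np.log(10.0), abs=0.01)

    def test_peak_anchor_shifts_by_peak_time(self):
        proto = self._proto()
        tau = 2.0
        t = np.arange(-1.0, 40.0, 0.001)
        peak_t = 5.0
        row = np.where(t < peak_t, np.clip(t, 0, None) / peak_t,
                       np.exp(-(t - peak_t) / tau))
        a = recovery_time_t90(row, t, proto, anchor="train-offset")
        b = recovery_time_t90(row, t, proto, anchor="peak")
        assert a - b == pytest.approx(peak_t - proto.train_duration_s, abs=0.01)


class TestUndershootAuc:
    def _proto(self):
        return StimulusProtocol([0.0])

    def test_pure_negative_lobe(self):
        proto = self._proto()
        offs = proto.train_duration_s
        t = np.arange(-1.0, 10.0, 0.001)
        row = np.where((t >= offs) & (t <= offs + 1.0), -2.0, 0.0)
        got = undershoot_auc(row, t, proto, window=(0.0, 2.0))
        assert got == pytest.approx(2.0, rel=1e-2)

    def test_positive_signal_contributes_zero(self):
        proto = self._proto()
        t = np.arange(-1.0, 10.0, 0.01)
        row = np.abs(np.sin(t))
        assert undershoot_auc(row, t, proto) == 0.0

    def test_result_is_nonnegative(self, rng):
        proto = self._proto()
        t = np.arange(-1.0, 10.0, 0.1)
        for _ in range(10):
            row = rng.normal(size=t.shape)
            assert undershoot_auc(row, t, proto) >= 0.0

    def test_onset_anchor(self):
        proto = self._proto()
        t = np.arange(-1.0, 10.0, 0.001)
        row = np.where((t >= 0.5) & (t <= 1.5), -1.0, 0.0)
        got = undershoot_auc(row, t, proto, window=(0.0, 2.0), anchor="onset")
        assert got == pytest.approx(1.0, rel=1e-2)
        # train-offset window (3.2..5.2 s) misses the lobe entirely
        assert undershoot_auc(row, t, proto) == 0.0


class TestCumulativeMap:
    def test_localised_response_wins(self, proto):
        ts = np.arange(0.0, 70.0, 0.1)
        stack = np.zeros((len(ts), 8, 8))
        for onset in proto.train_onsets:
            sel = (ts >= onset) & (ts <= onset + 3.0)
            stack[sel, 3, 4] = 1.0
        m = cumulative_map(stack, ts, proto, mask=np.ones((8, 8), bool))
        assert m[3, 4] == pytest.approx(1.0)
        assert np.unravel_index(np.argmax(m), m.shape) == (3, 4)

    def test_range_and_mask_zeroing(self, proto, rng):
        ts = np.arange(0.0, 70.0, 0.1)
        stack = rng.normal(size=(len(ts), 6, 6))
        mask = np.zeros((6, 6), bool)
        mask[1:5, 1:5] = True
        m = cumulative_map(stack, ts, proto, mask=mask)
        assert m[mask].min() == pytest.approx(0.0)
        assert m[mask].max() == pytest.approx(1.0)
        assert np.all(m[~mask] == 0.0)

    def test_flat_map_warns_all_zero(self, proto):
        ts = np.arange(0.0, 70.0, 0.1)
        stack = np.ones((len(ts), 4, 4))
        with pytest.warns(UserWarning):
            m = cumulative_map(stack, ts, proto)
        assert np.all(m == 0.0)

    def test_gain_invariance(self, proto, rng):
        ts = np.arange(0.0, 70.0, 0.1)
        stack = rng.normal(size=(len(ts), 5, 5))
        a = cumulative_map(stack, ts, proto)
        b = cumulative_map(10.0 * stack + 3.0, ts, proto)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestBehaviourSplit:
    def test_partition_counts_and_content(self, rng):
        data = rng.normal(size=(6, 10))
        labels = ["rest", "locomotion", "rest", "unlabeled", "locomotion", "rest"]
        em = EpochMatrix(data, np.arange(10.0), labels=labels)
        out = behaviour_split(em)
        assert out["counts"] == {"rest": 3, "locomotion": 2, "unlabeled": 1}
        np.testing.assert_array_equal(out["rest"].data, data[[0, 2, 5]])
        np.testing.assert_array_equal(out["locomotion"].data, data[[1, 4]])

    def test_empty_group_allowed(self, rng):
        em = EpochMatrix(rng.normal(size=(3, 5)), np.arange(5.0),
                         labels=["rest"] * 3)
        out = behaviour_split(em)
        assert out["locomotion"].n_trials == 0
        assert out["counts"]["rest"] == 3
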