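"""Forward phantom: kernels, determinism contract, and exact inversion."""

import numpy as np
import pytest

from wfoi.errors import InvalidArgumentError
from wfoi.hemodynamics import absorption_change, solve_haemoglobin
from wfoi.metrics import StimulusProtocol
from wfoi.phantom import (
    PhantomConfig,
    calcium_transient,
    default_sequence,
    double_gamma,
    recovery_report,
    simulate_session,
)
from wfoi.spectra import extinction_matrix
from wfoi.stack_io import Channel, RelativeStack, demultiplex, relative_series


class TestKernels:
    def test_double_gamma_causal(self):
        t = np.linspace(-5.0, 30.0, 1000)
        k = double_gamma(t)
        assert np.all(k[t <= 0] == 0.0)

    def test_double_gamma_peak_location_and_height(self):
        t = np.linspace(0.0, 30.0, 300001)
        k = double_gamma(t, peak_s=2.0, undershoot_frac=0.0)
        assert t[np.argmax(k)] == pytest.approx(2.0, abs=1e-3)
        assert k.max() == pytest.approx(1.0, abs=1e-6)

    def test_double_gamma_has_undershoot(self):
        t = np.linspace(0.0, 30.0, 3000)
        k = double_gamma(t, undershoot_frac=0.2)
        assert k.min() < -1e-3
        assert t[np.argmin(k)] > t[np.argmax(k)]

    def test_double_gamma_grid_independent(self):
        coarse = double_gamma(np.arange(0.0, 20.0, 0.5))
        fine = double_gamma(np.arange(0.0, 20.0, 0.1))
        np.testing.assert_allclose(coarse, fine[::5], rtol=1e-12)

    def test_calcium_transient_unit_peak_any_grid(self):
        t = np.linspace(0.0, 5.0, 2000001)
        c = calcium_transient(t, rise_s=0.05, decay_s=0.4)
        assert c.max() == pytest.approx(1.0, abs=1e-6)
        t_peak = 0.05 * np.log1p(0.4 / 0.05)
        assert t[np.argmax(c)] == pytest.approx(t_peak, abs=1e-4)

    def test_calcium_transient_causal_and_decaying(self):
        t = np.linspace(-1.0, 10.0, 2000)
        c = calcium_transient(t)
        assert np.all(c[t <= 0] == 0.0)
        tail = c[t > 2.0]
        assert np.all(np.diff(tail) < 0)
        assert tail[-1] < 1e-6


class TestConfigAndSession:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PhantomConfig(region_center=(1.5, 0.5))
        with pytest.raises(InvalidArgumentError):
            PhantomConfig(duration_s=-1.0)

    def test_frame_count_and_timestamps(self, quiet_phantom):
        s = quiet_phantom
        assert s.frames.shape == (600, 64, 64)
        np.testing.assert_allclose(np.diff(s.timestamps), 0.1)

    def test_counts_positive_and_near_baseline(self, quiet_phantom):
        s = quiet_phantom
        assert np.all(s.frames > 0)
        idx530 = s.channel_indices("LED530")
        med = np.median(s.frames[idx530])
        assert 0.5 * 8000 < med < 1.1 * 8000

    def test_channel_indices_partition_frames(self, quiet_phantom):
        s = quiet_phantom
        all_idx = np.concatenate([s.channel_indices(lbl)
                                  for lbl in ("LED470", "LED530", "LED656")])
        np.testing.assert_array_equal(np.sort(all_idx),
                                      np.arange(len(s.timestamps)))

    def test_spatial_map_disc_properties(self, quiet_phantom):
        m = quiet_phantom.spatial_map
        # centre falls between grid points, so the sampled max is just below 1
        assert m.max() == pytest.approx(1.0, abs=0.01)
        assert m.min() == 0.0
        # outside the responsive disc the map is exactly zero
        assert m[0, 0] == 0.0 and m[-1, -1] == 0.0

    def test_truth_field_separability(self, quiet_phantom):
        s = quiet_phantom
        f = s.truth_field("d_hbo", np.array([5, 50]))
        np.testing.assert_allclose(f[0], s.d_hbo_t[5] * s.spatial_map)
        np.testing.assert_allclose(f[1], s.d_hbo_t[50] * s.spatial_map)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig(shape=(8, 8), duration_s=30.0,
                            protocol=StimulusProtocol.regular(10.0, 15.0, 1),
                            read_noise_sd=2.0, seed=7)
        a, b = simulate_session(cfg), simulate_session(cfg)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_different_seed_different_noise_identical_truth(self):
        base = PhantomConfig(shape=(8, 8), duration_s=30.0,
                             protocol=StimulusProtocol.regular(10.0, 15.0, 1),
                             read_noise_sd=2.0, seed=7)
        a = simulate_session(base)
        b = simulate_session(base.with_(seed=8))
        assert np.any(a.frames != b.frames)
        np.testing.assert_array_equal(a.d_hbo_t, b.d_hbo_t)
        np.testing.assert_array_equal(a.f_true_t, b.f_true_t)
        np.testing.assert_array_equal(a.trial_amplitudes, b.trial_amplitudes)

    def test_noise_free_configs_identical_regardless_of_seed(self):
        base = PhantomConfig(shape=(8, 8), duration_s=30.0,
                             protocol=StimulusProtocol.regular(10.0, 15.0, 1))
        np.testing.assert_array_equal(simulate_session(base).frames,
                                      simulate_session(base.with_(seed=99)).frames)


class TestLocomotionStructure:
    def test_locomotion_trials_labelled_and_scaled(self):
        cfg = PhantomConfig(shape=(8, 8), duration_s=70.0,
                            protocol=StimulusProtocol.regular(10.0, 20.0, 3),
                            locomotion_trials=(1,), amplitude_cv=0.0)
        s = simulate_session(cfg)
        assert list(s.trial_labels) == ["rest", "locomotion", "rest"]
        # haemodynamic response of the locomotion trial is scaled up
        t = s.timestamps
        def peak_near(onset):
            sel = (t >= onset) & (t <= onset + 10.0)
            return np.max(np.abs(s.d_hbo_t[sel]))
        assert peak_near(30.0) > 5.0 * peak_near(10.0)


class TestExactInversion:
    def test_haemoglobin_roundtrip_to_numerical_precision(self, quiet_phantom,
                                                          table, pathlengths):
        """Demux -> ratios -> absorption -> 2x2 inversion recovers truth."""
        s = quiet_phantom
        stacks = demultiplex(s.frames, s.timestamps, s.sequence)
        by_label = {st.channel.label: st for st in stacks
                    if st.channel.label != "LED470"}
        rels = {}
        for lbl, st in by_label.items():
            r = relative_series(st, baseline=(0.0, 10.0))
            rels[lbl] = r
        z = extinction_matrix(table, 530.0, 656.0)
        a1 = absorption_change(rels["LED530"], pathlengths.get(530.0))
        a2 = absorption_change(rels["LED656"], pathlengths.get(656.0))
        hb = solve_haemoglobin(a1, a2, z)
        idx = by_label["LED530"].frame_indices
        truth_hbo = s.truth_field("d_hbo", idx)
        truth_hhb = s.truth_field("d_hhb", idx)
        assert np.max(np.abs(hb.d_hbo - truth_hbo)) < 1e-9
        assert np.max(np.abs(hb.d_hhb - truth_hhb)) < 1e-9

    def test_fluorescence_truth_recovered_with_mbll(self, quiet_phantom,
                                                    table, pathlengths):
        from wfoi.fluorescence import mbll_correct
        from wfoi.hemodynamics import AbsorptionChange

        from wfoi.stack_io import FrameStack

        s = quiet_phantom
        # merge both 470 slots into the full fluorescence series
        f_all_idx = s.channel_indices("LED470")
        merged = FrameStack(s.frames[f_all_idx], s.timestamps[f_all_idx],
                            channel=Channel("LED470", 470.0,
                                            "fluorescence-excitation"),
                            frame_indices=f_all_idx)
        rel = relative_series(merged, baseline=(0.0, 10.0))
        z = extinction_matrix(table, 470.0, 530.0)
        d_hbo = s.truth_field("d_hbo", f_all_idx) * 1e-6
        d_hhb = s.truth_field("d_hhb", f_all_idx) * 1e-6
        mua_ex = z.matrix[0, 0] * d_hbo + z.matrix[0, 1] * d_hhb
        mua_em = z.matrix[1, 0] * d_hbo + z.matrix[1, 1] * d_hhb
        from wfoi.fluorescence import FluorescenceSeries
        corrected = mbll_correct(
            FluorescenceSeries(rel.ratios),
            AbsorptionChange(mua_ex, 470.0), AbsorptionChange(mua_em, 530.0),
            pathlengths.get(470.0), pathlengths.get(530.0))
        truth = s.truth_field("f_true", f_all_idx)
        assert np.max(np.abs(corrected.f_rel - truth)) < 1e-9


class TestRecoveryReport:
    def test_perfect_recovery_metrics(self, rng):
        truth = rng.normal(size=(10, 4, 4))
        rep = recovery_report(truth, truth.copy())
        assert rep["overall"]["rmse"] == 0.0
        assert rep["overall"]["max_abs_error"] == 0.0
        assert rep["overall"]["correlation"] == pytest.approx(1.0)

    def test_known_bias(self, rng):
        truth = rng.normal(size=(10, 4, 4))
        rep = recovery_report(truth, truth + 0.5)
        assert rep["overall"]["rmse"] == pytest.approx(0.5)
        assert rep["overall"]["max_abs_error"] == pytest.approx(0.5)

    def test_region_mask_restricts(self, rng):
        truth = np.zeros((5, 4, 4))
        est = truth.copy()
        est[:, 0, 0] = 1.0  # error only outside the region
        mask = np.zeros((4, 4), bool)
        mask[2:, 2:] = True
        rep = recovery_report(truth, est, region_mask=mask)
        assert rep["region"]["rmse"] == 0.0
        assert rep["overall"]["rmse"] > 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            recovery_report(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDefaultSequence:
    def test_four_slot_interleave(self):
        seq = default_sequence()
        assert [c.wavelength_nm for c in seq] == [470.0, 530.0, 470.0, 656.0]
        assert sum(c.role == "fluorescence-excitation" for c in seq) == 2
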