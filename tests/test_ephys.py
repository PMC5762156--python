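"""Evoked-FP scoring, PPR, MUA, inverse CSD, pooling, I/O curve, irradiance."""

import numpy as np
import pytest

from strokephys.ephys import (CSDParams, LaminarRecording, build_io_curve,
                              compute_mua, csd_step_method, default_layer_map,
                              epoch_and_average, io_curve_from_amplitudes,
                              irradiance, measure_fp_components,
                              paired_pulse_ratio, pool_layers,
                              step_forward_matrix)
from strokephys.synth import CohortConfig, gen_evoked_lfp

from conftest import make_flat_average


def _hann(center_ms, half_ms, amp, times_ms):
    tau = times_ms - center_ms
    out = np.zeros_like(times_ms, dtype=float)
    inside = np.abs(tau) < half_ms
    out[inside] = amp * 0.5 * (1 + np.cos(np.pi * tau[inside] / half_ms))
    return out


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

class TestEpochAndAverage:
    def test_constant_trace_mean_and_zero_sem(self):
        sr = 1000.0
        v = np.full((3, 5000), 1.3)
        rec = LaminarRecording(v, sr, np.array([100.0, 200.0, 300.0]),
                               np.array([1.0, 2.0, 3.0]))
        avg = epoch_and_average(rec, (-50.0, 250.0))
        assert np.allclose(avg.mean_trace, 1.3)
        assert np.allclose(avg.sem_trace, 0.0)
        assert avg.n_trials == 3

    def test_noiseless_mean_equals_single_trial(self, noiseless_subject, noiseless_average):
        """15 identical evoked trials average to the single-trial waveform."""
        rec = noiseless_subject.recordings[None]
        one = LaminarRecording(rec.voltages, rec.sample_rate, rec.channel_depths,
                               rec.stim_times[:1])
        avg1 = epoch_and_average(one, (-50.0, 250.0))
        assert np.allclose(avg1.mean_trace, noiseless_average.mean_trace, atol=1e-12)

    def test_prestimulus_sem_matches_sampling_theory(self):
        sigma, n = 0.1, 15
        cfg = CohortConfig(condition="sham", n_subjects=1, seed=3, noise_sd=sigma,
                           n_trials=n, trial_spacing=1.0)
        sub = gen_evoked_lfp(cfg, [None])[0]
        avg = epoch_and_average(sub.recordings[None], (-50.0, 250.0))
        pre = avg.times_ms < 0
        observed = avg.sem_trace[:, pre].mean()
        expected = sigma / np.sqrt(n)
        assert abs(observed - expected) / expected < 0.30

    def test_edge_trials_excluded_with_warning(self):
        sr = 1000.0
        v = np.zeros((3, 2000))
        rec = LaminarRecording(v, sr, np.array([100.0, 200.0, 300.0]),
                               np.array([1.0, 1.9]))
        with pytest.warns(UserWarning, match="excluded"):
            avg = epoch_and_average(rec, (-50.0, 250.0))
        assert avg.n_trials == 1

    def test_no_usable_trials_is_an_error(self):
        rec = LaminarRecording(np.zeros((3, 300)), 1000.0,
                               np.array([100.0, 200.0, 300.0]), np.array([0.1]))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no stimulus"):
                epoch_and_average(rec, (-150.0, 250.0))


# ---------------------------------------------------------------------------
# FP components
# ---------------------------------------------------------------------------

class TestFPComponents:
    def test_flat_zero_trace_scores_zero(self):
        comp = measure_fp_components(make_flat_average(0.0))
        assert np.all(comp.neg_amplitude == 0)
        assert np.all(comp.pos_amplitude == 0)
        assert np.all(comp.baseline == 0)

    def test_recovers_injected_amplitudes_exactly(self, noiseless_subject, noiseless_average):
        """Noiseless synthesis: baseline-to-peak equals the injected values."""
        comp = measure_fp_components(noiseless_average)
        truth = noiseless_subject.truth
        assert np.allclose(comp.neg_amplitude, truth.neg_amp, atol=1e-9)
        assert np.allclose(comp.pos_amplitude, truth.pos_amp, atol=1e-9)
        assert np.allclose(comp.neg_latency, truth.neg_latency_ms, atol=1e-9)
        assert np.allclose(comp.pos_latency, truth.pos_latency_ms, atol=1e-9)

    def test_positive_only_trace(self):
        avg = make_flat_average(0.0)
        avg.mean_trace += _hann(50.0, 10.0, 0.7, avg.times_ms)
        comp = measure_fp_components(avg)
        assert np.all(comp.neg_amplitude == 0)
        assert np.allclose(comp.pos_amplitude, 0.7, atol=1e-9)
        assert np.allclose(comp.pos_latency, 50.0)

    def test_latencies_fall_inside_search_windows(self, noiseless_average):
        comp = measure_fp_components(noiseless_average)
        assert np.all((comp.neg_latency >= 5) & (comp.neg_latency <= 35))
        assert np.all((comp.pos_latency >= 35) & (comp.pos_latency <= 80))
        assert np.all(comp.neg_latency < comp.pos_latency)

    def test_misordered_windows_rejected(self, noiseless_average):
        with pytest.raises(ValueError, match="ordered"):
            measure_fp_components(noiseless_average, neg_window=(40.0, 60.0),
                                  pos_window=(5.0, 35.0))

    def test_window_outside_epoch_rejected(self, noiseless_average):
        with pytest.raises(ValueError, match="outside"):
            measure_fp_components(noiseless_average, pos_window=(300.0, 400.0))

    @pytest.mark.parametrize("k", [0.5, 2.0, 7.0])
    def test_scale_equivariance(self, noiseless_subject, k):
        rec = noiseless_subject.recordings[None]
        scaled = LaminarRecording(rec.voltages * k, rec.sample_rate,
                                  rec.channel_depths, rec.stim_times)
        base = measure_fp_components(epoch_and_average(rec, (-50.0, 250.0)))
        comp = measure_fp_components(epoch_and_average(scaled, (-50.0, 250.0)))
        assert np.allclose(comp.neg_amplitude, k * base.neg_amplitude, atol=1e-9)
        assert np.allclose(comp.pos_amplitude, k * base.pos_amplitude, atol=1e-9)


# ---------------------------------------------------------------------------
# paired-pulse ratio
# ---------------------------------------------------------------------------

class TestPairedPulseRatio:
    def _paired_average(self, a2_scale, isi=50):
        avg = make_flat_average(0.0, window=(-50.0, float(isi) + 100.0))
        resp = _hann(20.0, 6.0, -0.8, avg.times_ms) + _hann(45.0, 10.0, 0.5, avg.times_ms)
        resp2 = (_hann(isi + 20.0, 6.0, -0.8, avg.times_ms)
                 + _hann(isi + 45.0, 10.0, 0.5, avg.times_ms))
        avg.mean_trace += resp + a2_scale * resp2
        return avg

    def test_identical_responses_give_unity(self):
        res = paired_pulse_ratio(self._paired_average(1.0), 50)
        assert np.allclose(res.ppr, 1.0, atol=1e-9)

    def test_absent_second_response_gives_zero(self):
        res = paired_pulse_ratio(self._paired_average(0.0), 50)
        assert np.allclose(res.ppr, 0.0, atol=1e-9)

    def test_recovers_injected_depression(self, noiseless_subject):
        avg = epoch_and_average(noiseless_subject.recordings[50], (-50.0, 150.0))
        res = paired_pulse_ratio(avg, 50)
        assert np.allclose(res.ppr, noiseless_subject.truth.ppd_ratio, atol=1e-9)

    def test_monotone_in_injected_depression(self):
        """Measured PPR strictly decreases as injected depression deepens."""
        measured = []
        for ppd in (1.0, 0.8, 0.6, 0.4):
            cfg = CohortConfig(condition="sham", n_subjects=1, seed=11, noise_sd=0.0,
                               subject_cv=0.0, ppd_ratio=ppd, n_trials=2,
                               trial_spacing=1.0)
            sub = gen_evoked_lfp(cfg, [50])[0]
            avg = epoch_and_average(sub.recordings[50], (-50.0, 150.0))
            measured.append(np.nanmean(paired_pulse_ratio(avg, 50).ppr))
        assert np.all(np.diff(measured) < 0)

    def test_noise_only_channel_flagged_unreliable(self):
        rng = np.random.default_rng(0)
        avg = make_flat_average(0.0, window=(-50.0, 150.0))
        avg.mean_trace += rng.normal(0, 0.01, avg.mean_trace.shape)
        res = paired_pulse_ratio(avg, 50, noise_floor_k=4.5)
        assert res.unreliable.all()
        assert np.isnan(res.ppr).all()

    def test_real_response_not_flagged(self, noiseless_subject):
        avg = epoch_and_average(noiseless_subject.recordings[50], (-50.0, 150.0))
        res = paired_pulse_ratio(avg, 50)
        assert not res.unreliable.any()

    def test_ppr_invariant_under_scaling(self, noiseless_subject):
        rec = noiseless_subject.recordings[50]
        scaled = LaminarRecording(rec.voltages * 3.7, rec.sample_rate,
                                  rec.channel_depths, rec.stim_times)
        r1 = paired_pulse_ratio(epoch_and_average(rec, (-50.0, 150.0)), 50)
        r2 = paired_pulse_ratio(epoch_and_average(scaled, (-50.0, 150.0)), 50)
        assert np.allclose(r1.ppr, r2.ppr, atol=1e-9)

    def test_invalid_isi_rejected(self, noiseless_average):
        with pytest.raises(ValueError, match="isi"):
            paired_pulse_ratio(noiseless_average, 75)


# ---------------------------------------------------------------------------
# MUA
# ---------------------------------------------------------------------------

class TestMUA:
    def test_sinusoid_rms_closed_form(self):
        """A pure in-band sinusoid of amplitude a has RMS a/sqrt(2)."""
        sr, a = 25000.0, 0.2
        t = np.arange(int(sr * 3)) / sr
        v = np.tile(a * np.sin(2 * np.pi * 1000 * t), (3, 1))
        rec = LaminarRecording(v, sr, np.array([100.0, 200.0, 300.0]), np.array([1.0]))
        mua = compute_mua(rec, rms_window_ms=20.0, window_ms=(-20.0, 80.0))
        interior = (mua.times_ms >= 20) & (mua.times_ms <= 60)
        expected = a / np.sqrt(2) * 1e3  # uV
        assert np.allclose(mua.mua[:, interior], expected, rtol=0.01)

    def test_flat_zero_signal(self):
        rec = LaminarRecording(np.zeros((3, 75000)), 25000.0,
                               np.array([100.0, 200.0, 300.0]), np.array([1.0]))
        mua = compute_mua(rec)
        assert np.allclose(mua.mua, 0.0)

    def test_burst_latency_tracks_injected_lobe(self):
        """Evoked spike bursts put the MUA peak at the negative-lobe latency."""
        cfg = CohortConfig(condition="sham", n_subjects=1, seed=5, noise_sd=0.02,
                           n_trials=10, trial_spacing=1.0, sample_rate=25000.0)
        sub = gen_evoked_lfp(cfg, [None])[0]
        mua = compute_mua(sub.recordings[None], rms_window_ms=2.0,
                          window_ms=(-20.0, 80.0))
        ch = sub.truth.peak_channel
        search = (mua.times_ms >= 5) & (mua.times_ms <= 35)
        lat = mua.times_ms[search][np.argmax(mua.mua[ch][search])]
        assert abs(lat - sub.truth.neg_latency_ms) <= 3.0

    def test_normalization_to_first_peak(self):
        cfg = CohortConfig(condition="sham", n_subjects=1, seed=5, noise_sd=0.02,
                           n_trials=5, trial_spacing=1.0, sample_rate=25000.0)
        sub = gen_evoked_lfp(cfg, [None])[0]
        mua = compute_mua(sub.recordings[None], normalize_to_first_peak=True,
                          window_ms=(-20.0, 80.0))
        first = (mua.times_ms >= 0) & (mua.times_ms <= 50)
        assert np.allclose(mua.mua[:, first].max(axis=1), 1.0)

    def test_nyquist_violation_named(self):
        rec = LaminarRecording(np.zeros((3, 5000)), 1000.0,
                               np.array([100.0, 200.0, 300.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="Nyquist"):
            compute_mua(rec)


# ---------------------------------------------------------------------------
# CSD
# ---------------------------------------------------------------------------

class TestCSD:
    depths = (np.arange(16) + 1) * 100.0

    def test_forward_then_invert_recovers_step_csd(self):
        """F^{-1} F is the identity on arbitrary step-CSD vectors."""
        f = step_forward_matrix(self.depths)
        rng = np.random.default_rng(42)
        for _ in range(5):
            c = rng.standard_normal(16)
            rec = np.linalg.solve(f, f @ c)
            assert np.linalg.norm(rec - c) / np.linalg.norm(c) < 1e-8

    def test_linear_potential_gives_zero_interior_second_difference(self):
        avg = make_flat_average(0.0, n_channels=16)
        avg.mean_trace[:] = np.linspace(0.1, 1.6, 16)[:, None]  # linear in depth
        out = csd_step_method(avg, CSDParams(method="second_difference"))
        assert np.allclose(out.csd[1:-1], 0.0, atol=1e-9)

    def test_sink_positive_and_at_injected_depth(self, noiseless_subject, noiseless_average):
        """The evoked deep sink appears as a positive CSD extremum at the
        injected depth (inverted convention, warm colours = sinks)."""
        truth = noiseless_subject.truth
        out = csd_step_method(noiseless_average, CSDParams(method="step"))
        it = np.argmin(np.abs(out.times_ms - truth.neg_latency_ms))
        ch = int(np.argmax(out.csd[:, it]))
        assert abs(ch - truth.peak_channel) <= 1
        assert out.csd[ch, it] > 0

    def test_step_and_second_difference_agree_on_sink_channel(self, noiseless_subject,
                                                              noiseless_average):
        truth = noiseless_subject.truth
        a = csd_step_method(noiseless_average, CSDParams(method="step"))
        b = csd_step_method(noiseless_average, CSDParams(method="second_difference"))
        it = np.argmin(np.abs(a.times_ms - truth.neg_latency_ms))
        assert np.argmax(a.csd[:, it]) == np.argmax(b.csd[:, it])

    def test_nonuniform_spacing_rejected(self, noiseless_average):
        avg = make_flat_average(0.0, n_channels=4)
        avg.channel_depths = np.array([100.0, 200.0, 350.0, 400.0])
        with pytest.raises(ValueError, match="uniform"):
            csd_step_method(avg, CSDParams(method="step"))


# ---------------------------------------------------------------------------
# pooling, I/O curve, irradiance
# ---------------------------------------------------------------------------

class TestPoolLayers:
    def test_arithmetic_on_default_map(self):
        pools = pool_layers(np.arange(1, 17, dtype=float))
        assert [pools.mean[k] for k in ("Sup", "Sup/Middle", "Middle/Deep", "Deep")] \
            == [2.5, 6.5, 10.5, 14.5]

    def test_constant_channels_pool_to_constant(self):
        pools = pool_layers(np.full(16, 3.25))
        assert all(v == 3.25 for v in pools.mean.values())

    def test_single_channel_groups_are_identity(self):
        vals = np.array([1.0, 2.0, 3.0])
        pools = pool_layers(vals, {"a": [0], "b": [1], "c": [2]})
        assert [pools.mean[k] for k in "abc"] == [1.0, 2.0, 3.0]

    def test_sem_across_subjects(self):
        vals = np.array([[2.0] * 16, [4.0] * 16, [6.0] * 16])
        pools = pool_layers(vals)
        assert pools.mean["Deep"] == 4.0
        assert np.isclose(pools.sem["Deep"], 2.0 / np.sqrt(3))

    @pytest.mark.parametrize("bad", [
        {"a": [0, 1], "b": [1, 2]},          # overlap
        {"a": [0], "b": [2]},                 # incomplete
        {"a": [0, 1, 2], "b": []},            # empty group
    ])
    def test_invalid_partitions_rejected(self, bad):
        with pytest.raises(ValueError):
            pool_layers(np.zeros(3), bad)


class TestIOCurve:
    def test_plateau_example(self):
        io = io_curve_from_amplitudes([1, 2, 3, 4], [1, 2, 2, 2])
        assert io.saturation_intensity == 2

    def test_linear_amplitudes_saturate_last(self):
        io = io_curve_from_amplitudes([1, 2, 3, 4], [1, 2, 3, 4])
        assert io.saturation_intensity == 4

    def test_generator_ceiling_recovered_within_one_step(self):
        """Sigmoidal response ceiling is located to +/- one intensity step."""
        intensities = np.arange(1.0, 9.0)
        scale = 1.0 / (1.0 + np.exp(-2.0 * (intensities - 3.0)))
        true_sat = intensities[np.argmax(scale >= 0.95 * scale.max())]
        avgs = {}
        for inten, s in zip(intensities, scale):
            cfg = CohortConfig(condition="sham", n_subjects=1, seed=9, noise_sd=0.0,
                               subject_cv=0.0, neg_amp_scale=float(s), n_trials=2,
                               trial_spacing=1.0)
            sub = gen_evoked_lfp(cfg, [None])[0]
            avgs[inten] = epoch_and_average(sub.recordings[None], (-50.0, 250.0))
        io = build_io_curve(avgs)
        assert abs(io.saturation_intensity - true_sat) <= 1.0

    def test_too_few_intensities_rejected(self):
        with pytest.raises(ValueError, match="3 intensities"):
            io_curve_from_amplitudes([1, 2], [1, 2])


class TestIrradiance:
    @pytest.mark.parametrize("power,expected", [(3.0, 23.865), (4.0, 31.82), (0.0, 0.0)])
    def test_calibrated_values(self, power, expected):
        assert irradiance(power, 10.0, 79.55) == pytest.approx(expected, abs=1e-12)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            irradiance(-1.0, 10.0, 79.55)
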