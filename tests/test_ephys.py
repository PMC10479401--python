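"""Sweep feature extraction: peaks, spikes, screens, ITDP, E/I, connectivity."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcloop.ephys import (
    ConnectivityTable,
    ITDPExperiment,
    StimulusEvent,
    Sweep,
    classify_monosynaptic,
    compute_itdp,
    detect_spikes,
    detect_sustained_photocurrent,
    ei_ratio,
    input_output_curve,
    measure_peak_amplitude,
    summarize_connectivity,
)
from hcloop.synth import SynthConfig, gen_itdp_experiment, gen_sweep_set, saturating_amplitude

from conftest import make_flat_sweep


class TestPeakAmplitude:
    def test_constant_trace_has_zero_amplitude(self):
        m = measure_peak_amplitude(make_flat_sweep())
        assert m.amplitude == 0.0

    def test_noise_free_psp_measures_its_generative_amplitude(self, quiet_cfg):
        sw = gen_sweep_set(quiet_cfg, n=1, intensity=100.0).sweeps[0]
        m = measure_peak_amplitude(sw)
        assert m.amplitude == pytest.approx(
            saturating_amplitude(quiet_cfg, 100.0), abs=1e-9
        )

    def test_negative_going_trough_with_min_polarity(self):
        sw = make_flat_sweep(level=0.0, clamp_mode="voltage")
        i0 = int(0.16 / sw.sampling_interval)
        sw.samples[i0:i0 + 100] = -0.5  # nA
        m = measure_peak_amplitude(sw, polarity="min")
        assert m.amplitude == pytest.approx(-0.5)

    def test_amplitude_invariant_under_constant_offset(self, quiet_cfg):
        sw = gen_sweep_set(quiet_cfg, n=1).sweeps[0]
        a0 = measure_peak_amplitude(sw).amplitude
        sw.samples = sw.samples + 12.5
        assert measure_peak_amplitude(sw).amplitude == pytest.approx(a0, abs=1e-12)

    def test_baseline_window_before_sweep_start_rejected(self):
        sw = make_flat_sweep(onset=0.05)
        with pytest.raises(ValueError, match="baseline window"):
            measure_peak_amplitude(sw, baseline_window=0.1)


class TestSpikes:
    def test_subthreshold_trace_has_no_spikes(self):
        n, _ = detect_spikes(make_flat_sweep(level=-50.0))
        assert n == 0

    def test_two_well_separated_crossings(self):
        sw = make_flat_sweep()
        dt = sw.sampling_interval
        for t in (0.2, 0.25):  # 50 ms apart
            i = int(t / dt)
            sw.samples[i:i + 10] = 20.0
        n, times = detect_spikes(sw)
        assert n == 2
        assert times == pytest.approx([0.2, 0.25], abs=2 * dt)

    def test_burst_within_refractory_counts_once(self):
        sw = make_flat_sweep()
        dt = sw.sampling_interval
        i0 = int(0.2 / dt)
        # five 0.1-ms crossings spaced 0.4 ms apart, all within one 2-ms window
        for k in range(5):
            i = i0 + k * int(0.0004 / dt)
            sw.samples[i:i + 2] = 20.0
        n, _ = detect_spikes(sw)
        assert n == 1

    def test_voltage_clamp_sweep_rejected(self):
        with pytest.raises(ValueError, match="current-clamp"):
            detect_spikes(make_flat_sweep(clamp_mode="voltage"))


class TestPhotocurrentScreen:
    def make_screen_sweep(self, plateau_pa=0.0, transient_pa=0.0):
        sw = make_flat_sweep(level=0.0, n=16_000, onset=0.1, duration=0.5,
                             clamp_mode="voltage")
        dt = sw.sampling_interval
        i0, i1 = int(0.1 / dt), int(0.6 / dt)
        sw.samples[i0:i1] += plateau_pa
        if transient_pa:
            sw.samples[i0:i0 + int(0.01 / dt)] += transient_pa
        return sw

    def test_flat_trace_is_negative(self):
        assert detect_sustained_photocurrent(self.make_screen_sweep()) is False

    def test_square_step_is_positive(self):
        assert detect_sustained_photocurrent(self.make_screen_sweep(plateau_pa=200.0))

    def test_brief_synaptic_transient_is_negative(self):
        sw = self.make_screen_sweep(transient_pa=300.0)
        assert detect_sustained_photocurrent(sw) is False

    def test_short_pulse_rejected(self):
        sw = make_flat_sweep(clamp_mode="voltage", duration=0.05)
        with pytest.raises(ValueError, match="100 ms"):
            detect_sustained_photocurrent(sw)


class TestInputOutputCurve:
    def test_identical_sweeps_give_flat_curve_with_zero_sem(self, quiet_cfg):
        sw = gen_sweep_set(quiet_cfg, n=1).sweeps[0]
        curve = input_output_curve([sw, sw, sw])
        assert len(curve) == 1
        assert curve.loc[0, "sem_amplitude"] == 0.0

    def test_single_intensity_group_is_one_row(self, quiet_cfg):
        curve = input_output_curve(gen_sweep_set(quiet_cfg, n=4, intensity=30).sweeps)
        assert len(curve) == 1
        assert curve.loc[0, "intensity"] == 30

    def test_group_means_track_the_saturating_generative_curve(self, cfg):
        sweeps, expected = [], {}
        for intensity in (10.0, 25.0, 50.0, 100.0):
            s = gen_sweep_set(cfg, n=30, intensity=intensity,
                              seed=int(intensity))
            sweeps.extend(s.sweeps)
            expected[intensity] = saturating_amplitude(cfg, intensity)
        curve = input_output_curve(sweeps, smooth=0.002)
        assert list(curve["intensity"]) == sorted(expected)
        for _, row in curve.iterrows():
            # smoothed-extremum readout carries a small positive noise bias
            assert row["mean_amplitude"] == pytest.approx(
                expected[row["intensity"]], abs=0.3
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one sweep"):
            input_output_curve([])


class TestITDP:
    def test_unchanged_responses_give_unity_fold(self, quiet_cfg):
        exp = gen_itdp_experiment(quiet_cfg, fold=1.0)
        res = compute_itdp(exp)
        assert res.potentiation_fold == pytest.approx(1.0, abs=1e-6)
        assert res.spike_probability_pre == 0.0
        assert res.spike_probability_post == 0.0

    def test_7_over_4_mv_gives_1p75_fold(self, quiet_cfg):
        # pre steady state 4 mV, every late post sweep 7 mV
        exp = gen_itdp_experiment(quiet_cfg, fold=1.75)
        res = compute_itdp(exp)
        # default smoothing flattens the peak slightly but cancels in the ratio
        assert res.baseline_amplitude == pytest.approx(4.0, abs=0.05)
        assert res.potentiation_fold == pytest.approx(1.75, abs=1e-9)

    def test_spiking_fraction_of_last_ten_post_sweeps(self, quiet_cfg):
        import dataclasses
        # threshold low enough that jittered post amplitudes straddle it
        cfg = dataclasses.replace(quiet_cfg, spike_threshold_depol=7.0,
                                  amplitude_jitter_sd=1.0)
        exp = gen_itdp_experiment(cfg, fold=1.75, seed=5)
        res = compute_itdp(exp)
        assert 0.0 < res.spike_probability_post <= 1.0
        assert res.spike_probability_post == pytest.approx(
            sum(s.samples.max() > 0 for s in exp.post_sweeps[-10:]) / 10
        )

    def test_all_spiking_post_epoch_flags_undefined_fold(self, quiet_cfg):
        import dataclasses
        cfg = dataclasses.replace(quiet_cfg, spike_threshold_depol=5.0)
        exp = gen_itdp_experiment(cfg, fold=1.75)
        res = compute_itdp(exp)
        assert not res.fold_defined
        assert np.isnan(res.potentiation_fold)
        assert res.spike_probability_post == 1.0

    def test_fewer_than_ten_sweeps_rejected(self, quiet_cfg):
        sweeps = gen_itdp_experiment(quiet_cfg, fold=1.0).pre_sweeps
        with pytest.raises(ValueError, match=">= 10"):
            ITDPExperiment(pre_sweeps=sweeps[:5], post_sweeps=sweeps)

    @pytest.mark.parametrize("fold", [1.0, 1.12, 1.40, 1.75])
    def test_fold_recovery_under_noise(self, fold):
        """0.5 mV trace noise leaves the recovered fold within +/-0.1."""
        cfg = SynthConfig(seed=99, noise_sd=0.5)
        est = [
            compute_itdp(gen_itdp_experiment(cfg, fold=fold, seed=7 + i)
                         ).potentiation_fold
            for i in range(5)
        ]
        assert np.mean(est) == pytest.approx(fold, abs=0.1)


class TestEIRatio:
    @pytest.mark.parametrize(
        "epsc,ipsc,expected",
        [(-0.5, 2.0, 0.25), (-1.0, 1.0, 1.0), (-0.83, 1.61, 0.5155)],
    )
    def test_definitional_examples(self, epsc, ipsc, expected):
        assert ei_ratio(epsc, ipsc) == pytest.approx(expected, abs=1e-4)

    @settings(derandomize=True, max_examples=30)
    @given(epsc=st.floats(-5, -0.01), ipsc=st.floats(0.01, 5),
           c=st.floats(0.1, 10))
    def test_scale_invariance(self, epsc, ipsc, c):
        assert ei_ratio(c * epsc, c * ipsc) == pytest.approx(
            ei_ratio(epsc, ipsc), rel=1e-9
        )

    def test_zero_ipsc_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ei_ratio(-1.0, 0.0)


class TestMonosynaptic:
    def peak(self, amplitude):
        sw = make_flat_sweep()
        i = int(0.16 / sw.sampling_interval)
        sw.samples[i:i + 50] += amplitude
        return measure_peak_amplitude(sw)

    def test_large_response_is_monosynaptic(self):
        assert classify_monosynaptic(self.peak(10.0), noise_sd=1.0)

    def test_flat_response_is_not(self):
        assert not classify_monosynaptic(self.peak(0.0), noise_sd=1.0)

    def test_boundary_at_exactly_k_sd_is_excluded(self):
        assert not classify_monosynaptic(self.peak(3.0), noise_sd=1.0, k=3)

    def test_invalid_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            classify_monosynaptic(self.peak(1.0), noise_sd=0.0)


class TestConnectivity:
    def test_reported_cohort_percentages(self):
        from hcloop.reference import CONNECTIVITY_COUNTS

        df = summarize_connectivity(CONNECTIVITY_COUNTS).set_index(
            ["layer", "category"]
        )
        assert df.loc[("EC_L5", "responsive"), "percent"] == 98.36
        assert df.loc[("EC_L2/3", "responsive"), "percent"] == 87.50
        assert df.loc[("EC_L5", "spiking"), "percent"] == 27.66
        assert df.loc[("EC_L5", "monosynaptic"), "percent"] == 81.82
        assert df.loc[("EC_L2/3", "monosynaptic"), "percent"] == 40.91

    def test_zero_responsive_cells(self):
        df = summarize_connectivity(
            ConnectivityTable(counts={"L": {"responsive": (0, 10)}})
        )
        assert df.loc[0, "percent"] == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(1, 500), data=st.data())
    def test_matches_exact_rational_fraction(self, n, data):
        c = data.draw(st.integers(0, n))
        df = summarize_connectivity(
            ConnectivityTable(counts={"L": {"responsive": (c, n)}})
        )
        exact = Fraction(100 * c, n)
        assert abs(df.loc[0, "percent"] - float(exact)) <= 0.005

    def test_count_above_denominator_rejected(self):
        with pytest.raises(ValueError):
            ConnectivityTable(counts={"L": {"responsive": (11, 10)}})

    def test_zero_tested_rejected_at_summary(self):
        with pytest.raises(ValueError, match="0 tested"):
            summarize_connectivity(
                ConnectivityTable(counts={"L": {"responsive": (0, 0)}})
            )
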