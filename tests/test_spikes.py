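"""Both spike detectors, amplitude conventions, SNR and cell QC."""

import numpy as np
import pytest
from scipy import stats

from voltimage import (
    APTemplate,
    DffTrace,
    SensorParams,
    SpikeTrain,
    VmConfig,
    amplitude_correct,
    cell_qc,
    detect_spikes_fixed_threshold,
    detect_spikes_kde,
    dff_detrend,
    simulate_vm,
    snr_cell,
    snr_high_frequency,
    spike_amplitude_trough_to_peak,
    spike_waveform_and_halfwidth,
    vm_to_fluorescence,
)
from voltimage.spikes import _local_maxima, highpass_dff

from conftest import f1_score, match_spikes


def pos_dff(values, fs=1000.0):
    return DffTrace(values=np.asarray(values, float), fs=fs,
                    polarity="positive_spikes",
                    baseline_method="moving_avg_1s_inverted")


def neg_dff(values, fs=500.0):
    return DffTrace(values=np.asarray(values, float), fs=fs,
                    polarity="negative_spikes", baseline_method="median_20ms")


class TestLocalMaxima:
    @pytest.mark.parametrize("x,expected", [
        ([0, 1, 0], [1]),
        ([0, 1, 1, 0], [1]),        # plateau takes the first sample
        ([0, 1, 2, 3], []),          # monotone has no interior peak
        ([3, 2, 1, 2, 3], []),       # valley only
        ([0, 2, 1, 3, 0], [1, 3]),
    ])
    def test_plateau_first_convention(self, x, expected):
        assert _local_maxima(np.array(x, float)).tolist() == expected


class TestAmplitudeCorrection:
    @staticmethod
    def template(peak=1.0):
        # triangular AP template over ±2 ms with value 0.4·peak at 1.5 ms
        lags = np.array([-2e-3, 0.0, 1.5e-3, 2.5e-3])
        vals = np.array([0.0, peak, 0.4 * peak, 0.0])
        return APTemplate(lags_s=lags, values=vals)

    def test_shadowed_peak_subtraction_is_exact(self):
        a = 0.10
        tpl = self.template(a)
        corrected = amplitude_correct(
            np.array([0.0, 1.5e-3]), np.array([a, 0.6 * a]), tpl)
        assert corrected[0] == a  # larger peak untouched
        assert corrected[1] == pytest.approx(0.2 * a, abs=1e-15)

    def test_isolated_and_smaller_neighbors_unchanged(self):
        tpl = self.template()
        times = np.array([0.0, 0.010, 0.0115])
        amps = np.array([1.0, 0.5, 0.8])
        corrected = amplitude_correct(times, amps, tpl)
        assert corrected[0] == 1.0  # isolated
        # peak 1 has a larger neighbor (peak 2) within 1.5 ms -> corrected
        assert corrected[1] == pytest.approx(0.5 - tpl(-1.5e-3), abs=1e-15)
        # peak 2's neighbor is smaller -> unchanged
        assert corrected[2] == 0.8

    def test_matches_bruteforce_on_all_small_clusters(self, rng):
        # oracle: direct definition applied peak by peak
        tpl = self.template()
        for _ in range(200):
            n = rng.integers(1, 4)
            times = np.sort(rng.uniform(0, 6e-3, n))
            amps = rng.uniform(0.1, 1.0, n)
            got = amplitude_correct(times, amps, tpl)
            expected = amps.copy()
            for i in range(n):
                bigger = [j for j in range(n)
                          if j != i and amps[j] > amps[i]
                          and abs(times[i] - times[j]) <= 2e-3]
                if bigger:
                    j = max(bigger, key=lambda j: amps[j])
                    expected[i] = amps[i] - tpl(times[i] - times[j])
            assert np.allclose(got, expected)

    def test_idempotent_on_isolated_peaks(self, rng):
        tpl = self.template()
        times = np.arange(10) * 0.1
        amps = rng.uniform(0.5, 1.0, 10)
        once = amplitude_correct(times, amps, tpl)
        twice = amplitude_correct(times, once, tpl)
        assert np.array_equal(once, amps)
        assert np.array_equal(twice, once)


class TestKdeDetector:
    @staticmethod
    def noisy_recording(seed, duration=180.0, rate=2.0, amp_over_sigma=10.0):
        cfg = VmConfig(duration=duration, spike_rate=rate, seed=seed)
        vm, spikes = simulate_vm(cfg)
        sensor = SensorParams()
        clean = vm_to_fluorescence(vm, sensor, noise_sd=0.0)
        hp = highpass_dff(dff_detrend(clean, "moving_avg_1s_inverted"))
        idx = np.round(spikes * cfg.fs).astype(int)
        amp = float(np.median(hp.values[idx])) if idx.size else 0.04
        sigma = amp / amp_over_sigma
        noisy = vm_to_fluorescence(vm, sensor, noise_sd=sigma, seed=seed + 1)
        return dff_detrend(noisy, "moving_avg_1s_inverted"), spikes, sigma

    def test_pure_noise_final_false_positives_below_cap(self):
        dff, _, _ = self.noisy_recording(seed=5, rate=0.0)
        train, model = detect_spikes_kde(dff)
        assert model.fp_cap == 18
        assert train.n_spikes <= 18

    def test_high_snr_recall_and_false_positive_rate(self):
        dff, spikes, _ = self.noisy_recording(seed=2, amp_over_sigma=10.0)
        train, model = detect_spikes_kde(dff)
        tp, fp, fn = match_spikes(spikes, train.times)
        assert tp / (tp + fn) >= 0.95
        assert fp / dff.duration <= 0.1

    def test_polarity_contract(self):
        with pytest.raises(ValueError):
            detect_spikes_kde(neg_dff(np.zeros(20000)))

    def test_no_candidates_yields_empty_train_with_model(self):
        train, model = detect_spikes_kde(pos_dff(np.zeros(20000)))
        assert train.n_spikes == 0
        assert model.candidate_amps.size == 0

    def test_raising_fp_cap_never_loses_spikes(self):
        dff, _, _ = self.noisy_recording(seed=9, amp_over_sigma=6.0)
        counts = []
        for cap in (0.05, 0.1, 0.5, 2.0):
            train, _ = detect_spikes_kde(dff, fp_rate_cap=cap)
            counts.append(train.n_spikes)
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_model_exposes_consistent_intermediates(self):
        dff, _, _ = self.noisy_recording(seed=3)
        train, model = detect_spikes_kde(dff)
        assert np.allclose(model.s_density,
                           model.p_density - model.pnoise_density)
        assert model.snr == pytest.approx(
            model.amplitude_mean / model.noise_sd)
        assert model.n_fp <= model.fp_cap or model.threshold == model.th1


class TestFixedThresholdDetector:
    def test_doublet_rule_takes_larger_amplitude(self):
        x = np.zeros(1000)
        x[500] = -5.0
        x[501] = -6.0
        train = detect_spikes_fixed_threshold(neg_dff(x), sd_noise=1.0, k=4)
        assert train.n_spikes == 1
        assert train.times[0] == pytest.approx(501 / 500.0)
        assert train.amplitudes[0] == 6.0

    def test_no_crossing_gives_empty_train(self):
        x = np.zeros(1000)
        train = detect_spikes_fixed_threshold(neg_dff(x), sd_noise=1.0)
        assert train.n_spikes == 0

    def test_gaussian_false_spike_rate_matches_tail_bound(self, rng):
        # 10 min of N(0, σ²) noise at 500 Hz: expected false-spike rate
        # ≈ fs·60·Φ(−4) ≈ 0.95/min before merging, and ≤ 2/min
        fs = 500.0
        minutes = 10.0
        x = rng.normal(0, 1.0, int(fs * 60 * minutes))
        train = detect_spikes_fixed_threshold(neg_dff(x, fs=fs), sd_noise=1.0)
        rate_per_min = train.n_spikes / minutes
        expected = fs * 60 * stats.norm.cdf(-4.0)
        # Poisson fluctuation bound: 3 SDs on the total count
        sd = np.sqrt(expected * minutes) / minutes
        assert abs(rate_per_min - expected) <= 3 * sd + 0.05
        assert rate_per_min <= 2.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes_fixed_threshold(
                pos_dff(np.zeros(100)), sd_noise=1.0)
        with pytest.raises(ValueError):
            detect_spikes_fixed_threshold(neg_dff(np.zeros(100)), sd_noise=0.0)


class TestWaveformAndQc:
    def test_triangular_template_fwhm_is_half_base(self):
        fs = 20000.0
        x = np.zeros(int(fs))
        tri = np.concatenate([np.linspace(0, 1, 21), np.linspace(1, 0, 21)[1:]])
        spike_idx = [2000, 6000, 10000, 14000, 17000]
        for i in spike_idx:
            x[i - 20: i + 21] = tri  # base 2 ms at 20 kHz
        hp = pos_dff(x, fs=fs)
        tpl, hw = spike_waveform_and_halfwidth(hp, np.array(spike_idx) / fs)
        assert hw == pytest.approx(1.0, abs=0.06)

    def test_edge_spikes_dropped_from_average(self):
        fs = 10000.0
        x = np.zeros(1000)
        x[500] = 1.0
        hp = pos_dff(x, fs=fs)
        tpl, _ = spike_waveform_and_halfwidth(
            hp, np.array([0.00005, 0.05]))  # first spike window leaves trace
        assert tpl is not None
        assert tpl.values.max() == pytest.approx(1.0)

    def test_recovered_template_matches_injection(self, rng):
        fs = 10000.0
        shape = np.exp(-np.abs(np.arange(-20, 41)) / 8.0)
        x = rng.normal(0, 0.02, 200000)
        times = np.arange(100) * 0.02 + 0.01
        for t in times:
            i = int(t * fs)
            x[i - 20: i + 41] += shape
        tpl, _ = spike_waveform_and_halfwidth(pos_dff(x, fs=fs), times)
        assert np.max(np.abs(tpl.values - shape)) < 5 * 0.02 / np.sqrt(100)

    def test_snr_is_amplitude_over_noise(self):
        assert snr_cell(10.0, 2.0) == 5.0
        with pytest.raises(ValueError):
            snr_cell(1.0, 0.0)

    def test_hippocampal_qc_gates_are_strict(self):
        train_91 = SpikeTrain(times=np.linspace(0, 179, 91),
                              amplitudes=np.ones(91))
        # SNR exactly 5 fails the "exceeded 5" criterion
        rep = cell_qc(5.0, train_91, halfwidth_ms=0.5, duration_s=180.0)
        assert not rep.criteria["snr"]
        assert rep.criteria["n_spikes"]  # 91 > 90
        rep2 = cell_qc(6.0, train_91, halfwidth_ms=0.5, duration_s=180.0)
        assert rep2.passed

    def test_count_gate_at_90(self):
        train_90 = SpikeTrain(times=np.linspace(0, 179, 90),
                              amplitudes=np.ones(90))
        rep = cell_qc(6.0, train_90, halfwidth_ms=0.5, duration_s=180.0)
        assert not rep.criteria["n_spikes"]

    def test_isi_violation_fraction_rule(self):
        times = np.concatenate([np.arange(99) * 0.1,
                                [9.8001, 9.8011]])  # 2 short ISIs
        times = np.sort(times)
        train = SpikeTrain(times=times, amplitudes=np.ones(times.size))
        rep = cell_qc(6.0, train, halfwidth_ms=0.5, duration_s=180.0)
        assert rep.frac_isi_below_2ms >= 0.02
        assert not rep.criteria["isi"]

    def test_alm_profile_uses_snr_3(self):
        train = SpikeTrain(times=np.array([1.0]), amplitudes=np.array([1.0]))
        assert cell_qc(3.0, train, np.nan, 180.0, profile="alm").passed
        assert not cell_qc(2.9, train, np.nan, 180.0, profile="alm").passed


class TestAmplitudeConventions:
    def test_trough_to_peak_on_constructed_doublet(self):
        fs = 1000.0
        x = np.zeros(1000)
        x[500] = 0.09
        x[505] = 0.02  # trough between
        x[510] = 0.10
        d = pos_dff(x, fs=fs)
        train = SpikeTrain(times=np.array([0.5, 0.510]),
                           amplitudes=np.array([0.09, 0.10]))
        amps = spike_amplitude_trough_to_peak(d, train)
        assert amps.size == 1
        assert amps[0] == pytest.approx(0.10 - 0.0, abs=1e-12)

    def test_widely_spaced_spikes_do_not_qualify(self):
        d = pos_dff(np.zeros(1000))
        train = SpikeTrain(times=np.array([0.1, 0.125]),
                           amplitudes=np.ones(2))
        assert spike_amplitude_trough_to_peak(d, train).size == 0

    def test_single_spike_gives_empty(self):
        d = pos_dff(np.zeros(1000))
        train = SpikeTrain(times=np.array([0.1]), amplitudes=np.ones(1))
        assert spike_amplitude_trough_to_peak(d, train).size == 0

    def test_hf_snr_matches_bruteforce_formula(self, rng):
        x = rng.normal(0, 1.0, 200)
        d = pos_dff(x, fs=100.0)
        train = SpikeTrain(times=np.array([0.5, 1.0]),
                           amplitudes=np.ones(2))
        got = snr_high_frequency(d, train)
        med = np.median(x)
        expected = np.mean([x[50], x[100]]) / np.sqrt(
            np.mean((x - med) ** 2))
        assert got == pytest.approx(expected)

    def test_hf_snr_scale_invariant_and_flat_trace_flagged(self, rng):
        x = rng.normal(0, 1.0, 500) + 5.0
        d1 = pos_dff(x, fs=100.0)
        d2 = pos_dff(3.0 * x, fs=100.0)
        train = SpikeTrain(times=np.array([1.0]), amplitudes=np.ones(1))
        assert snr_high_frequency(d2, train) == pytest.approx(
            snr_high_frequency(d1, train))
        flat = pos_dff(np.zeros(100), fs=100.0)
        assert snr_high_frequency(flat, train) == np.inf
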