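"""CCG, coincidence fractions, synchrony strength, co-depolarization."""

import numpy as np
import pytest
from scipy import stats

from voltimage import (
    DffTrace,
    PopulationConfig,
    SpikeTrain,
    VmConfig,
    ccg,
    co_depolarization,
    fraction_synchronous,
    simulate_cells,
    synchrony_codep_correlation,
    synchrony_strength,
)
from voltimage.synth import psp_waveform


def train(times):
    times = np.asarray(times, float)
    return SpikeTrain(times=times, amplitudes=np.ones(times.size))


def poisson_train(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return train(np.sort(rng.uniform(0, duration, n)))


class TestCcg:
    def test_identical_trains_peak_in_central_bin(self, rng):
        a = poisson_train(2.0, 120.0, rng)
        res = ccg(a, a)
        assert res.counts[np.argmin(np.abs(res.lags_ms))] >= a.n_spikes
        assert res.fwhm_ms <= 0.5

    def test_time_reversal_symmetry(self, rng):
        a = poisson_train(2.0, 60.0, rng)
        b = poisson_train(3.0, 60.0, rng)
        ab = ccg(a, b)
        ba = ccg(b, a)
        assert np.array_equal(ab.counts, ba.counts[::-1])

    def test_independent_poisson_is_flat_with_undefined_width(self, rng):
        a = poisson_train(4.0, 300.0, rng)
        b = poisson_train(4.0, 300.0, rng)
        res = ccg(a, b)
        # uniformity: no bin deviates from the mean by more than Poisson
        # fluctuation allows
        mean = res.counts.mean()
        assert np.all(np.abs(res.counts - mean) < 6 * np.sqrt(mean))
        assert np.isnan(res.fwhm_ms)

    def test_triangular_ccg_has_fwhm_4ms(self, rng):
        # deterministic triangular lag distribution with base 8 ms:
        # FWHM of the triangle is half the base = 4 ms
        n = 4000
        u = (np.arange(n) + 0.5) / n
        base_half = 4e-3
        lags = np.where(
            u < 0.5,
            -base_half * (1 - np.sqrt(2 * u)),
            base_half * (1 - np.sqrt(2 * (1 - u))),
        )
        ref_times = np.arange(n) * 1.0 + 100.0
        tgt_times = np.sort(ref_times + lags)
        res = ccg(train(ref_times), train(tgt_times))
        assert res.fwhm_ms == pytest.approx(4.0, abs=0.5)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            ccg(train([]), train([1.0]))


class TestFractionSynchronous:
    def test_identical_trains_are_fully_synchronous(self, rng):
        a = poisson_train(2.0, 60.0, rng)
        frac, shuf = fraction_synchronous(a, a, 60.0, seed=0)
        assert frac == 100.0
        assert shuf < 50.0

    def test_disjoint_trains_are_asynchronous(self):
        a = train(np.arange(10) * 1.0)
        b = train(np.arange(10) * 1.0 + 0.5)
        frac, _ = fraction_synchronous(a, b, 20.0, seed=0)
        assert frac == 0.0

    def test_symmetry_in_arguments(self, rng):
        a = poisson_train(2.0, 100.0, rng)
        b = poisson_train(3.0, 100.0, rng)
        fab, _ = fraction_synchronous(a, b, 100.0, seed=3)
        fba, _ = fraction_synchronous(b, a, 100.0, seed=3)
        assert fab == fba

    def test_independent_poisson_matches_closed_form(self, rng):
        # P(partner within ±5 ms) = 1 − exp(−2·r·w) for rate r = 2 Hz
        obs, shufs = [], []
        for _ in range(5):
            a = poisson_train(2.0, 180.0, rng)
            b = poisson_train(2.0, 180.0, rng)
            frac, shuf = fraction_synchronous(a, b, 180.0, seed=1)
            obs.append(frac)
            shufs.append(shuf)
        expected = 100 * (1 - np.exp(-2 * 2.0 * 5e-3))
        assert np.mean(obs) == pytest.approx(expected, abs=0.8)
        assert np.mean(shufs) == pytest.approx(expected, abs=0.5)


class TestSynchronyStrength:
    def test_independent_poisson_ratio_near_one(self, rng):
        ratios = [synchrony_strength(poisson_train(5.0, 600.0, rng),
                                     poisson_train(5.0, 600.0, rng))
                  for _ in range(10)]
        assert np.nanmean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_identical_trains_give_large_ratio(self, rng):
        a = poisson_train(2.0, 300.0, rng)
        ratio = synchrony_strength(a, a)
        assert ratio > 10.0

    def test_ratio_increases_with_coupling_weight(self):
        def strength_at(w, seed):
            cfg = PopulationConfig(
                n_cells=2,
                cell_positions=np.array([[0.0, 0.0], [50.0, 0.0]]),
                shared_input_weights=np.array([[0, w], [w, 0]], float),
                vm=VmConfig(duration=120.0, spike_rate=2.0),
                noise_sd=0.0,
                seed=seed,
            )
            _, truth = simulate_cells(cfg)
            return synchrony_strength(train(truth.spike_times[0]),
                                      train(truth.spike_times[1]))

        lo = np.nanmean([strength_at(0.3, s) for s in range(5)])
        hi = np.nanmean([strength_at(0.7, s) for s in range(5)])
        assert hi > lo

    def test_poisson_ratio_within_analytic_ci(self, rng):
        # on independent trains the ratio should sit inside the 95% CI of 1
        # in ≥ 90% of seeded runs
        inside = 0
        n_runs = 50
        for _ in range(n_runs):
            a = poisson_train(4.0, 300.0, rng)
            b = poisson_train(4.0, 300.0, rng)
            lags = np.abs(np.subtract.outer(a.times, b.times))
            n_sync = np.sum(lags <= 1.5e-3)
            n_ctrl = np.sum((lags >= 15e-3) & (lags <= 25e-3))
            ratio = synchrony_strength(a, b)
            if np.isnan(ratio):
                continue
            # delta-method CI on a ratio of Poisson counts
            se = ratio * np.sqrt(1 / max(n_sync, 1) + 1 / max(n_ctrl, 1))
            if abs(ratio - 1.0) <= 1.96 * se:
                inside += 1
        assert inside >= 0.9 * n_runs


class TestCoDepolarization:
    @staticmethod
    def target_with_bumps(ref_times, bump_pct, fs=1000.0, duration=200.0,
                          sigma=0.002, rng=None, center=True):
        rng = rng or np.random.default_rng(0)
        x = rng.normal(0, sigma, int(duration * fs))
        t_axis = np.arange(x.size) / fs
        for tr in ref_times:
            # bump peaking at the reference spike time
            onset = tr - 0.005
            sel = (t_axis >= onset) & (t_axis < onset + 0.1)
            x[sel] += bump_pct / 100.0 * psp_waveform(
                t_axis[sel] - onset, 1.0, 2.0, 10.0)
        return DffTrace(values=x, fs=fs, polarity="positive_spikes",
                        baseline_method="moving_avg_1s_inverted")

    def test_flat_target_has_zero_codep(self):
        dff = DffTrace(values=np.zeros(100_000), fs=1000.0,
                       polarity="positive_spikes",
                       baseline_method="moving_avg_1s_inverted")
        refs = train(np.arange(10.0, 90.0, 0.4))
        res = co_depolarization(dff, train([]), refs)
        assert res.codep_size_pct == 0.0
        assert not res.low_confidence

    def test_injected_bump_recovered_within_10pct(self, rng):
        refs = np.arange(5.0, 195.0, 0.8)  # ≥ 200 reference spikes
        dff = self.target_with_bumps(refs, bump_pct=1.0, rng=rng)
        res = co_depolarization(dff, train([]), train(refs))
        assert res.n_segments >= 200
        assert res.codep_size_pct == pytest.approx(1.0, rel=0.10)

    def test_target_spikes_near_references_are_excluded(self):
        dff = DffTrace(values=np.zeros(50_000), fs=1000.0,
                       polarity="positive_spikes",
                       baseline_method="moving_avg_1s_inverted")
        refs = train(np.arange(1.0, 49.0, 1.0))
        # target spikes 5 ms after every reference -> all segments excluded
        tgt = train(np.arange(1.0, 49.0, 1.0) + 0.005)
        res = co_depolarization(dff, tgt, refs)
        assert res.n_segments == 0
        assert res.low_confidence


class TestSynchronyCodepCorrelation:
    # keep the averaged segments free of the target's own APs: exclude
    # reference spikes with a target spike anywhere in the analysis window
    CODEP_KWARGS = dict(exclusion_ms=30.0, win_ms=(-30.0, 30.0),
                        baseline_ms=(-30.0, -20.0))

    @staticmethod
    def star_population(seed=0, n_refs=16, duration=300.0):
        """Target cell 0 coupled to references with varied weights.

        Weights stay below ~0.6: beyond that nearly every shared event
        makes the target spike, leaving no subthreshold co-depolarization
        to measure.
        """
        n = n_refs + 1
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 300.0, (n, 2))
        weights = np.zeros((n, n))
        w_vals = np.linspace(0.15, 0.6, n_refs)
        rng.shuffle(w_vals)  # decorrelate weight from index/distance
        weights[0, 1:] = w_vals
        weights[1:, 0] = w_vals
        cfg = PopulationConfig(
            n_cells=n,
            cell_positions=pos,
            shared_input_weights=weights,
            vm=VmConfig(duration=duration, spike_rate=2.0),
            noise_sd=0.0003,
            shared_event_rate=1.0,
            codep_bump_mv=15.0,
            seed=seed,
        )
        return cfg, w_vals

    def test_same_pair_correlation_high_different_near_zero(self):
        # averaged over independent populations, pair-specific coupling
        # must show up in r_same but not in the distance-matched control
        r_same, r_diff = [], []
        for seed in range(6):
            cfg, _ = self.star_population(seed=seed)
            rec, _ = simulate_cells(cfg)
            results = synchrony_codep_correlation(rec, min_refs=10,
                                                  **self.CODEP_KWARGS)
            r0 = {r.target: r for r in results}[0]
            r_same.append(r0.r_same)
            r_diff.append(r0.r_different)
        assert np.mean(r_same) > 0.8
        assert abs(np.mean(r_diff)) < 0.3

    def test_degenerate_codep_flagged(self):
        # all-zero traces: codep sizes identical -> correlation undefined
        n = 12
        zeros = DffTrace(values=np.zeros(30_000), fs=1000.0,
                         polarity="positive_spikes",
                         baseline_method="moving_avg_1s_inverted")
        from voltimage import PopulationRecording
        rng = np.random.default_rng(1)
        rec = PopulationRecording(
            dff=[zeros] * n,
            spikes=[train(np.sort(rng.uniform(0, 30.0, 60)))
                    for _ in range(n)],
            positions=rng.uniform(0, 100, (n, 2)),
        )
        results = synchrony_codep_correlation(rec, min_refs=10)
        assert all(np.isnan(r.r_same) for r in results)

    def test_permuting_references_destroys_correlation(self):
        cfg, _ = self.star_population(seed=1)
        rec, truth = simulate_cells(cfg)
        results = synchrony_codep_correlation(rec, min_refs=10,
                                              **self.CODEP_KWARGS)
        r0 = {r.target: r for r in results}[0]
        # permutation null: pair synchrony values with shuffled codep values
        from voltimage.synchrony import co_depolarization as codep
        sync, sizes = [], []
        for j in range(1, rec.n_cells):
            sync.append(synchrony_strength(rec.spikes[j], rec.spikes[0]))
            sizes.append(codep(rec.dff[0], rec.spikes[0], rec.spikes[j],
                               **self.CODEP_KWARGS).codep_size_pct)
        rng = np.random.default_rng(0)
        perms = [abs(stats.pearsonr(sync, rng.permutation(sizes))[0])
                 for _ in range(100)]
        assert r0.r_same > np.percentile(perms, 95)


class TestRoundTrip:
    def test_synchrony_monotone_in_imposed_weight_across_population(self):
        # pairwise weights spanning [0, 1): measured synchrony strength
        # must track the imposed coupling (Spearman ≥ 0.9 at low noise)
        n = 6
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 200, (n, 2))
        weights = np.zeros((n, n))
        vals = np.linspace(0.0, 0.9, n * (n - 1) // 2)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                weights[i, j] = weights[j, i] = vals[k]
                k += 1
        cfg = PopulationConfig(
            n_cells=n, cell_positions=pos, shared_input_weights=weights,
            vm=VmConfig(duration=240.0, spike_rate=3.0),
            noise_sd=0.0, shared_event_rate=0.4, seed=5,
        )
        _, truth = simulate_cells(cfg)
        imposed, measured = [], []
        for i in range(n):
            for j in range(i + 1, n):
                s = synchrony_strength(train(truth.spike_times[i]),
                                       train(truth.spike_times[j]))
                if np.isfinite(s):
                    imposed.append(weights[i, j])
                    measured.append(s)
        rho = stats.spearmanr(imposed, measured).statistic
        assert rho >= 0.9
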