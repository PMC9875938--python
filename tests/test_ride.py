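"""RIDE decomposition: latency recovery, identities and robustness."""

import numpy as np
import pytest

import ridemvpa as rm
from ridemvpa.ride import _shift_zero, estimate_latencies


@pytest.fixture()
def decomposed(nogo_decomposition):
    return nogo_decomposition


class TestEstimateLatencies:
    def _template(self):
        rng = np.random.default_rng(0)
        topo = rng.standard_normal(8)
        wave = np.exp(-((np.arange(200) - 100) ** 2) / (2 * 15.0**2))
        return np.outer(topo, wave)

    def test_recovers_known_shift(self):
        tmpl = self._template()
        resid = _shift_zero(tmpl, 10)[None]
        assert estimate_latencies(resid, tmpl, (50, 150), ref_sample=100)[0] == 110

    def test_orthogonal_residual_tie_breaks_to_zero_shift(self):
        tmpl = self._template()
        resid = np.zeros_like(tmpl)[None]
        assert estimate_latencies(resid, tmpl, (50, 150), ref_sample=100)[0] == 100

    def test_noisy_shifts_mean_error_below_half_jitter(self):
        rng = np.random.default_rng(1)
        tmpl = self._template()
        jitter_sd = 20.0
        shifts = rng.normal(0, jitter_sd, size=300).round().astype(int).clip(-60, 60)
        scale = tmpl.std()
        resid = np.stack([
            _shift_zero(tmpl, s) + scale * rng.standard_normal(tmpl.shape)  # SNR 1
            for s in shifts
        ])
        est = estimate_latencies(resid, tmpl, (40, 160), ref_sample=100)
        err = np.abs((est - 100) - shifts)
        assert err.mean() < jitter_sd / 2

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_latencies(np.ones((1, 2, 50)), np.ones((2, 50)), (30, 10))

    def test_zero_template_rejected(self):
        with pytest.raises(ValueError):
            estimate_latencies(np.ones((1, 2, 50)), np.zeros((2, 50)), (10, 30))


class TestDecomposition:
    def test_two_source_recovery(self, decomposed):
        """C latencies r >= 0.8 with truth; S waveform r >= 0.9 at its peak channel."""
        epochs, truth, result = decomposed
        true_idx = np.searchsorted(epochs.times_ms, truth.c_latency_ms)
        r_lat = np.corrcoef(result.c_latency_samples, true_idx)[0, 1]
        assert r_lat >= 0.8
        ch = np.abs(truth.s_topography).argmax()
        r_s = np.corrcoef(result.s_waveform[ch], truth.s_waveform)[0, 1]
        assert r_s >= 0.9

    def test_latencies_inside_search_window(self, decomposed):
        epochs, _, result = decomposed
        t_lat = epochs.times_ms[result.c_latency_samples]
        assert (t_lat >= 150.0).all() and (t_lat <= 800.0).all()

    def test_c_waveform_zero_outside_window(self, decomposed):
        epochs, _, result = decomposed
        outside = ~epochs.time_mask(150.0, 800.0)
        assert np.abs(result.c_waveform[:, outside]).max() < 1e-9

    def test_median_latency_change_nonincreasing(self, decomposed):
        _, _, result = decomposed
        h = result.latency_history
        deltas = [np.median(np.abs(h[i + 1] - h[i])) for i in range(len(h) - 1)]
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(deltas, deltas[1:]))
        assert result.converged

    def test_pure_s_data_gives_average_and_degenerate_c(self, montage60):
        design = rm.TaskDesign(n_trials=16, go_proportion=0.5, n_blocks=2)
        trials = rm.generate_trial_table(design, seed=0)
        trials = rm.simulate_behaviour(trials, seed=0)
        tp = rm.TruthParams(srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0),
                            c_amp=0.0, pink_sd=0.0, white_sd=0.0)
        epochs, truth = rm.simulate_epochs(trials, tp, montage60, seed=0)
        result = rm.ride_decompose(epochs)
        assert result.degenerate and result.converged
        assert np.abs(result.c_waveform).max() < 1e-9
        avg = epochs.data.mean(axis=0)
        inner = epochs.time_mask(-100.0, 500.0)  # away from taper edges
        assert np.allclose(result.s_waveform[:, inner], avg[:, inner], atol=1e-8)

    def test_zero_jitter_constant_latencies_and_reconstruction(self, montage60):
        from ridemvpa.task_sim import CONGRUENT, INCONGRUENT
        design = rm.TaskDesign(n_trials=32, go_proportion=0.5, n_blocks=2)
        trials = rm.generate_trial_table(design, seed=0)
        trials = rm.simulate_behaviour(trials, rm.BehaviourParams(rt_sd_ms=0.0), seed=0)
        tp = rm.TruthParams(
            srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0),
            pink_sd=0.0, white_sd=0.0, c_jitter_sd_ms=0.0, pseudo_rt_sd_ms=0.0,
            amplitude_by_condition={CONGRUENT: (1.0, 1.0), INCONGRUENT: (1.0, 1.0)},
            pseudo_rt_mean_ms={CONGRUENT: 539.18, INCONGRUENT: 549.63})
        epochs, _ = rm.simulate_epochs(trials, tp, montage60, seed=0)
        result = rm.ride_decompose(epochs)
        assert np.ptp(result.c_latency_samples) <= 2
        recon = result.s_waveform + _shift_zero(
            result.c_waveform,
            int(np.median(result.c_latency_samples)) - result.ref_latency_sample)
        avg = epochs.data.mean(axis=0)
        inner = epochs.time_mask(-100.0, 700.0)
        scale = np.abs(avg).max()
        err = np.abs(recon[:, inner] - avg[:, inner]).max() / scale
        assert err < 0.1

    def test_self_consistency_on_own_model(self, decomposed):
        """Data resynthesized from the fitted model is reproduced."""
        epochs, _, result = decomposed
        lat = result.c_latency_samples
        data = np.stack([
            result.s_waveform + _shift_zero(result.c_waveform,
                                            int(li - result.ref_latency_sample))
            for li in lat
        ])
        synth = rm.Epochs(data=data, srate_hz=epochs.srate_hz,
                          times_ms=epochs.times_ms, montage=epochs.montage,
                          trials=epochs.trials)
        res2 = rm.ride_decompose(synth)
        r = np.corrcoef(res2.c_latency_samples, lat)[0, 1]
        assert r >= 0.95
        num = (res2.s_waveform * result.s_waveform).sum()
        den = np.linalg.norm(res2.s_waveform) * np.linalg.norm(result.s_waveform)
        assert num / den >= 0.98

    def test_median_more_robust_than_mean_to_outlier_trials(self, nogo_session):
        epochs, truth, = nogo_session
        rng = np.random.default_rng(9)
        dirty = epochs.copy()
        bad = rng.choice(epochs.n_trials, size=epochs.n_trials // 10, replace=False)
        dirty.data[bad] += 200.0 * rng.standard_normal(dirty.data[bad].shape)
        res_clean = rm.ride_decompose(epochs)
        res_dirty = rm.ride_decompose(dirty)
        d_median = np.abs(res_dirty.s_waveform - res_clean.s_waveform).max()
        d_mean = np.abs(dirty.data.mean(axis=0) - epochs.data.mean(axis=0)).max()
        assert d_median < d_mean

    def test_too_few_trials_rejected(self, small_epochs):
        few = rm.Epochs(data=small_epochs.data[:4], srate_hz=small_epochs.srate_hz,
                        times_ms=small_epochs.times_ms, montage=small_epochs.montage,
                        trials=small_epochs.trials.iloc[:4])
        with pytest.raises(ValueError):
            rm.ride_decompose(few, rm.RideConfig(
                s_window_ms=(-200.0, 300.0), c_window_ms=(100.0, 500.0)))


class TestSingleTrialClusters:
    def test_noiseless_exact_cancellation_given_true_model(self, montage60):
        """With a perfect decomposition, S-trials equal the pure S contribution."""
        from ridemvpa.task_sim import CONGRUENT, INCONGRUENT, _half_cycle
        design = rm.TaskDesign(n_trials=32, go_proportion=0.5, n_blocks=2)
        trials = rm.generate_trial_table(design, seed=0)
        trials = rm.simulate_behaviour(trials, seed=0)
        tp = rm.TruthParams(
            srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0),
            pink_sd=0.0, white_sd=0.0,
            amplitude_by_condition={CONGRUENT: (1.0, 1.0), INCONGRUENT: (1.0, 1.0)})
        epochs, truth = rm.simulate_epochs(trials, tp, montage60, seed=0)
        times = epochs.times_ms
        # snap true latencies to the sample grid so the shift is exact
        lat = np.searchsorted(times, truth.c_latency_ms)
        ref = int(np.median(lat))
        result = rm.RideResult(
            s_waveform=tp.s_amp * np.outer(truth.s_topography, truth.s_waveform),
            c_waveform=tp.c_amp * np.outer(truth.c_topography,
                                           _half_cycle(times, times[ref], 200.0)),
            c_latency_samples=lat, ref_latency_sample=ref,
            s_latency_sample=int(np.searchsorted(times, 0.0)),
            n_iterations=1, converged=True, times_ms=times, srate_hz=250.0)
        # rebuild the data on the snapped latency grid for exact cancellation
        data = np.stack([
            result.s_waveform + _shift_zero(result.c_waveform, int(li - ref))
            for li in lat])
        snapped = rm.Epochs(data=data, srate_hz=250.0, times_ms=times,
                            montage=montage60, trials=trials)
        s_tr, c_tr = rm.single_trial_clusters(snapped, result)
        assert np.allclose(s_tr.data, result.s_waveform[None], atol=1e-10)
        assert np.allclose(
            c_tr.data,
            np.stack([_shift_zero(result.c_waveform, int(li - ref)) for li in lat]),
            atol=1e-10)

    def test_bookkeeping_identity(self, decomposed):
        epochs, _, result = decomposed
        s_tr, c_tr = rm.single_trial_clusters(epochs, result)
        # S-trial + C-trial - trial = trial - C_shift - S = residual identity
        lhs = s_tr.data + c_tr.data - epochs.data
        expect = epochs.data - np.stack([
            _shift_zero(result.c_waveform,
                        int(li - result.ref_latency_sample))
            for li in result.c_latency_samples
        ]) - result.s_waveform[None]
        assert np.allclose(lhs, expect, atol=1e-10)
        assert "c_shift_clipped" in s_tr.trials.columns

    def test_degenerate_c_gives_noise_c_trials(self, montage60):
        design = rm.TaskDesign(n_trials=16, go_proportion=0.5, n_blocks=2)
        trials = rm.generate_trial_table(design, seed=0)
        trials = rm.simulate_behaviour(trials, seed=0)
        tp = rm.TruthParams(srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0),
                            c_amp=0.0, pink_sd=0.0, white_sd=0.0)
        epochs, _ = rm.simulate_epochs(trials, tp, montage60, seed=0)
        result = rm.ride_decompose(epochs)
        s_tr, c_tr = rm.single_trial_clusters(epochs, result)
        inner = epochs.time_mask(-100.0, 500.0)
        assert np.abs(c_tr.data[:, :, inner]).max() < 1e-6 * np.abs(epochs.data).max() + 1e-9
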