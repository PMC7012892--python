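"""Baseline fitting, neuropil subtraction, deconvolution, response windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls
from scipy.signal import lfilter

import audiotactile as at
from audiotactile.processing import (EventTrace, ProcessingParams, _oasis_ar1,
                                     extract_responses, reconstruct)
from audiotactile.stimuli import StimulusEvent, StimulusSchedule

FR = 5.0
GAMMA = math.exp(-1.0 / (0.7 * FR))


def kernel_matrix(n: int, gamma: float = GAMMA) -> np.ndarray:
    return np.tril(gamma ** np.subtract.outer(np.arange(n), np.arange(n)))


class TestComputeDff:
    def test_constant_trace(self):
        F = np.full(600, 80.0)
        F0, dff = at.compute_dff(F, frame_rate=FR)
        np.testing.assert_allclose(F0, 80.0, rtol=1e-6)
        np.testing.assert_allclose(dff, 0.0, atol=1e-6)

    def test_dff_definition(self):
        F = np.full(600, 100.0)
        F[300] = 120.0
        _, dff = at.compute_dff(F, frame_rate=FR)
        assert dff[300] == pytest.approx(0.2, abs=0.01)

    def test_tracks_slow_drift_and_keeps_transients(self, rng):
        n = 3000
        t = np.arange(n) / FR
        drift_amp = 20.0
        drift = 100.0 + drift_amp * np.sin(2 * np.pi * t / 400.0)
        F = drift.copy()
        peaks = [300, 900, 1500, 2100, 2700]
        for p in peaks:  # sparse transients, tau 0.7 s
            k = np.arange(n - p)
            F[p:] += 30.0 * GAMMA ** k
        F0, dff = at.compute_dff(F, frame_rate=FR)
        rms = np.sqrt(np.mean((F0 - drift) ** 2))
        assert rms < 0.05 * drift_amp
        for p in peaks:
            true_peak = 30.0 / drift[p]
            assert dff[p] == pytest.approx(true_peak, rel=0.10)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            at.compute_dff(np.full(10, 50.0), frame_rate=FR)


class TestNeuropilSubtract:
    def test_constant_neuropil_is_identity(self, rng):
        F = rng.uniform(50, 150, 300)
        np.testing.assert_allclose(
            at.neuropil_subtract(F, np.full(300, 70.0), coef=1.0), F)

    def test_zero_coefficient_is_identity(self, rng):
        F = rng.uniform(50, 150, 300)
        Fnp = rng.uniform(50, 150, 300)
        np.testing.assert_allclose(at.neuropil_subtract(F, Fnp, coef=0.0), F)

    def test_removes_known_contamination(self, rng):
        n = 2000
        true_soma = 100 + lfilter([1.0], [1.0, -GAMMA],
                                  (rng.random(n) < 0.05) * 20.0)
        shared = 10 * np.sin(2 * np.pi * np.arange(n) / 50.0) \
            + rng.standard_normal(n)
        soma_obs = true_soma + 0.7 * (shared - shared.mean())
        corrected = at.neuropil_subtract(soma_obs, 100 + shared, coef=0.7)
        r_raw = np.corrcoef(soma_obs, true_soma)[0, 1]
        r_cor = np.corrcoef(corrected, true_soma)[0, 1]
        assert r_cor > r_raw

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal shape"):
            at.neuropil_subtract(np.ones(10), np.ones(11))


class TestDeconvolve:
    def test_zero_in_zero_out(self):
        ev = at.deconvolve(np.zeros(100), frame_rate=FR)
        assert np.all(ev.rates == 0)

    def test_single_kernel_recovered(self):
        n = 50
        dff = np.zeros(n)
        dff[10:] = GAMMA ** np.arange(n - 10)
        ev = at.deconvolve(dff, ProcessingParams(event_threshold=0.0), FR)
        s = ev.rates[0]
        assert s[10] == pytest.approx(1.0, abs=1e-6)
        mask = np.ones(n, bool)
        mask[10] = False
        assert np.all(s[mask] < 1e-6)

    def test_two_kernels_recovered(self):
        n = 50
        dff = np.zeros(n)
        dff[5:] += 0.8 * GAMMA ** np.arange(n - 5)
        dff[20:] += 1.5 * GAMMA ** np.arange(n - 20)
        ev = at.deconvolve(dff, ProcessingParams(event_threshold=0.0), FR)
        s = ev.rates[0]
        big = np.flatnonzero(s > 0.1)
        assert set(big) <= {4, 5, 6, 19, 20, 21}
        assert s[5] == pytest.approx(0.8, abs=1e-6)
        assert s[20] == pytest.approx(1.5, abs=1e-6)

    def test_matches_nnls_oracle_on_random_instances(self, rng):
        # brute-force nonnegative least squares on 30-frame instances
        K = kernel_matrix(30)
        for _ in range(100):
            s_true = np.zeros(30)
            idx = rng.choice(30, size=rng.integers(0, 4), replace=False)
            s_true[idx] = rng.uniform(0.2, 2.0, size=len(idx))
            y = K @ s_true
            expected, _ = nnls(K, y)
            got = _oasis_ar1(y, GAMMA)
            np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_reconstruction_error_on_noiseless_input(self, rng):
        K = kernel_matrix(100)
        s_true = np.zeros(100)
        s_true[rng.choice(100, 5, replace=False)] = rng.uniform(0.5, 2, 5)
        y = K @ s_true
        ev = at.deconvolve(y, ProcessingParams(event_threshold=0.0), FR)
        recon = reconstruct(ev, tau=0.7)[0]
        assert np.sqrt(np.mean((recon - y) ** 2)) < 1e-4

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scaling_equivariance(self, k):
        rng = np.random.default_rng(99)
        y = np.clip(rng.standard_normal(60) * 0.1, 0, None) \
            + lfilter([1.0], [1.0, -GAMMA], (rng.random(60) < 0.1) * 1.0)
        p = ProcessingParams(event_threshold=0.0)
        s1 = at.deconvolve(y, p, FR).rates[0]
        sk = at.deconvolve(k * y, p, FR).rates[0]
        np.testing.assert_allclose(sk, k * s1, atol=1e-8 * max(1, k))

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError):
            ProcessingParams(decon_tau=0.0)


class TestExtractResponses:
    def _schedule(self, onsets, modality="tactile", freq=8.0):
        evs = [StimulusEvent(onset=o, modality=modality, tactile_freq=freq)
               for o in onsets]
        return StimulusSchedule(events=evs, block_labels=["b"] * len(evs))

    def test_single_event_window_arithmetic(self):
        # amplitude A averaged over the 3 in-window frames at 5 Hz, scaled
        # to events/s: A * 5 / 3
        rates = np.zeros((1, 100))
        rates[0, 51] = 0.9  # t = 10.2 s, inside [10, 10.6)
        ev = EventTrace(rates=rates, frame_rate=FR)
        rt = extract_responses(ev, self._schedule([10.0]))
        expected_baseline = 0.0
        assert rt.baseline_rate[0] == expected_baseline
        assert rt.values[0, 0] == pytest.approx(0.9 * FR / 3)

    def test_event_outside_window_ignored(self):
        rates = np.zeros((1, 100))
        rates[0, 55] = 1.0  # t = 11 s, 1 s after onset
        ev = EventTrace(rates=rates, frame_rate=FR)
        rt = extract_responses(ev, self._schedule([10.0]))
        # the stray event only raises the inter-stimulus baseline slightly
        assert rt.values[0, 0] == pytest.approx(-rt.baseline_rate[0])
        assert rt.baseline_rate[0] == pytest.approx(1.0 / 97 * FR)

    def test_zero_trace_zero_everything(self):
        ev = EventTrace(rates=np.zeros((2, 100)), frame_rate=FR)
        rt = extract_responses(ev, self._schedule([4.0, 8.0]))
        np.testing.assert_array_equal(rt.values, 0.0)

    def test_window_past_trace_end_flagged(self):
        ev = EventTrace(rates=np.zeros((1, 60)), frame_rate=FR)
        with pytest.warns(UserWarning, match="excluded"):
            rt = extract_responses(ev, self._schedule([4.0, 11.8]))
        assert list(rt.events["excluded"]) == [False, True]
        assert np.isnan(rt.values[0, 1])

    def test_baseline_correction_uses_interstimulus_frames(self):
        rates = np.full((1, 200), 0.2)  # uniform activity
        ev = EventTrace(rates=rates, frame_rate=FR)
        rt = extract_responses(ev, self._schedule([10.0, 20.0]))
        # in-window mean equals out-of-window mean -> corrected response 0
        np.testing.assert_allclose(rt.values, 0.0, atol=1e-12)
        assert rt.baseline_rate[0] == pytest.approx(0.2 * FR)


class TestEndToEndLinearity:
    def test_doubling_gain_doubles_responses(self):
        # averaged over repeats and seeds so Poisson sampling noise does not
        # mask the (approximately linear) amplitude scaling of the pipeline
        def mean_resp(gain, seed):
            tun = at.TuningParams(gain=gain, center=3.0, width=0.8,
                                  kind="gaussian")
            nrn = at.GroundTruthNeuron(cell_type="touch_low_btf",
                                       position=(100, 100), btf_true=8.0,
                                       tuning=tun,
                                       rsound=at.RsoundParams(floor=1, ceiling=1),
                                       baseline_rate=0.05, velocity_coef=0.0)
            pop = at.GroundTruthPopulation([nrn], (232, 232), 465.0)
            sched = at.make_stimulus_schedule(["tactile"], n_repeats=20, seed=5)
            quiet = at.NoiseParams(noise_sigma=0.1, np_sigma=0.1,
                                   drift_amp=0.0, npil_gain=0.0)
            sess = at.synthesize_session(pop, sched, quiet, seed=seed)
            proc = at.process_session(sess, ProcessingParams(event_threshold=0.0))
            _, mat = proc.responses.by_frequency(0, "tactile")
            return np.nanmean(mat)

        seeds = [31, 32, 33]
        r1 = np.mean([mean_resp(2.0, s) for s in seeds])
        r2 = np.mean([mean_resp(4.0, s) for s in seeds])
        assert r2 / r1 == pytest.approx(2.0, rel=0.15)
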