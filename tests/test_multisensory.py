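"""Sound-modulation statistics: dR, r_sound, modulation class, response ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audiotactile.multisensory import (_twoway_anova_balanced, btf_shift,
                                       classify_modulation,
                                       compare_consistency_fractions,
                                       consistency_fraction, delta_r,
                                       percent_inhibition, response_ratio,
                                       rsound_curve)
from audiotactile.stimuli import frequency_ladder
from audiotactile.tuning import TuningCurve


def make_curve(means, freqs=None, baseline=0.08):
    means = np.asarray(means, dtype=float)
    if freqs is None:
        freqs = frequency_ladder()[:len(means)]
    return TuningCurve(freqs=np.asarray(freqs, float), mean=means,
                       sem=np.zeros_like(means), n_repeats=6, baseline=baseline)


class TestDeltaR:
    def test_no_change_gives_zero(self):
        assert delta_r([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_complete_suppression(self):
        assert delta_r([1.0, 2.0], [0.0, 0.0]) == -1.0

    def test_half_suppression_arithmetic(self):
        assert delta_r([1.0, 1.0], [0.5, 0.5]) == pytest.approx(-1 / 3)

    def test_percent_convention(self):
        assert percent_inhibition(-0.43) == pytest.approx(43.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            delta_r([0.0, 0.0], [0.0, 0.0])

    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_and_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        dr = delta_r(a, b)
        assert -1.0 <= dr <= 1.0
        assert delta_r(b, a) == pytest.approx(-dr, abs=1e-12)

    @given(st.floats(0.1, 20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        a = np.array([1.0, 2.0, 0.5])
        b = np.array([0.3, 1.0, 0.2])
        assert delta_r(k * a, k * b) == pytest.approx(delta_r(a, b), rel=1e-9)

    def test_proportional_curves_forced_sign(self):
        # combined = c * tactile implies sign(dR) = sign(c - 1)
        t = np.array([1.0, 2.0, 3.0])
        assert delta_r(t, 0.5 * t) < 0
        assert delta_r(t, 2.0 * t) > 0
        assert delta_r(t, 1.0 * t) == 0


class TestClassifyModulation:
    def _trials(self, rng, scale_combined, n_freq=8, n_rep=6, gain=5.0,
                noise=0.5):
        freqs = frequency_ladder()[:n_freq]
        tune = gain * np.exp(-0.5 * ((np.log2(freqs) - 3) / 1.0) ** 2)
        t = tune[:, None] + rng.normal(0, noise, (n_freq, n_rep))
        c = scale_combined * tune[:, None] + rng.normal(0, noise, (n_freq, n_rep))
        return t, c

    def test_strong_suppression_detected(self, rng):
        hits = 0
        for _ in range(40):
            t, c = self._trials(rng, 0.2)
            cls, p = classify_modulation(t, c)
            hits += cls == "inhibited"
        assert hits >= 38  # >= 95% power at 5x suppression

    def test_facilitation_sign(self, rng):
        t, c = self._trials(rng, 2.0, noise=0.1)
        cls, _ = classify_modulation(t, c)
        assert cls == "facilitated"

    def test_null_type_one_error_rate(self, rng):
        false = 0
        n = 400
        for _ in range(n):
            t, c = self._trials(rng, 1.0)
            cls, _ = classify_modulation(t, c)
            false += cls != "no_change"
        # nominal 5%; allow 3 binomial sigma
        assert abs(false / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_anova_matches_statsmodels(self, rng):
        # closed-form balanced two-way ANOVA vs the OLS route
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        y = rng.normal(size=(5, 2, 4)) + np.arange(5)[:, None, None] * 0.3
        y[:, 1] += 0.4
        f_mine, p_mine = _twoway_anova_balanced(y)
        rows = [{"y": y[i, j, k], "freq": i, "sound": j}
                for i in range(5) for j in range(2) for k in range(4)]
        df = pd.DataFrame(rows)
        fit = ols("y ~ C(freq) + C(sound) + C(freq):C(sound)", df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert f_mine == pytest.approx(tab.loc["C(sound)", "F"], rel=1e-9)
        assert p_mine == pytest.approx(tab.loc["C(sound)", "PR(>F)"], rel=1e-9)

    def test_too_few_levels_rejected(self, rng):
        with pytest.raises(ValueError, match="levels"):
            classify_modulation(rng.normal(size=(1, 4)), rng.normal(size=(1, 4)))
        with pytest.raises(ValueError, match="repeats"):
            classify_modulation(rng.normal(size=(3, 1)), rng.normal(size=(3, 1)))


class TestRsoundCurve:
    def test_identical_curves_give_unity_no_halfmax(self):
        t = make_curve(np.linspace(0.2, 1.0, 16))
        res = rsound_curve(t, t, baseline=0.08)
        np.testing.assert_allclose(res.values, 1.0, atol=1e-9)
        assert res.half_max_freq is None

    def test_combined_at_baseline_gives_zero(self):
        t = make_curve([0.5, 0.6, 0.7, 0.8])
        c = make_curve([0.08, 0.08, 0.08, 0.08])
        res = rsound_curve(t, c, baseline=0.08)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-9)

    def test_forced_arithmetic(self):
        # (0.33 - 0.08)/(0.58 - 0.08) = 0.5
        t = make_curve([0.58] * 4)
        c = make_curve([0.33] * 4)
        res = rsound_curve(t, c, baseline=0.08)
        np.testing.assert_allclose(res.values, 0.5, atol=1e-12)

    def test_half_max_of_logistic_profile(self):
        freqs = frequency_ladder()
        t = make_curve(np.full(16, 1.0), freqs)
        from scipy.special import expit
        r_true = 0.1 + 0.7 * expit(2.0 * (np.log2(freqs) - np.log2(20.0)))
        c = make_curve(0.08 + (1.0 - 0.08) * r_true, freqs)
        res = rsound_curve(t, c, baseline=0.08)
        # generative crossing of 0.5 at ~22 Hz for this parameterization
        crossing = 2 ** (np.log2(20) + np.log(0.4 / 0.3) / 2.0 / np.log(2))
        assert res.half_max_freq == pytest.approx(crossing, rel=0.05)

    def test_insignificant_frequencies_excluded(self):
        t = make_curve([0.5, 0.9, 0.05, 0.9])
        c = make_curve([0.3, 0.5, 0.04, 0.5])
        sig = np.array([True, True, False, True])
        res = rsound_curve(t, c, baseline=0.08, per_freq_sig=sig)
        assert len(res.values) == 3  # third freq excluded (sig and < baseline)

    def test_no_valid_frequencies_flagged_empty(self):
        t = make_curve([0.01, 0.02, 0.03])
        res = rsound_curve(t, make_curve([0.0, 0.0, 0.0]), baseline=0.08)
        assert len(res.values) == 0 and res.half_max_freq is None


class TestBtfShift:
    def test_zero_and_one_octave(self):
        assert btf_shift(16.0, 16.0) == 0.0
        assert btf_shift(16.0, 32.0) == pytest.approx(1.0)

    def test_low_frequency_suppression_shifts_btf_up(self):
        # populations generated with low-frequency-selective suppression
        # show a positive mean BTF shift when sound is added
        import audiotactile as at
        from audiotactile.pipeline import analyze_session
        pop = at.sample_population({"touch_low_btf": 0.5, "touch_high_btf": 0.5},
                                   n_neurons=40, seed=41)
        sched = at.make_stimulus_schedule(["tactile", "combined"],
                                          n_repeats=6, seed=42)
        sess = at.synthesize_session(pop, sched, seed=43)
        res = analyze_session(sess, run_glm=False, run_spatial=False)
        shifts = res.neurons["btf_shift_oct"].dropna()
        assert len(shifts) >= 10
        assert shifts.mean() > 0


class TestResponseRatio:
    FREQS = frequency_ladder()

    def _trials(self, lo, hi):
        vals = np.where(self.FREQS <= 8.0, lo,
                        np.where(self.FREQS >= 76.0, hi, (lo + hi) / 2))
        return np.tile(vals[:, None], (1, 6))

    def test_equal_bands_give_zero(self):
        r = response_ratio(self.FREQS, self._trials(2.0, 2.0))
        assert r.response_ratio == 0.0

    def test_complete_high_band_suppression(self):
        r = response_ratio(self.FREQS, self._trials(3.0, 0.0))
        assert r.response_ratio == 1.0

    def test_forced_arithmetic(self):
        r = response_ratio(self.FREQS, self._trials(3.0, 1.0))
        assert r.response_ratio == pytest.approx(0.5)
        assert r.r_lo == 3.0 and r.r_hi == 1.0

    def test_sign_convention_flag(self):
        r = response_ratio(self.FREQS, self._trials(3.0, 1.0),
                           sign="hi_minus_lo")
        assert r.response_ratio == pytest.approx(-0.5)

    def test_suppression_significance(self, rng):
        trials = self._trials(3.0, 0.5) + rng.normal(0, 0.2, (16, 6))
        r = response_ratio(self.FREQS, trials)
        assert r.suppressed
        null = self._trials(2.0, 2.0) + rng.normal(0, 0.2, (16, 6))
        assert not response_ratio(self.FREQS, null).suppressed

    def test_cutoff_below_1p5x_baseline(self):
        # monotonically falling sound response crosses 1.5x baseline
        vals = np.interp(np.log2(self.FREQS), [1, 7], [3.0, 0.1])
        trials = np.tile(vals[:, None], (1, 6))
        r = response_ratio(self.FREQS, trials, baseline=0.5)
        assert r.cutoff_freq_1p5x is not None
        # profile 3.0 -> 0.1 linear in x = log2 f over [1, 7] crosses
        # 1.5 x 0.5 = 0.75 at x = 1 + 6 (3 - 0.75)/(3 - 0.1)
        x_cross = 1 + 6 * (3.0 - 0.75) / (3.0 - 0.1)
        assert np.log2(r.cutoff_freq_1p5x) == pytest.approx(x_cross, abs=0.25)

    def test_scale_invariance(self):
        a = response_ratio(self.FREQS, self._trials(3.0, 1.0))
        b = response_ratio(self.FREQS, 7.0 * self._trials(3.0, 1.0))
        assert a.response_ratio == pytest.approx(b.response_ratio)

    def test_zero_bands_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            response_ratio(self.FREQS, self._trials(0.0, 0.0))


class TestConsistency:
    def test_identical_and_discordant(self):
        a = ["inhibited", "no_change", "facilitated"]
        assert consistency_fraction(a, list(a))[0] == 1.0
        b = ["no_change", "facilitated", "inhibited"]
        assert consistency_fraction(a, b)[0] == 0.0

    def test_independent_labels_match_multinomial_oracle(self, rng):
        # marginals (0.5, 0.4, 0.1): expected agreement 0.42
        p = np.array([0.5, 0.4, 0.1])
        expected = float(np.sum(p ** 2))
        n, runs = 500, 200
        fracs = []
        for _ in range(runs):
            a = rng.choice(3, size=n, p=p)
            b = rng.choice(3, size=n, p=p)
            fracs.append(consistency_fraction(list(a), list(b))[0])
        se = np.std(fracs, ddof=1) / np.sqrt(runs)
        assert np.mean(fracs) == pytest.approx(expected, abs=3 * se)

    def test_proportion_tests(self):
        p = compare_consistency_fractions([(80, 100), (40, 100), (78, 100)])
        assert p[0, 1] < 0.001       # clearly different proportions
        assert p[0, 2] > 0.5         # close proportions
        np.testing.assert_allclose(p, p.T)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consistency_fraction([], [])
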