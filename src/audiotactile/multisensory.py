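"""Cross-modal modulation statistics.

Quantifies how concurrent sound changes tactile responses (modulation class
by two-way ANOVA, the aggregate response-change ratio dR, the per-frequency
sound-inhibition ratio r_sound with its half-maximum, and the BTF shift),
and how concurrent touch changes sound responses (the lo-vs-hi-band response
ratio of sound-selective neurons and the 1.5x-baseline cutoff frequency).

Sign conventions: dR = sum(R_TS - R_T) / sum(R_TS + R_T) is negative for
sound-driven inhibition; summaries report |dR| as a percentage with the
sign kept alongside. The response ratio (r_lo - r_hi)/(r_lo + r_hi) is
positive when high tactile frequencies suppress the sound response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .tuning import TuningCurve, smooth_fit

MOD_CLASSES = ("no_change", "inhibited", "facilitated")

LO_BAND_HZ = (2.0, 8.0)
HI_BAND_HZ = (76.0, 128.0)


# --- modulation class ------------------------------------------------------

def _twoway_anova_balanced(y: np.ndarray) -> tuple[float, float]:
    """Sound main-effect (F, p) of a balanced freq x sound x repeat design.

    ``y`` has shape (n_freq, 2, n_rep): axis 1 is sound absent/present.
    Closed-form balanced two-way ANOVA with interaction; equivalent to an
    OLS fit with both factors (checked against statsmodels in the tests).
    """
    nf, ns, nr = y.shape
    grand = y.mean()
    cell = y.mean(axis=2)
    a_means = y.mean(axis=(1, 2))   # frequency
    b_means = y.mean(axis=(0, 2))   # sound
    ss_b = nf * nr * np.sum((b_means - grand) ** 2)
    ss_err = np.sum((y - cell[:, :, None]) ** 2)
    df_b = ns - 1
    df_err = nf * ns * (nr - 1)
    if df_err <= 0 or ss_err <= 0:
        return np.nan, 1.0
    f = (ss_b / df_b) / (ss_err / df_err)
    return float(f), float(stats.f.sf(f, df_b, df_err))


def classify_modulation(tactile_trials: np.ndarray,
                        combined_trials: np.ndarray,
                        alpha: float = 0.05) -> tuple[str, float]:
    """Modulation class of one neuron from per-frequency repeat sets.

    Inputs are (n_freq, n_rep) matrices of baseline-corrected responses
    under tactile-alone and combined stimulation. The sound main effect of
    a two-way ANOVA (factors: tactile frequency, sound presence) decides
    no_change (p >= alpha) vs inhibited/facilitated (sign of the mean sound
    effect). Unbalanced rows with missing repeats are trimmed to the common
    repeat count with a warning.
    """
    t = np.asarray(tactile_trials, dtype=float)
    c = np.asarray(combined_trials, dtype=float)
    if t.shape[0] != c.shape[0]:
        raise ValueError("tactile and combined must share the frequency axis")
    if t.shape[0] < 2:
        raise ValueError("need >= 2 tactile frequency levels")

    def trim(m):
        rows = [row[np.isfinite(row)] for row in m]
        k = min(len(r) for r in rows)
        if k < 2:
            raise ValueError("need >= 2 repeats per cell")
        if any(len(r) > k for r in rows):
            warnings.warn("unbalanced design: repeats trimmed to the smallest "
                          "cell", stacklevel=3)
        return np.stack([r[:k] for r in rows])

    t, c = trim(t), trim(c)
    k = min(t.shape[1], c.shape[1])
    y = np.stack([t[:, :k], c[:, :k]], axis=1)  # (n_freq, 2, n_rep)
    _, p = _twoway_anova_balanced(y)
    if not np.isfinite(p) or p >= alpha:
        return "no_change", p
    effect = c.mean() - t.mean()
    return ("facilitated" if effect > 0 else "inhibited"), p


# --- dR --------------------------------------------------------------------

def delta_r(R_T: np.ndarray, R_TS: np.ndarray) -> float:
    """Aggregate response-change ratio sum(R_TS - R_T)/sum(R_TS + R_T).

    Summed over all tactile frequencies tested; -1 means complete
    suppression, +1 complete facilitation from zero.
    """
    R_T = np.asarray(R_T, dtype=float)
    R_TS = np.asarray(R_TS, dtype=float)
    if R_T.shape != R_TS.shape:
        raise ValueError("R_T and R_TS must have equal length")
    denom = np.sum(R_TS + R_T)
    if denom == 0:
        raise ValueError("delta_r undefined: responses sum to zero")
    return float(np.sum(R_TS - R_T) / denom)


def percent_inhibition(dr: float) -> float:
    """Magnitude convention for reporting: |dR| as a percentage."""
    return abs(dr) * 100.0


def btf_shift(btf_nosound: float, btf_sound: float) -> float:
    """Octave change in BTF when sound is added: log2(btf_sound/btf_nosound)."""
    return float(np.log2(btf_sound / btf_nosound))


# --- r_sound ---------------------------------------------------------------

@dataclass
class RsoundResult:
    freqs: np.ndarray          # valid frequencies only
    values: np.ndarray         # r_sound at valid frequencies
    fit_freqs: np.ndarray
    fit_values: np.ndarray
    fit_params: tuple          # (floor, ceiling, midpoint_log2hz, slope)
    half_max_freq: float | None


def _logistic(x, lo, hi, x0, k):
    return lo + (hi - lo) * expit(k * (x - x0))


def rsound_curve(tactile_curve: TuningCurve, combined_curve: TuningCurve,
                 baseline: float = 0.08,
                 per_freq_sig: np.ndarray | None = None,
                 n_grid: int = 100) -> RsoundResult:
    """Per-frequency sound-inhibition ratio and its monotone logistic fit.

    r_sound(f) = (combined(f) - b) / (tactile(f) - b) at frequencies with a
    significant tactile response and tactile(f) > b. The fitted curve is a
    monotone (non-decreasing) logistic in log2 frequency; the half-maximum
    is where the fit crosses 0.5, if it does within the tested range.
    """
    if not np.array_equal(tactile_curve.freqs, combined_curve.freqs):
        raise ValueError("curves must share the frequency ladder")
    freqs = tactile_curve.freqs
    if per_freq_sig is None:
        per_freq_sig = np.ones(len(freqs), dtype=bool)
    valid = per_freq_sig & (tactile_curve.mean > baseline)
    if not valid.any():
        return RsoundResult(freqs=np.array([]), values=np.array([]),
                            fit_freqs=np.array([]), fit_values=np.array([]),
                            fit_params=(), half_max_freq=None)
    f_valid = freqs[valid]
    r = (combined_curve.mean[valid] - baseline) / (tactile_curve.mean[valid] - baseline)
    r = np.clip(r, 0.0, None)

    x = np.log2(f_valid)
    grid = np.linspace(1.0, 7.0, n_grid)  # log2 of 2..128 Hz
    if len(x) >= 3 and np.ptp(r) > 1e-9:
        lo0 = float(np.clip(r.min(), 0.0, 1.0))
        hi0 = float(np.clip(r.max(), lo0 + 1e-3, 2.0))
        x00 = float(x[np.argmin(np.abs(r - (lo0 + hi0) / 2))])
        res = least_squares(
            lambda p: _logistic(x, *p) - r,
            x0=[lo0, hi0, x00, 2.0],
            bounds=([0.0, 0.0, 0.0, 0.05], [1.5, 2.5, 8.0, 10.0]))
        lo, hi, x0_, k = res.x
    else:
        lo = hi = float(np.mean(r))
        x0_, k = 4.0, 1.0
    fit_vals = _logistic(grid, lo, hi, x0_, k)

    half = None
    if lo < 0.5 < hi:
        q = (0.5 - lo) / (hi - lo)
        xh = x0_ + logit(q) / k
        if 1.0 <= xh <= 7.0:
            half = float(2.0 ** xh)
    return RsoundResult(freqs=f_valid, values=r, fit_freqs=2.0 ** grid,
                        fit_values=fit_vals,
                        fit_params=(float(lo), float(hi), float(x0_), float(k)),
                        half_max_freq=half)


# --- sound-selective neurons: suppression by touch --------------------------

@dataclass
class SoundNeuronModulation:
    response_ratio: float
    r_lo: float
    r_hi: float
    suppressed: bool
    p_suppression: float
    cutoff_freq_1p5x: float | None


def response_ratio(freqs: np.ndarray, combined_trials: np.ndarray,
                   baseline: float = 0.0,
                   lo_band: tuple[float, float] = LO_BAND_HZ,
                   hi_band: tuple[float, float] = HI_BAND_HZ,
                   sign: str = "lo_minus_hi",
                   alpha: float = 0.05) -> SoundNeuronModulation:
    """Touch-frequency suppression of a sound-selective neuron's response.

    ``combined_trials`` is (n_freq, n_rep) combined-stimulus responses.
    Band responses are baseline-subtracted means floored at 0; the ratio is
    (r_lo - r_hi)/(r_lo + r_hi) (positive = suppression by high tactile
    frequencies; ``sign='hi_minus_lo'`` flips the convention). Significant
    suppression is a one-tailed rank-sum of hi-band vs lo-band trials.
    The 1.5x-baseline cutoff is the lowest fitted frequency at which the
    combined response falls below 1.5x baseline (requires baseline > 0).
    """
    freqs = np.asarray(freqs, dtype=float)
    trials = np.asarray(combined_trials, dtype=float)
    lo_mask = (freqs >= lo_band[0]) & (freqs <= lo_band[1])
    hi_mask = (freqs >= hi_band[0]) & (freqs <= hi_band[1])
    if not lo_mask.any() or not hi_mask.any():
        raise ValueError("frequency bands must be nonempty")
    lo_trials = trials[lo_mask].ravel()
    hi_trials = trials[hi_mask].ravel()
    lo_trials = lo_trials[np.isfinite(lo_trials)]
    hi_trials = hi_trials[np.isfinite(hi_trials)]
    r_lo = max(float(np.mean(lo_trials)) - baseline, 0.0)
    r_hi = max(float(np.mean(hi_trials)) - baseline, 0.0)
    if r_lo + r_hi == 0:
        raise ValueError("response ratio undefined: both band responses zero")
    ratio = (r_lo - r_hi) / (r_lo + r_hi)
    if sign == "hi_minus_lo":
        ratio = -ratio
    elif sign != "lo_minus_hi":
        raise ValueError(f"unknown sign convention {sign!r}")
    p = stats.mannwhitneyu(hi_trials, lo_trials, alternative="less").pvalue \
        if len(lo_trials) and len(hi_trials) else 1.0
    suppressed = bool(ratio > 0 and p < alpha) if sign == "lo_minus_hi" \
        else bool(ratio < 0 and p < alpha)

    cutoff = None
    if baseline > 0 and len(freqs) >= 4:
        means = np.nanmean(trials, axis=1)
        curve = TuningCurve(freqs=freqs, mean=means,
                            sem=np.zeros_like(means), n_repeats=trials.shape[1],
                            baseline=baseline)
        gf, gv = smooth_fit(curve, monotone=False)
        below = gv < 1.5 * baseline
        if below.any():
            cutoff = float(gf[np.argmax(below)])
    return SoundNeuronModulation(response_ratio=float(ratio), r_lo=r_lo,
                                 r_hi=r_hi, suppressed=suppressed,
                                 p_suppression=float(p),
                                 cutoff_freq_1p5x=cutoff)


# --- consistency across stimulus types --------------------------------------

def consistency_fraction(classes_a: list[str], classes_b: list[str]
                         ) -> tuple[float, int, int]:
    """Fraction of neurons with the same modulation class under two stimulus
    types. Returns (fraction, n_same, n_total)."""
    if len(classes_a) != len(classes_b) or len(classes_a) == 0:
        raise ValueError("class vectors must be nonempty and aligned")
    same = sum(a == b for a, b in zip(classes_a, classes_b))
    return same / len(classes_a), same, len(classes_a)


def compare_consistency_fractions(counts: list[tuple[int, int]]) -> np.ndarray:
    """Pairwise chi-squared proportion tests between consistency fractions.

    ``counts`` holds (n_same, n_total) per condition pair; returns a
    symmetric matrix of p-values.
    """
    m = len(counts)
    p = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            k1, n1 = counts[i]
            k2, n2 = counts[j]
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if table.sum() == 0 or (table.sum(axis=0) == 0).any():
                continue
            p[i, j] = p[j, i] = stats.chi2_contingency(table, correction=False)[1]
    return p
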