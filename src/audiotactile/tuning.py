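"""Tactile frequency tuning curves and best-tactile-frequency (BTF) estimation.

The BTF combines two standard measures — the response-weighted mean frequency
over significant responses and the argmax frequency — averaged in the octave
(log2) domain, which matches the geometric spacing of the stimulus ladder.
Neurons with BTF <= 60 Hz are categorised as low-BTF, above 60 Hz as high-BTF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator, make_smoothing_spline

LOW_BTF_CUT_HZ = 60.0

NORMALIZATION_MODES = ("within_tactile", "tactile_vs_combined", "three_way")


@dataclass
class TuningCurve:
    """Normalized mean response per tactile frequency.

    ``mean`` is normalized so that the mode-appropriate maximum equals 1
    (within the tactile condition alone, across tactile and combined
    conditions, or across three conditions). ``baseline`` is the normalized
    spontaneous response level (population default 0.08).
    """

    freqs: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_repeats: int
    normalization_mode: str = "within_tactile"
    baseline: float = 0.08
    normalized: bool = True
    norm_value: float = 1.0    # divisor applied (events/s), for un-normalizing

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be ascending")
        if np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")


def tuning_curve(freqs: np.ndarray, responses: np.ndarray,
                 mode: str = "within_tactile",
                 other_max: float | list[float] | None = None,
                 baseline: float = 0.08) -> TuningCurve:
    """Average repeats per frequency and normalize to the relevant maximum.

    Parameters
    ----------
    responses
        (n_freq, n_repeats) baseline-corrected responses in events/s.
    mode
        'within_tactile' normalizes to this condition's own maximum;
        'tactile_vs_combined' and 'three_way' normalize to the maximum over
        this condition and the other conditions' maxima given in
        ``other_max``.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    responses = np.asarray(responses, dtype=float)
    means = np.nanmean(responses, axis=1)
    n_rep = responses.shape[1]
    sems = (np.nanstd(responses, axis=1, ddof=1) / np.sqrt(n_rep)
            if n_rep > 1 else np.zeros_like(means))
    candidates = [np.nanmax(means)]
    if mode != "within_tactile":
        if other_max is None:
            raise ValueError(f"mode {mode!r} requires other_max")
        candidates += list(np.atleast_1d(other_max).astype(float))
    norm = float(np.nanmax(candidates))
    if norm > 0:
        return TuningCurve(freqs=freqs, mean=means / norm, sem=sems / norm,
                           n_repeats=n_rep, normalization_mode=mode,
                           baseline=baseline, normalized=True, norm_value=norm)
    return TuningCurve(freqs=freqs, mean=np.zeros_like(means),
                       sem=np.zeros_like(means), n_repeats=n_rep,
                       normalization_mode=mode, baseline=baseline,
                       normalized=False, norm_value=1.0)


def per_freq_significance(responses: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """One-sample t-test (one-sided, response > 0) of repeats per frequency."""
    responses = np.asarray(responses, dtype=float)
    sig = np.zeros(responses.shape[0], dtype=bool)
    for i, row in enumerate(responses):
        row = row[np.isfinite(row)]
        if len(row) < 2 or np.allclose(row, row[0]):
            sig[i] = len(row) > 0 and row.mean() > 0 and not np.allclose(row, 0)
            continue
        t, p = stats.ttest_1samp(row, 0.0, alternative="greater")
        sig[i] = p < alpha
    return sig


@dataclass(frozen=True)
class BtfEstimate:
    btf: float
    measure_weighted: float
    measure_argmax: float
    category: str
    octave_gap: float

    def __post_init__(self):
        assert self.category in ("low", "high")


def btf_point_estimate(freqs: np.ndarray, means: np.ndarray,
                       significant: np.ndarray) -> BtfEstimate:
    """Two-measure BTF on a (possibly noiseless) curve of per-frequency means.

    measure 1: response-weighted mean of log2 frequency over significant
    responses (weights clipped at 0); measure 2: argmax frequency (ties to
    the lowest frequency); BTF = exp2 of the mean of the two log2 values.
    """
    freqs = np.asarray(freqs, dtype=float)
    means = np.asarray(means, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    logf = np.log2(freqs)
    argmax_f = float(freqs[int(np.argmax(means))])  # argmax ties -> lowest index
    w = np.clip(means, 0.0, None) * significant
    if w.sum() > 0:
        weighted = float(2.0 ** (np.sum(w * logf) / w.sum()))
    elif np.any(means > 0):
        weighted = argmax_f
    else:
        raise ValueError("BTF undefined: no significant frequencies and zero curve")
    btf = float(2.0 ** (0.5 * (np.log2(weighted) + np.log2(argmax_f))))
    return BtfEstimate(btf=btf, measure_weighted=weighted,
                       measure_argmax=argmax_f,
                       category="low" if btf <= LOW_BTF_CUT_HZ else "high",
                       octave_gap=abs(np.log2(weighted / argmax_f)))


def estimate_btf(curve: TuningCurve,
                 per_freq_sig: np.ndarray | None = None) -> BtfEstimate:
    """BTF of a tuning curve given per-frequency significance flags."""
    if per_freq_sig is None:
        per_freq_sig = curve.mean > 0
    return btf_point_estimate(curve.freqs, curve.mean, per_freq_sig)


def smooth_fit(curve: TuningCurve, n_grid: int = 100,
               monotone: bool = False,
               lam: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Smooth fit of a tuning curve on a dense log2-frequency grid.

    Default is a cubic smoothing spline in log2-frequency with GCV-selected
    smoothing; the monotone option fits a shape-constrained (isotonic +
    PCHIP) interpolant instead. Returns (grid_freqs_hz, fitted values).
    """
    x = np.log2(curve.freqs)
    y = curve.mean
    grid = np.linspace(np.log2(curve.freqs[0]), np.log2(curve.freqs[-1]), n_grid)
    if len(x) < 4:
        raise ValueError("smooth_fit needs >= 4 frequencies")
    if monotone:
        # pool-adjacent-violators then shape-preserving interpolation
        iso = _isotonic(y)
        fit = PchipInterpolator(x, iso)(grid)
    else:
        spl = make_smoothing_spline(x, y, lam=lam)
        fit = spl(grid)
    return 2.0 ** grid, fit


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Nondecreasing least-squares projection (PAV)."""
    y = np.asarray(y, dtype=float)
    sol = y.copy()
    w = np.ones_like(y)
    blocks = [[i] for i in range(len(y))]
    vals = list(sol)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i] += blocks[i + 1]
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty_like(y)
    for v, idx in zip(vals, blocks):
        out[idx] = v
    return out
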