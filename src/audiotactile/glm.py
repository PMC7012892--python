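"""Single-trial encoding model of responses vs stimulus and locomotion.

Each included trial (tactile alone, tactile+sound, sound alone, silent)
contributes a row with indicators for four log-spaced tactile frequency
channels, an indicator for sound presence, and the transformed running
velocity log2(6v + 1)/10 (0 at rest, 1 at the empirical 170.5 cm/s
ceiling). Responses are max-normalized to [0, 1] and fit with a logit link
(quasi-binomial variance); coefficients are z-scored by their standard
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .processing import ResponseTable
from .stimuli import frequency_ladder

GLM_MODALITIES = ("tactile", "combined", "auditory", "silent")
N_FREQ_BINS = 4
EPS_CLIP = 1e-3


def velocity_transform(v) -> np.ndarray:
    """log2(6v + 1)/10: maps running velocity (cm/s) onto [0, 1]."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be >= 0")
    out = np.log2(6.0 * v + 1.0) / 10.0
    return float(out) if out.ndim == 0 else out


def velocity_inverse(t) -> np.ndarray:
    """Inverse of the velocity transform: v = (2^(10 t) - 1)/6."""
    t = np.asarray(t, dtype=float)
    out = (2.0 ** (10.0 * t) - 1.0) / 6.0
    return float(out) if out.ndim == 0 else out


def frequency_bin(freq_hz: float, ladder: np.ndarray | None = None) -> int:
    """Index (0..3) of the frequency channel: consecutive ladder quartets."""
    if ladder is None:
        ladder = frequency_ladder()
    idx = int(np.argmin(np.abs(np.log2(ladder) - np.log2(freq_hz))))
    return idx * N_FREQ_BINS // len(ladder)


DESIGN_COLUMNS = ["const"] + [f"freq_bin{i}" for i in range(N_FREQ_BINS)] \
    + ["sound", "velocity_t"]


def build_design(responses: ResponseTable, velocity: np.ndarray,
                 ladder: np.ndarray | None = None,
                 trial_filter: np.ndarray | None = None
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and per-trial velocity covariate from a response table.

    The velocity covariate is the mean raw velocity over each trial's
    response window, transformed after averaging. Returns (X, trial_index)
    where trial_index maps design rows back to presentation columns.
    """
    ev = responses.events
    fr = responses.frame_rate
    n_frames = len(velocity)
    keep = ev["modality"].isin(GLM_MODALITIES) & ~ev["excluded"]
    if trial_filter is not None:
        keep &= pd.Series(trial_filter, index=ev.index)
    idx = np.flatnonzero(keep.to_numpy())
    rows = []
    for j in idx:
        onset = ev.iloc[j]["onset_s"]
        i0 = int(np.ceil(onset * fr - 1e-9))
        i1 = min(n_frames, int(np.ceil((onset + responses.window) * fr - 1e-9)))
        v = float(np.mean(velocity[i0:i1])) if i1 > i0 else 0.0
        modality = ev.iloc[j]["modality"]
        row = {"const": 1.0, "sound": 1.0 if modality in ("combined", "auditory") else 0.0,
               "velocity_t": velocity_transform(v)}
        for b in range(N_FREQ_BINS):
            row[f"freq_bin{b}"] = 0.0
        if modality in ("tactile", "combined"):
            row[f"freq_bin{frequency_bin(ev.iloc[j]['tactile_freq_hz'], ladder)}"] = 1.0
        rows.append(row)
    X = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return X, idx


@dataclass
class GlmFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    z_scores: pd.Series
    converged: bool
    n_trials: int
    deviance: float
    null_deviance: float
    flagged: str | None = None

    @property
    def z_sound(self) -> float:
        return float(self.z_scores["sound"])

    @property
    def z_velocity(self) -> float:
        return float(self.z_scores["velocity_t"])


def fit_glm_design(X: pd.DataFrame, y: np.ndarray) -> GlmFit:
    """Quasi-binomial logit fit of max-normalized responses on a design.

    Responses are shifted/scaled to [0, 1] by their maximum, clipped to
    [eps, 1-eps], and fit by IRLS with a logit link; the dispersion is
    estimated (Pearson chi2), giving quasi-binomial standard errors.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("response/design length mismatch")
    if len(y) < 20:
        raise ValueError("need >= 20 trials for the GLM")
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("responses must contain positive values")
    yn = np.clip(y / ymax, EPS_CLIP, 1.0 - EPS_CLIP)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    flagged = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(yn, X, family=sm.families.Binomial())
        res = model.fit(scale="X2")
    converged = bool(res.converged)
    if not converged:
        flagged = "non-convergence"
    elif np.any(res.bse > 1e3):
        flagged = "possible separation (huge standard errors)"
    null_dev = float(sm.GLM(yn, X[["const"]],
                            family=sm.families.Binomial()).fit().deviance)
    z = res.params / res.bse
    return GlmFit(coefficients=res.params, standard_errors=res.bse,
                  z_scores=z, converged=converged, n_trials=len(y),
                  deviance=float(res.deviance), null_deviance=null_dev,
                  flagged=flagged)


def fit_glm(responses: ResponseTable, neuron: int, velocity: np.ndarray,
            ladder: np.ndarray | None = None,
            trial_filter: np.ndarray | None = None) -> GlmFit:
    """Fit the encoding GLM for one neuron of a response table."""
    X, idx = build_design(responses, velocity, ladder, trial_filter)
    y = responses.values[neuron, idx]
    y = y - y.min() if y.min() < 0 else y  # shift: logit needs y in [0, 1]
    return fit_glm_design(X, y)


def simulate_glm_trials(coefs: dict[str, float], n_trials: int = 200,
                        seed: int = 0, noise_sd: float = 0.15
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate trials from known GLM coefficients for recovery testing.

    Trial types are drawn uniformly from the four included conditions;
    tactile trials get a random frequency bin, and the velocity covariate is
    drawn from a resting-skewed mixture. Responses are the logistic mean
    plus noise with binomial-type variance mu(1-mu) scaled by ``noise_sd``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for _ in range(n_trials):
        kind = rng.choice(GLM_MODALITIES)
        row = {"const": 1.0,
               "sound": 1.0 if kind in ("combined", "auditory") else 0.0,
               "velocity_t": 0.0}
        for b in range(N_FREQ_BINS):
            row[f"freq_bin{b}"] = 0.0
        if kind in ("tactile", "combined"):
            row[f"freq_bin{rng.integers(N_FREQ_BINS)}"] = 1.0
        if rng.random() < 0.4:  # running bout
            row["velocity_t"] = velocity_transform(rng.gamma(2.0, 10.0))
        rows.append(row)
    X = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    beta = np.array([coefs.get(c, 0.0) for c in DESIGN_COLUMNS])
    mu = expit(X.to_numpy() @ beta)
    y = mu + noise_sd * np.sqrt(mu * (1 - mu)) * rng.standard_normal(n_trials)
    return X, np.clip(y, 0.0, 1.0)
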