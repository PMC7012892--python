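"""Ground-truth population and session synthesis.

The generator inverts the analysis pipeline's assumptions: each neuron has a
known cell type, tactile tuning curve, sound-modulation curve and locomotion
coefficient; instantaneous event rates drive a Poisson process whose events
are convolved with a GCaMP6s-like exponential kernel (tau ~ 0.7 s), scaled
onto a baseline fluorescence with slow drift, mixed with a shared neuropil
signal, and corrupted with shot-like noise.

Cell types
----------
``touch_low_btf`` / ``touch_high_btf``
    Tactile-selective neurons. Low-BTF cells have biphasic (log2-Gaussian)
    tuning; high-BTF cells have monotonically saturating (sigmoid) tuning.
    Their tactile responses are suppressed by concurrent sound according to a
    logistic ``r_sound`` curve rising with tactile frequency (inhibition is
    strongest at low frequencies).
``sound_TI`` / ``sound_NTI``
    Sound-selective neurons; the TI (touch-inhibited) variant has its sound
    response suppressed by concurrent high-frequency tactile stimulation,
    the NTI variant does not.
``both``
    Responsive to touch alone and sound alone.
``unresponsive``
    Baseline firing only.

All randomness descends from a single seed through ``numpy``'s
``SeedSequence.spawn`` mechanism, so every synthetic artefact is
reproducible from (population seed, session seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import expit

from .session import Session
from .stimuli import StimulusSchedule, frequency_ladder
from .tuning import btf_point_estimate

CELL_TYPES = ("touch_low_btf", "touch_high_btf", "sound_TI", "sound_NTI",
              "both", "unresponsive")

#: Default cell-type mix, emulating secondary somatosensory cortex (S2):
#: ~9% tactile-responsive with high-BTF cells outnumbering low-BTF ~4:1,
#: ~1.2% sound-selective of which ~38% are touch-inhibited, ~0.3% dual.
DEFAULT_TYPE_FRACTIONS = {
    "touch_low_btf": 0.018,
    "touch_high_btf": 0.072,
    "sound_TI": 0.0045,
    "sound_NTI": 0.0075,
    "both": 0.003,
}

LOW_BTF_CUT_HZ = 60.0


@dataclass(frozen=True)
class TuningParams:
    """Tactile tuning curve in log2-frequency (x = log2 f)."""

    gain: float          # peak drive, events/s
    center: float        # log2 Hz: Gaussian mean or sigmoid midpoint
    width: float         # octaves: Gaussian sigma or 1/slope of sigmoid
    kind: str            # 'gaussian' (biphasic) or 'sigmoid' (monotone)

    def rate(self, freq_hz) -> np.ndarray:
        x = np.log2(np.asarray(freq_hz, dtype=float))
        if self.kind == "gaussian":
            return self.gain * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)
        if self.kind == "sigmoid":
            return self.gain * expit((x - self.center) / self.width)
        raise ValueError(f"unknown tuning kind {self.kind!r}")


@dataclass(frozen=True)
class RsoundParams:
    """Logistic sound-inhibition ratio in log2 tactile frequency.

    r_sound(f) is the fraction of the tactile response that survives
    concurrent sound; it rises from ``floor`` at low tactile frequencies to
    ``ceiling`` at high ones. ``half_max_hz`` is the frequency at which the
    curve crosses exactly 0.5 (when floor < 0.5 < ceiling), matching the
    half-maximum convention of the analysis side.
    """

    floor: float = 0.1
    ceiling: float = 0.8
    half_max_hz: float = 20.0
    slope: float = 2.0   # per octave

    def __post_init__(self):
        if self.floor > self.ceiling:
            raise ValueError("rsound floor must be <= ceiling")

    def _midpoint_log2(self) -> float:
        mid = math.log2(self.half_max_hz)
        if self.floor < 0.5 < self.ceiling:
            q = (0.5 - self.floor) / (self.ceiling - self.floor)
            mid -= math.log(q / (1 - q)) / self.slope
        return mid

    def value(self, freq_hz) -> np.ndarray:
        x = np.log2(np.asarray(freq_hz, dtype=float))
        mid = self._midpoint_log2()
        return self.floor + (self.ceiling - self.floor) * expit(self.slope * (x - mid))


@dataclass(frozen=True)
class GroundTruthNeuron:
    cell_type: str
    position: tuple[float, float]
    baseline_rate: float = 0.1
    velocity_coef: float = 0.0      # events/s at the transformed-velocity ceiling
    btf_true: float = float("nan")  # Hz, tactile types only
    tuning: TuningParams | None = None
    rsound: RsoundParams | None = None
    sound_gain: float = 0.0         # events/s, sound-selective / dual types
    touch_suppression_freq: float = float("nan")  # Hz, sound_TI only
    suppression_slope: float = 2.5  # per octave
    suppression_floor: float = 0.05

    def tactile_rate(self, freq_hz) -> np.ndarray:
        if self.tuning is None:
            return np.zeros_like(np.asarray(freq_hz, dtype=float))
        return self.tuning.rate(freq_hz)

    def sound_suppression(self, freq_hz) -> np.ndarray:
        """Fraction of the sound response surviving tactile frequency f."""
        f = np.asarray(freq_hz, dtype=float)
        if self.cell_type != "sound_TI" or not np.isfinite(self.touch_suppression_freq):
            return np.ones_like(f)
        x = np.log2(f)
        mid = math.log2(self.touch_suppression_freq)
        fall = expit(-self.suppression_slope * (x - mid))
        return self.suppression_floor + (1.0 - self.suppression_floor) * fall

    def stimulus_drive(self, modality: str, tactile_freq: float | None) -> float:
        """Added event rate (events/s) while a stimulus is on."""
        if modality == "tactile":
            return float(self.tactile_rate(tactile_freq)) if tactile_freq else 0.0
        if modality == "auditory":
            return self.sound_gain
        if modality == "combined":
            touch = float(self.tactile_rate(tactile_freq)) if tactile_freq else 0.0
            if self.rsound is not None and tactile_freq:
                touch *= float(self.rsound.value(tactile_freq))
            sound = self.sound_gain
            if tactile_freq:
                sound *= float(self.sound_suppression(tactile_freq))
            return touch + sound
        return 0.0  # visual, silent


@dataclass
class GroundTruthPopulation:
    neurons: list[GroundTruthNeuron]
    fov_center_true: tuple[float, float]
    fov_size: float
    type_fractions: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def coords(self) -> np.ndarray:
        return np.array([n.position for n in self.neurons], dtype=float).reshape(-1, 2)

    @property
    def cell_types(self) -> list[str]:
        return [n.cell_type for n in self.neurons]


# --- population sampling -------------------------------------------------

def _analytic_btf(tuning: TuningParams, freqs: np.ndarray) -> float:
    """BTF that the two-measure estimator returns on the noiseless curve."""
    means = tuning.rate(freqs)
    sig = means > 0.05 * means.max() if means.max() > 0 else means > 0
    return btf_point_estimate(freqs, means, sig).btf


def _solve_center(kind: str, width: float, btf_target: float,
                  freqs: np.ndarray) -> float:
    """Place the tuning-curve center so the noiseless BTF estimate hits target."""
    target = math.log2(btf_target)

    def err(center):
        t = TuningParams(gain=1.0, center=center, width=width, kind=kind)
        return math.log2(_analytic_btf(t, freqs)) - target

    lo, hi = -3.0, 12.0
    elo, ehi = err(lo), err(hi)
    if elo > 0:
        return lo
    if ehi < 0:
        return hi
    return brentq(err, lo, hi, xtol=1e-6)


@dataclass(frozen=True)
class PopulationParams:
    """Knobs of the generative population (defaults emulate S2)."""

    touch_gain: float = 5.0          # events/s at the tuning peak
    sound_gain: float = 5.0          # events/s for sound responses
    gain_jitter: float = 0.15        # lognormal sd (log-units)
    baseline_rate: float = 0.1       # events/s
    gauss_width_oct: float = 0.8
    sigmoid_width_oct: float = 0.4
    rsound: RsoundParams = RsoundParams()
    p_sound_modulated: float = 1.0   # fraction of touch cells with r_sound < 1
    touch_suppression_freq: float = 32.0
    cluster_sigma_um: float = 80.0   # spatial clustering of touch/sound_TI cells
    velocity_coef_sd: float = 0.5    # half-normal, events/s


def sample_population(type_fractions: dict[str, float] | None = None,
                      n_neurons: int = 200, fov_size: float = 465.0,
                      seed: int = 0,
                      params: PopulationParams = PopulationParams()
                      ) -> GroundTruthPopulation:
    """Draw a ground-truth population with multinomial type counts.

    Touch-selective and touch-inhibited sound cells cluster (Gaussian,
    ``params.cluster_sigma_um``) around the FOV center; non-touch-inhibited
    sound cells and unresponsive cells are uniform over the FOV.
    """
    if type_fractions is None:
        type_fractions = dict(DEFAULT_TYPE_FRACTIONS)
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    for k in type_fractions:
        if k not in CELL_TYPES:
            raise ValueError(f"unknown cell type {k!r}")
    fracs = {k: float(v) for k, v in type_fractions.items() if k != "unresponsive"}
    if any(v < 0 for v in fracs.values()):
        raise ValueError("fractions must be >= 0")
    total = sum(fracs.values())
    if total > 1 + 1e-9:
        raise ValueError(f"type fractions sum to {total} > 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    names = sorted(fracs)
    probs = [fracs[k] for k in names] + [max(0.0, 1.0 - total)]
    counts = rng.multinomial(n_neurons, np.array(probs) / np.sum(probs))
    ladder = frequency_ladder()
    low_freqs = ladder[ladder <= LOW_BTF_CUT_HZ]
    high_freqs = ladder[ladder > LOW_BTF_CUT_HZ]
    center = (fov_size / 2.0, fov_size / 2.0)

    def draw_position(clustered: bool) -> tuple[float, float]:
        if clustered:
            p = rng.normal(center, params.cluster_sigma_um, size=2)
            return tuple(np.clip(p, 0.0, fov_size))
        return tuple(rng.uniform(0.0, fov_size, size=2))

    def jitter(g: float) -> float:
        return g * math.exp(rng.normal(0.0, params.gain_jitter))

    neurons: list[GroundTruthNeuron] = []
    for name, count in zip(names + ["unresponsive"], counts):
        for _ in range(count):
            clustered = name in ("touch_low_btf", "touch_high_btf", "sound_TI", "both")
            pos = draw_position(clustered)
            vcoef = abs(rng.normal(0.0, params.velocity_coef_sd))
            base = dict(cell_type=name, position=pos,
                        baseline_rate=params.baseline_rate, velocity_coef=vcoef)
            if name in ("touch_low_btf", "touch_high_btf", "both"):
                if name == "touch_high_btf":
                    btf = float(rng.choice(high_freqs))
                    kind, width = "sigmoid", params.sigmoid_width_oct
                elif name == "touch_low_btf":
                    btf = float(rng.choice(low_freqs))
                    kind, width = "gaussian", params.gauss_width_oct
                else:  # 'both': any BTF, biphasic
                    btf = float(rng.choice(ladder))
                    kind, width = "gaussian", params.gauss_width_oct
                c = _solve_center(kind, width, btf, ladder)
                tun = TuningParams(gain=jitter(params.touch_gain), center=c,
                                   width=width, kind=kind)
                rs = params.rsound if rng.random() < params.p_sound_modulated \
                    else RsoundParams(floor=1.0, ceiling=1.0)
                base.update(btf_true=btf, tuning=tun, rsound=rs)
            if name in ("sound_TI", "sound_NTI", "both"):
                base.update(sound_gain=jitter(params.sound_gain))
            if name == "sound_TI":
                base.update(touch_suppression_freq=params.touch_suppression_freq)
            neurons.append(GroundTruthNeuron(**base))
    order = rng.permutation(len(neurons))
    neurons = [neurons[i] for i in order]
    return GroundTruthPopulation(neurons=neurons, fov_center_true=center,
                                 fov_size=fov_size,
                                 type_fractions=dict(type_fractions))


# --- running behaviour ----------------------------------------------------

V_MAX_CM_S = 170.5  # empirical treadmill ceiling assumed by the velocity transform


@dataclass(frozen=True)
class BoutParams:
    rest_mean_s: float = 20.0
    run_mean_s: float = 5.0
    min_bout_s: float = 1.0
    speed_mean: float = 15.0   # cm/s, per-bout target
    speed_sd: float = 5.0
    run_prob: float = 1.0      # probability a scheduled run bout occurs


def synthesize_running(duration: float, frame_rate: float = 5.0,
                       bout_params: BoutParams = BoutParams(),
                       seed: int = 0) -> np.ndarray:
    """Alternating rest/run bouts with smooth bout envelopes, capped at 170.5 cm/s."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    bp = bout_params
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(duration * frame_rate))
    v = np.zeros(n)
    t = rng.exponential(bp.rest_mean_s) + bp.min_bout_s
    while t < duration:
        run_len = rng.exponential(bp.run_mean_s) + bp.min_bout_s
        if rng.random() < bp.run_prob:
            speed = max(0.0, rng.normal(bp.speed_mean, bp.speed_sd))
            i0 = int(t * frame_rate)
            i1 = min(n, int((t + run_len) * frame_rate))
            v[i0:i1] = speed
        t += run_len + rng.exponential(bp.rest_mean_s) + bp.min_bout_s
    # smooth bout edges (~0.4 s) without inflating the peak speed
    if n > 3:
        kernel = np.array([0.25, 0.5, 0.25])
        v = np.convolve(v, kernel, mode="same")
    return np.clip(v, 0.0, V_MAX_CM_S)


# --- session synthesis ----------------------------------------------------

@dataclass(frozen=True)
class NoiseParams:
    """Fluorescence forward-model parameters (arbitrary units)."""

    f0: float = 100.0            # baseline fluorescence
    transient_amp: float = 0.2   # dF/F0 per unit event amplitude
    decay_tau: float = 0.7       # s, GCaMP6s-like decay
    noise_sigma: float = 1.0     # shot-like noise scale (a.u. at F = f0)
    np_sigma: float = 1.0        # neuropil channel noise
    drift_amp: float = 0.03      # fractional slow baseline drift
    drift_period_s: float = 600.0
    npil_mix: float = 0.7        # fraction of neuropil fluctuation leaking into soma
    npil_gain: float = 0.5       # neuropil response amplitude vs population drive
    npil_sigma_um: float = 150.0  # spatial footprint of the neuropil response

    def __post_init__(self):
        if min(self.f0, self.transient_amp, self.decay_tau) <= 0:
            raise ValueError("f0, transient_amp and decay_tau must be > 0")
        if min(self.noise_sigma, self.np_sigma, self.drift_amp, self.npil_mix,
               self.npil_gain) < 0:
            raise ValueError("noise parameters must be >= 0")


def _event_rate_matrix(population: GroundTruthPopulation,
                       schedule: StimulusSchedule, n_frames: int,
                       frame_rate: float, vt: np.ndarray) -> np.ndarray:
    """Instantaneous rate (events/s) per neuron and frame."""
    times = np.arange(n_frames) / frame_rate
    rates = np.empty((len(population), n_frames))
    for i, nrn in enumerate(population.neurons):
        rates[i] = nrn.baseline_rate + nrn.velocity_coef * vt
    for ev in schedule.events:
        on = (times >= ev.onset) & (times < ev.onset + ev.duration)
        if not on.any():
            continue
        for i, nrn in enumerate(population.neurons):
            d = nrn.stimulus_drive(ev.modality, ev.tactile_freq)
            if d:
                rates[i, on] += d
    return rates


def synthesize_session(population: GroundTruthPopulation,
                       schedule: StimulusSchedule,
                       noise_params: NoiseParams = NoiseParams(),
                       seed: int = 0, frame_rate: float = 5.0,
                       velocity: np.ndarray | None = None,
                       bout_params: BoutParams = BoutParams(),
                       tail_s: float = 4.0,
                       fov_id: str = "fov0") -> Session:
    """Forward-model a full session from a ground-truth population.

    rate -> Poisson events -> exponential-kernel calcium -> fluorescence with
    drifting baseline, shared spatially-weighted neuropil, and shot-like noise.
    """
    if not schedule.events:
        raise ValueError("schedule must contain at least one event")
    npar = noise_params
    ss = np.random.SeedSequence(seed)
    s_run, s_pois, s_noise = ss.spawn(3)
    duration = schedule.end_time + tail_s
    n_frames = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate

    if velocity is None:
        velocity = synthesize_running(duration, frame_rate, bout_params,
                                      seed=s_run.generate_state(1)[0] % (2**31))
    velocity = np.asarray(velocity, dtype=float)
    if velocity.shape != (n_frames,):
        raise ValueError(
            f"velocity length {velocity.shape} does not match session frames "
            f"({n_frames})")
    vt = np.log2(6.0 * velocity + 1.0) / 10.0

    rates = _event_rate_matrix(population, schedule, n_frames, frame_rate, vt)
    rng_p = np.random.default_rng(s_pois)
    rng_n = np.random.default_rng(s_noise)
    events = rng_p.poisson(rates * dt).astype(float)

    gamma = math.exp(-dt / npar.decay_tau)
    calcium = lfilter([1.0], [1.0, -gamma], events, axis=1)

    times = np.arange(n_frames) * dt
    n = len(population)
    phases = rng_n.uniform(0, 2 * np.pi, size=n)
    drift = 1.0 + npar.drift_amp * np.sin(
        2 * np.pi * times[None, :] / npar.drift_period_s + phases[:, None])

    # shared neuropil response: deterministic population tactile drive,
    # filtered by the calcium kernel, weighted by distance from the FOV center
    touch = [nr for nr in population.neurons if nr.tuning is not None]
    npil_rate = np.zeros(n_frames)
    if touch:
        for ev in schedule.events:
            if ev.tactile_freq is None:
                continue
            on = (times >= ev.onset) & (times < ev.onset + ev.duration)
            drive = np.mean([nr.stimulus_drive(ev.modality, ev.tactile_freq)
                             for nr in touch])
            npil_rate[on] += drive
    npil_c = lfilter([1.0], [1.0, -gamma], npil_rate * dt)
    coords = population.coords
    d2 = np.sum((coords - np.asarray(population.fov_center_true)) ** 2, axis=1)
    g = np.exp(-0.5 * d2 / npar.npil_sigma_um ** 2)
    npil_dff = npar.npil_gain * npar.transient_amp * np.outer(g, npil_c)

    neuropil_F = npar.f0 * (1.0 + npil_dff) * drift \
        + npar.np_sigma * rng_n.standard_normal((n, n_frames))
    neuropil_F = np.clip(neuropil_F, 0.0, None)

    soma_clean = npar.f0 * (1.0 + npar.transient_amp * calcium) * drift
    npil_fluct = neuropil_F - neuropil_F.mean(axis=1, keepdims=True)
    soma_F = soma_clean + npar.npil_mix * npil_fluct
    shot = npar.noise_sigma * np.sqrt(np.clip(soma_F, 1.0, None) / npar.f0)
    soma_F = soma_F + shot * rng_n.standard_normal((n, n_frames))
    soma_F = np.clip(soma_F, 0.0, None)

    return Session(soma_F=soma_F, neuropil_F=neuropil_F, frame_rate=frame_rate,
                   coords=coords, velocity=velocity, schedule=schedule,
                   fov_id=fov_id, ground_truth=population)
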