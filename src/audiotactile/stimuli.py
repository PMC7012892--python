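"""Stimulus schedules for auditory-tactile experiments.

A session is organised as interleaved *blocks*. A tactile (or combined
tactile+auditory) block presents each of the 16 log-spaced whisker-deflection
frequencies (2-128 Hz) exactly once in random order, with stimulus onsets
spaced 2 s apart and each stimulus lasting 500 ms. Auditory stimuli are
sinusoidal amplitude-modulated (SAM) tones described by a carrier frequency
(kHz), an envelope modulation frequency (Hz) and a speaker attenuation (dB).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("tactile", "auditory", "combined", "visual", "silent")

#: modalities that carry a tactile deflection frequency
TACTILE_MODALITIES = ("tactile", "combined")
#: modalities that carry a sound stimulus
SOUND_MODALITIES = ("auditory", "combined")


def frequency_ladder(n: int = 16, lo: float = 2.0, hi: float = 128.0) -> np.ndarray:
    """The geometric ladder of tactile frequencies, 2..128 Hz in 16 steps."""
    return np.geomspace(lo, hi, n)


def mean_angular_speed(freq_hz: float, amplitude_mm: float = 0.6,
                       distance_mm: float = 2.0) -> float:
    """Mean angular whisker-deflection speed (deg/s) of a sinusoidal stimulus.

    A piezo deflecting ``amplitude_mm`` at a needle ``distance_mm`` from the
    skin sweeps an angle of atan(amplitude/distance) per half cycle; each
    cycle contains one forward and one backward deflection, so the mean
    angular speed is ``atan(a/d) * freq * 2`` (in degrees).
    """
    return math.degrees(math.atan(amplitude_mm / distance_mm)) * freq_hz * 2.0


def angular_speed_coefficient(amplitude_mm: float = 0.6,
                              distance_mm: float = 2.0) -> float:
    """Degrees-per-second per Hz of tactile frequency (33.4 at defaults)."""
    return mean_angular_speed(1.0, amplitude_mm, distance_mm)


@dataclass(frozen=True)
class SoundParams:
    """A SAM tone: carrier (kHz), envelope modulation (Hz), attenuation (dB)."""

    carrier_khz: float = 7.8
    mod_freq_hz: float = 28.0
    attenuation_db: float = 20.0


@dataclass(frozen=True)
class StimulusEvent:
    onset: float
    modality: str
    duration: float = 0.5
    tactile_freq: float | None = None
    sound: SoundParams | None = None

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if (self.tactile_freq is not None) != (self.modality in TACTILE_MODALITIES):
            raise ValueError(
                f"tactile_freq must be present iff modality is tactile/combined "
                f"(got modality={self.modality!r}, tactile_freq={self.tactile_freq})")
        if (self.sound is not None) != (self.modality in SOUND_MODALITIES):
            raise ValueError(
                f"sound must be present iff modality is auditory/combined "
                f"(got modality={self.modality!r})")


@dataclass
class StimulusSchedule:
    events: list[StimulusEvent]
    block_labels: list[str]
    frequencies: np.ndarray = field(default_factory=frequency_ladder)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        onsets = np.array([e.onset for e in self.events])
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if len(self.block_labels) != len(self.events):
            raise ValueError("block_labels must match events")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def end_time(self) -> float:
        if not self.events:
            return 0.0
        return max(e.onset + e.duration for e in self.events)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per presentation), suitable for CSV."""
        rows = []
        for ev, blk in zip(self.events, self.block_labels):
            rows.append({
                "onset_s": ev.onset,
                "duration_s": ev.duration,
                "modality": ev.modality,
                "tactile_freq_hz": ev.tactile_freq if ev.tactile_freq is not None else np.nan,
                "carrier_khz": ev.sound.carrier_khz if ev.sound else np.nan,
                "mod_freq_hz": ev.sound.mod_freq_hz if ev.sound else np.nan,
                "attenuation_db": ev.sound.attenuation_db if ev.sound else np.nan,
                "block": blk,
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   frequencies: np.ndarray | None = None) -> "StimulusSchedule":
        events, labels = [], []
        for i, row in df.iterrows():
            modality = row["modality"]
            tf = row.get("tactile_freq_hz", np.nan)
            tf = None if pd.isna(tf) else float(tf)
            if modality in TACTILE_MODALITIES and tf is None:
                raise ValueError(
                    f"row {i}: tactile_freq_hz required for modality {modality!r}")
            sound = None
            if modality in SOUND_MODALITIES:
                if pd.isna(row.get("carrier_khz", np.nan)):
                    raise ValueError(f"row {i}: carrier_khz required for {modality!r}")
                sound = SoundParams(float(row["carrier_khz"]),
                                    float(row["mod_freq_hz"]),
                                    float(row["attenuation_db"]))
            events.append(StimulusEvent(onset=float(row["onset_s"]),
                                        duration=float(row["duration_s"]),
                                        modality=modality,
                                        tactile_freq=tf, sound=sound))
            labels.append(str(row.get("block", "")))
        if frequencies is None:
            tfs = sorted({e.tactile_freq for e in events if e.tactile_freq is not None})
            frequencies = np.array(tfs) if tfs else frequency_ladder()
        return cls(events=events, block_labels=labels, frequencies=frequencies)

    def save_csv(self, path) -> None:
        # %.17g round-trips float64 exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def load_csv(cls, path) -> "StimulusSchedule":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def shifted(self, offset: float, period: float) -> "StimulusSchedule":
        """Circularly shift all onsets by ``offset`` modulo ``period``.

        Used by the shuffle test; event order is re-sorted after wrapping.
        """
        new = [(float((e.onset + offset) % period), e, b)
               for e, b in zip(self.events, self.block_labels)]
        new.sort(key=lambda t: t[0])
        events = [dataclasses.replace(e, onset=t) for t, e, _ in new]
        labels = [b for _, _, b in new]
        return StimulusSchedule(events=events, block_labels=labels,
                                frequencies=self.frequencies)


def make_stimulus_schedule(block_specs: list[str], n_repeats: int = 1,
                           seed: int = 0, *,
                           sound: SoundParams = SoundParams(),
                           inter_onset: float = 2.0,
                           block_gap: float = 6.0,
                           start: float = 4.0,
                           events_per_block: int = 16,
                           frequencies: np.ndarray | None = None,
                           shuffle_blocks: bool = True) -> StimulusSchedule:
    """Build an interleaved block schedule.

    Each repeat cycle presents every condition in ``block_specs`` once, in a
    seeded-random order (blocks are interleaved across the session to spread
    habituation). Tactile and combined blocks contain all 16 ladder
    frequencies exactly once, shuffled; auditory/visual/silent blocks contain
    ``events_per_block`` identical presentations. Within-block onsets are
    spaced exactly ``inter_onset`` seconds.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    for cond in block_specs:
        if cond not in MODALITIES:
            raise ValueError(f"unknown condition label {cond!r}")
    freqs = frequency_ladder() if frequencies is None else np.asarray(frequencies, float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    events: list[StimulusEvent] = []
    labels: list[str] = []
    t = float(start)
    for rep in range(n_repeats):
        order = list(block_specs)
        if shuffle_blocks and len(order) > 1:
            order = [order[i] for i in rng.permutation(len(order))]
        for cond in order:
            label = f"{cond}_{rep}"
            if cond in TACTILE_MODALITIES:
                block_freqs = freqs[rng.permutation(len(freqs))]
                n_ev = len(block_freqs)
            else:
                block_freqs = [None] * events_per_block
                n_ev = events_per_block
            for k in range(n_ev):
                tf = block_freqs[k]
                events.append(StimulusEvent(
                    onset=t + k * inter_onset, modality=cond,
                    tactile_freq=float(tf) if tf is not None else None,
                    sound=sound if cond in SOUND_MODALITIES else None))
                labels.append(label)
            t = events[-1].onset + max(block_gap, inter_onset)
    return StimulusSchedule(events=events, block_labels=labels, frequencies=freqs)
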