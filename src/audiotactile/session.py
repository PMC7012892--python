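"""The in-memory container for one imaging session (one field of view)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import StimulusSchedule


@dataclass
class Session:
    """Somatic and neuropil fluorescence for one FOV, plus behaviour.

    Traces are neuron x frame arrays in arbitrary fluorescence units (>= 0);
    ``velocity`` is the treadmill running speed (cm/s) per frame; ``coords``
    are neuron centroid positions in micrometres within the FOV. Synthetic
    sessions carry their generative ``ground_truth``.
    """

    soma_F: np.ndarray
    neuropil_F: np.ndarray
    frame_rate: float
    coords: np.ndarray
    velocity: np.ndarray
    schedule: StimulusSchedule
    fov_id: str = "fov0"
    region_label: str = "S2"
    ground_truth: "object | None" = field(default=None, repr=False)

    def __post_init__(self):
        self.soma_F = np.asarray(self.soma_F, dtype=float)
        self.neuropil_F = np.asarray(self.neuropil_F, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        n, t = self.soma_F.shape
        if self.neuropil_F.shape != (n, t):
            raise ValueError("neuropil_F shape must match soma_F")
        if self.velocity.shape != (t,):
            raise ValueError("velocity length must match trace length")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_neurons, 2)")
        if np.any(self.soma_F < 0) or np.any(self.neuropil_F < 0):
            raise ValueError("fluorescence must be >= 0")
        if np.any(self.velocity < 0):
            raise ValueError("velocity must be >= 0")
        if self.schedule.events and self.duration < self.schedule.end_time:
            raise ValueError("session shorter than the last stimulus")

    @property
    def n_neurons(self) -> int:
        return self.soma_F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.soma_F.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate
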