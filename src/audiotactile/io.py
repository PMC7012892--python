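"""Persistence: sessions as HDF5, schedules as CSV, configs as YAML.

HDF5 layout (schema version 1): datasets ``soma_F``, ``neuropil_F``,
``velocity``, ``coords``; root attributes ``frame_rate``, ``fov_id``,
``region_label``, ``schema_version``; the stimulus schedule under the
``schedule`` group (one dataset per column) and, for synthetic sessions,
the ground-truth population as a JSON attribute.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .processing import ProcessingParams
from .responsiveness import ScoreParams
from .session import Session
from .stimuli import StimulusSchedule
from . import synthetic

SCHEMA_VERSION = 1
_SCHEDULE_COLS = ["onset_s", "duration_s", "modality", "tactile_freq_hz",
                  "carrier_khz", "mod_freq_hz", "attenuation_db", "block"]


def _ground_truth_to_json(pop: synthetic.GroundTruthPopulation) -> str:
    return json.dumps(dataclasses.asdict(pop))


def _ground_truth_from_json(text: str) -> synthetic.GroundTruthPopulation:
    d = json.loads(text)
    neurons = []
    for nd in d["neurons"]:
        if nd.get("tuning"):
            nd["tuning"] = synthetic.TuningParams(**nd["tuning"])
        if nd.get("rsound"):
            nd["rsound"] = synthetic.RsoundParams(**nd["rsound"])
        nd["position"] = tuple(nd["position"])
        neurons.append(synthetic.GroundTruthNeuron(**nd))
    return synthetic.GroundTruthPopulation(
        neurons=neurons, fov_center_true=tuple(d["fov_center_true"]),
        fov_size=d["fov_size"], type_fractions=d.get("type_fractions", {}))


def save_session(session: Session, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["frame_rate"] = session.frame_rate
        f.attrs["fov_id"] = session.fov_id
        f.attrs["region_label"] = session.region_label
        f.create_dataset("soma_F", data=session.soma_F)
        f.create_dataset("neuropil_F", data=session.neuropil_F)
        f.create_dataset("velocity", data=session.velocity)
        f.create_dataset("coords", data=session.coords)
        g = f.create_group("schedule")
        df = session.schedule.to_frame()
        for col in _SCHEDULE_COLS:
            data = df[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        g.create_dataset("frequencies", data=session.schedule.frequencies)
        if session.ground_truth is not None:
            f.attrs["ground_truth_json"] = _ground_truth_to_json(session.ground_truth)


def load_session(path) -> Session:
    with h5py.File(path, "r") as f:
        for name in ("soma_F", "neuropil_F", "velocity", "coords"):
            if name not in f:
                raise ValueError(f"session file missing dataset {name!r}")
        if "schedule" not in f:
            raise ValueError("session file missing the 'schedule' group")
        g = f["schedule"]
        cols = {}
        for col in _SCHEDULE_COLS:
            if col not in g:
                raise ValueError(f"schedule group missing column {col!r}")
            arr = g[col][()]
            if arr.dtype.kind == "S":
                arr = arr.astype(str)
            cols[col] = arr
        schedule = StimulusSchedule.from_frame(pd.DataFrame(cols),
                                               frequencies=g["frequencies"][()])
        gt = None
        if "ground_truth_json" in f.attrs:
            gt = _ground_truth_from_json(f.attrs["ground_truth_json"])
        soma = f["soma_F"][()]
        npil = f["neuropil_F"][()]
        vel = f["velocity"][()]
        if soma.shape[1] != len(vel):
            raise ValueError("frame-count mismatch between soma_F and velocity")
        return Session(soma_F=soma, neuropil_F=npil,
                       frame_rate=float(f.attrs["frame_rate"]),
                       coords=f["coords"][()], velocity=vel, schedule=schedule,
                       fov_id=str(f.attrs.get("fov_id", "fov0")),
                       region_label=str(f.attrs.get("region_label", "S2")),
                       ground_truth=gt)


def load_traces_csv(path, frame_rate: float, schedule: StimulusSchedule,
                    coords: np.ndarray | None = None) -> Session:
    """Legacy fallback: a CSV trace table with soma_<i>/neuropil_<i>/velocity
    columns imports into an equivalent Session."""
    df = pd.read_csv(path)
    soma_cols = sorted([c for c in df.columns if c.startswith("soma_")],
                       key=lambda c: int(c.split("_")[1]))
    np_cols = sorted([c for c in df.columns if c.startswith("neuropil_")],
                     key=lambda c: int(c.split("_")[1]))
    if not soma_cols or len(soma_cols) != len(np_cols):
        raise ValueError("trace CSV needs matching soma_<i>/neuropil_<i> columns")
    soma = df[soma_cols].to_numpy().T
    npil = df[np_cols].to_numpy().T
    vel = df["velocity"].to_numpy() if "velocity" in df else np.zeros(soma.shape[1])
    if coords is None:
        coords = np.zeros((soma.shape[0], 2))
    return Session(soma_F=soma, neuropil_F=npil, frame_rate=frame_rate,
                   coords=coords, velocity=vel, schedule=schedule)


# --- configuration ----------------------------------------------------------

@dataclass
class SimulateConfig:
    n_neurons: int = 50
    fov_size: float = 465.0
    type_fractions: dict | None = None
    blocks: list[str] = field(default_factory=lambda: ["tactile", "auditory", "combined"])
    n_repeats: int = 6
    frame_rate: float = 5.0


@dataclass
class PipelineConfig:
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    scoring: ScoreParams = field(default_factory=ScoreParams)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    run_glm: bool = True
    run_spatial: bool = True
    run_shuffle: bool = False
    n_shuffles: int = 100
    seed: int = 0
    out_dir: str = "results"
    baseline_norm: float = 0.08

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "processing" in d:
            d["processing"] = ProcessingParams(**d["processing"])
        if "scoring" in d:
            d["scoring"] = ScoreParams(**d["scoring"])
        if "simulate" in d:
            d["simulate"] = SimulateConfig(**d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        import hashlib
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
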