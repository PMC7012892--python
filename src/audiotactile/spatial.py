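"""Spatial organisation: strength maps, FOV registration, noise correlations.

Each FOV is registered by the peak of its soma-excluded neuropil tactile
response-strength map (disc-averaged area under the tuning curve, 100 um
radius, 10 um pixels). Neuron positions are then expressed relative to that
center, and the distance distributions of functional cell groups compared.
Pairwise correlations of spontaneous activity exclude frames near any
stimulus and neuron pairs closer than 15 um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .processing import EventTrace
from .stimuli import StimulusSchedule

MIN_PAIR_DIST_UM = 15.0
POST_STIM_PAD_S = 1.5


@dataclass
class StrengthMap:
    grid: np.ndarray           # (ny, nx) strength values
    pixel_size: float          # um
    origin: tuple[float, float]  # (x, y) of grid[0, 0]
    center: tuple[float, float]  # um, argmax of grid
    smoothing_radius: float = 100.0
    low_confidence: bool = False


def strength_map(coords: np.ndarray, strengths: np.ndarray,
                 fov_size: float = 465.0, pixel_size: float = 10.0,
                 radius: float = 100.0,
                 exclude: np.ndarray | None = None) -> StrengthMap:
    """Disc-averaged response-strength map over the FOV grid.

    ``strengths`` are area-under-tuning-curve values at the neuropil sites
    ``coords``; sites flagged in ``exclude`` (e.g. somata) are dropped.
    The map center is the argmax pixel (ties broken by smallest linear
    index; a flat map is flagged low-confidence).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    strengths = np.asarray(strengths, dtype=float)
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        coords, strengths = coords[keep], strengths[keep]
    if len(coords) == 0:
        raise ValueError("no sites available for the strength map")
    axis = np.arange(0.0, fov_size + pixel_size / 2, pixel_size)
    gx, gy = np.meshgrid(axis, axis)
    pixels = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(coords)
    grid = np.zeros(len(pixels))
    for i, nbrs in enumerate(tree.query_ball_point(pixels, r=radius)):
        if nbrs:
            grid[i] = max(float(np.mean(strengths[nbrs])), 0.0)
    grid = grid.reshape(gy.shape)
    flat_idx = int(np.argmax(grid))  # ties -> smallest linear index
    iy, ix = np.unravel_index(flat_idx, grid.shape)
    center = (float(axis[ix]), float(axis[iy]))
    low_conf = bool(np.allclose(grid, grid.flat[0]))
    return StrengthMap(grid=grid, pixel_size=pixel_size,
                       origin=(float(axis[0]), float(axis[0])), center=center,
                       smoothing_radius=radius, low_confidence=low_conf)


def tuning_curve_area(responses_by_freq: np.ndarray) -> float:
    """Total area under a per-frequency response curve (positive part)."""
    means = np.nanmean(np.asarray(responses_by_freq, float), axis=-1)
    return float(np.clip(means, 0.0, None).sum())


def register_and_distances(fovs: list[tuple[StrengthMap, np.ndarray, list[str]]]
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center each FOV's neurons on its strength-map peak and pool distances.

    ``fovs`` holds (map, coords, group labels) per FOV. Returns the pooled
    per-neuron table and per-group summaries (mean, SEM, n); weighting is
    by neuron, not by FOV.
    """
    if not fovs:
        raise ValueError("need at least one FOV")
    rows = []
    for k, (smap, coords, groups) in enumerate(fovs):
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        if len(coords) != len(groups):
            raise ValueError("coords and group labels must align")
        centered = coords - np.asarray(smap.center)
        dist = np.hypot(centered[:, 0], centered[:, 1])
        for i in range(len(coords)):
            rows.append({"fov": k, "neuron_id": i, "group": groups[i],
                         "x_centered": centered[i, 0],
                         "y_centered": centered[i, 1],
                         "distance": dist[i]})
    table = pd.DataFrame(rows)
    summaries = []
    for grp, sub in table.groupby("group"):
        d = sub["distance"].to_numpy()
        summaries.append({"group": grp, "n": len(d), "mean_distance": d.mean(),
                          "sem_distance": d.std(ddof=1) / np.sqrt(len(d))
                          if len(d) > 1 else np.nan})
    empty = {g for _, _, gl in fovs for g in gl} - set(table["group"])
    if empty:
        warnings.warn(f"groups with no neurons: {sorted(empty)}", stacklevel=2)
    return table, pd.DataFrame(summaries)


def tail_distribution(distances: np.ndarray, grid: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical complementary CDF of a distance sample."""
    d = np.sort(np.asarray(distances, dtype=float))
    if grid is None:
        grid = d
    ccdf = 1.0 - np.searchsorted(d, grid, side="right") / len(d)
    return grid, ccdf


def spontaneous_frames(schedule: StimulusSchedule, n_frames: int,
                       frame_rate: float,
                       pad: float = POST_STIM_PAD_S) -> np.ndarray:
    """Frames outside every [onset, onset + duration + pad) window."""
    times = np.arange(n_frames) / frame_rate
    mask = np.ones(n_frames, dtype=bool)
    for ev in schedule.events:
        mask &= ~((times >= ev.onset) & (times < ev.onset + ev.duration + pad))
    return mask


def spontaneous_correlations(events: EventTrace, schedule: StimulusSchedule,
                             coords: np.ndarray, groups: list[str],
                             min_dist: float = MIN_PAIR_DIST_UM,
                             pad: float = POST_STIM_PAD_S) -> pd.DataFrame:
    """Pairwise Pearson correlations of event traces during spontaneous frames.

    Pairs closer than ``min_dist`` are excluded; each pair is labelled by the
    sorted tuple of its two group labels.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = events.n_neurons
    if n < 2:
        raise ValueError("need >= 2 neurons")
    mask = spontaneous_frames(schedule, events.n_frames, events.frame_rate, pad)
    if not mask.any():
        raise ValueError("no spontaneous frames in this session")
    x = events.rates[:, mask]
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d < min_dist:
                continue
            c = corr[i, j] if sd[i] > 0 and sd[j] > 0 else np.nan
            rows.append({"i": i, "j": j, "distance": d,
                         "pair_type": "-".join(sorted((groups[i], groups[j]))),
                         "correlation": c})
    return pd.DataFrame(rows)


def compare_correlation_groups(pairs: pd.DataFrame) -> pd.DataFrame:
    """Unpaired t-tests of mean correlation between every pair-type group."""
    types = sorted(pairs["pair_type"].unique())
    rows = []
    for a in range(len(types)):
        for b in range(a + 1, len(types)):
            ca = pairs.loc[pairs["pair_type"] == types[a], "correlation"].dropna()
            cb = pairs.loc[pairs["pair_type"] == types[b], "correlation"].dropna()
            if len(ca) < 2 or len(cb) < 2:
                continue
            t, p = stats.ttest_ind(ca, cb, equal_var=False)
            rows.append({"group_a": types[a], "group_b": types[b],
                         "mean_a": ca.mean(), "mean_b": cb.mean(),
                         "t": t, "p": p})
    return pd.DataFrame(rows)
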