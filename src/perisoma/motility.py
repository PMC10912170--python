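"""Time-lapse motility of co-cultured microglia around a neuronal soma.

Distances are measured from the microglial centroid to the neuron soma
*boundary* (distance 0 means touching). Each inter-frame interval is
classed as moving towards the soma (+1, distance shrinks by more than
``epsilon``), immobile (0) or moving away (-1); the association index at a
time point is the sum of the classes across microglia.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "track_distances",
    "classify_movement",
    "classify_all",
    "association_index",
    "speed_by_radius_fold",
]

DEFAULT_EPSILON_UM = 1.0  # ~2x the simulator's centroid-localisation jitter


def track_distances(tracks: pd.DataFrame, geometry: dict) -> pd.DataFrame:
    """Add a ``distance`` column: centroid to soma boundary, um, >= 0."""
    cy, cx = geometry["center_um"][1], geometry["center_um"][0]
    r = geometry["radius_um"]
    out = tracks.copy()
    rho = np.hypot(out["x_um"] - cx, out["y_um"] - cy)
    out["distance"] = np.maximum(rho - r, 0.0)
    return out


def classify_movement(track: pd.DataFrame, epsilon: float = DEFAULT_EPSILON_UM) -> pd.DataFrame:
    """Per-interval movement classes for one track.

    The input needs ``t_min`` and ``distance`` columns and at least two
    frames with strictly increasing timestamps. Returns one row per
    interval: ``t_start, t_end, d_start, d_end, cls`` (+1 towards / 0 /
    -1 away) and the approach speed ``-dd/dt`` in um/min.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if len(track) < 2:
        raise ValueError("track needs >= 2 frames")
    t = track["t_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    d = track["distance"].to_numpy(dtype=float)
    dd = np.diff(d)
    cls = np.zeros(len(dd), dtype=int)
    cls[dd < -epsilon] = 1
    cls[dd > epsilon] = -1
    return pd.DataFrame(
        {
            "t_start": t[:-1],
            "t_end": t[1:],
            "d_start": d[:-1],
            "d_end": d[1:],
            "cls": cls,
            "approach_speed": -dd / np.diff(t),
        }
    )


def classify_all(
    tracks: pd.DataFrame, geometry: dict, epsilon: float = DEFAULT_EPSILON_UM
) -> pd.DataFrame:
    """Movement classes for every track in a long-format trajectory table."""
    with_d = track_distances(tracks, geometry)
    frames = []
    for mid, sub in with_d.groupby("microglia_id"):
        intervals = classify_movement(sub.sort_values("t_min"), epsilon)
        intervals.insert(0, "microglia_id", mid)
        frames.append(intervals)
    return pd.concat(frames, ignore_index=True)


def association_index(intervals: pd.DataFrame, t: float) -> int:
    """Sum of movement classes over microglia for the interval ending at ``t``.

    Bounded by [-N, +N] for N microglia. Tracks without an interval ending
    at ``t`` are excluded with a warning.
    """
    total = 0
    n_missing = 0
    for mid, sub in intervals.groupby("microglia_id"):
        match = sub[np.isclose(sub["t_end"], t)]
        if len(match) == 0:
            n_missing += 1
            continue
        total += int(match["cls"].iloc[0])
    if n_missing:
        warnings.warn(f"{n_missing} track(s) have no frame at t={t}; excluded", stacklevel=2)
    return total


def speed_by_radius_fold(
    intervals: pd.DataFrame,
    neuron_radius_um: float,
    fold_edges: list[float] | None = None,
) -> pd.Series:
    """Mean approach speed of towards-moving intervals, binned by starting
    distance in multiples of the neuronal soma radius.

    Only intervals classed +1 contribute. Empty bins are reported as NaN
    (missing), never 0.
    """
    if fold_edges is None:
        fold_edges = [0, 1, 2, 3, 4, 5]
    fold_edges = list(fold_edges)
    if len(fold_edges) < 2 or np.any(np.diff(fold_edges) <= 0):
        raise ValueError("fold_edges must be increasing with >= 2 edges")
    approach = intervals[intervals["cls"] == 1]
    labels = [f"[{a}, {b})" for a, b in zip(fold_edges[:-1], fold_edges[1:])]
    if len(approach) == 0:
        return pd.Series([np.nan] * len(labels), index=labels, name="mean_speed_um_per_min")
    folds = approach["d_start"] / neuron_radius_um
    binned = pd.cut(folds, bins=fold_edges, labels=labels, right=False)
    means = approach.groupby(binned, observed=False)["approach_speed"].mean()
    means.name = "mean_speed_um_per_min"
    return means.reindex(labels)
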