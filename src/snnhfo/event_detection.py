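"""From second-layer rasters to HFO events.

Marking rule: the recording is tiled into consecutive 15 ms windows
anchored at t = 0; a window containing at least one spike from any
(non-outlier) neuron is marked, and maximal runs of marked windows are
concatenated into one event whose boundaries are the run's window
boundaries. Events are half-open intervals [start, end).

Neurons that fire continuously (occupying more than half of all windows
by default) carry no information about events and are removed globally,
for the whole recording, before marking.

For scalp EEG, every spike of the artifact-detection network defines an
artifact interval of 15 ms starting at the spike; an event of interest
(EoI) that intersects any artifact interval is rejected, the rest are
accepted as HFO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HFOEvent",
    "suppress_outlier_neurons",
    "mark_events",
    "reject_artifacts",
    "events_frame",
]

DEFAULT_WINDOW_MS = 15.0
DEFAULT_OUTLIER_OCCUPANCY = 0.5


@dataclass
class HFOEvent:
    """A detected interval on one channel; status is EoI until artifact
    screening, then HFO or rejected_artifact."""

    channel: str
    start: float
    end: float
    n_contributing_spikes: int = 0
    status: str = "EoI"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


def suppress_outlier_neurons(
    neurons: np.ndarray,
    times: np.ndarray,
    duration: float,
    window_ms: float = DEFAULT_WINDOW_MS,
    max_occupancy: float = DEFAULT_OUTLIER_OCCUPANCY,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove continuously spiking neurons for the whole recording.

    A neuron whose spikes occupy more than ``max_occupancy`` of all
    ``window_ms`` windows of the recording is discarded globally (never
    per-segment). Returns (neurons, times, removed neuron ids).
    """
    neurons = np.asarray(neurons)
    times = np.asarray(times, dtype=float)
    if neurons.size == 0:
        return neurons, times, np.zeros(0, dtype=np.int64)
    w = window_ms * 1e-3
    n_windows = max(int(np.ceil(duration / w)), 1)
    removed = []
    for j in np.unique(neurons):
        occupied = np.unique((times[neurons == j] // w).astype(np.int64))
        if occupied.size > max_occupancy * n_windows:
            removed.append(j)
    removed = np.asarray(removed, dtype=np.int64)
    if removed.size:
        keep = ~np.isin(neurons, removed)
        neurons, times = neurons[keep], times[keep]
        if neurons.size == 0:
            warnings.warn("all neurons classified as outliers; raster is empty")
    return neurons, times, removed


def mark_events(
    times: np.ndarray,
    duration: float,
    window_ms: float = DEFAULT_WINDOW_MS,
    channel: str = "",
) -> list[HFOEvent]:
    """Tile, mark and concatenate: spike-containing 15 ms windows become
    events of interest with boundaries on the window grid."""
    times = np.asarray(times, dtype=float)
    w = window_ms * 1e-3
    n_windows = int(np.ceil(duration / w))
    if times.size == 0 or n_windows == 0:
        return []
    widx = (times // w).astype(np.int64)
    widx = widx[(widx >= 0) & (widx < n_windows)]
    if widx.size == 0:
        return []
    counts = np.bincount(widx, minlength=n_windows)
    marked = counts > 0
    # maximal runs of marked windows
    edges = np.diff(np.concatenate([[0], marked.astype(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        HFOEvent(
            channel=channel,
            start=s * w,
            end=min(e * w, duration) if e * w > duration else e * w,
            n_contributing_spikes=int(counts[s:e].sum()),
        )
        for s, e in zip(starts, ends)
    ]


def reject_artifacts(
    eoi: list[HFOEvent],
    artifact_times: np.ndarray,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> list[HFOEvent]:
    """Classify EoIs against artifact-network spikes.

    Each artifact spike at t defines an artifact interval [t, t+15 ms);
    an EoI intersecting any artifact interval becomes rejected_artifact,
    the others become HFO.
    """
    t_art = np.asarray(artifact_times, dtype=float)
    w = window_ms * 1e-3
    out = []
    for ev in eoi:
        hit = np.any((t_art < ev.end) & (t_art + w > ev.start)) if t_art.size \
            else False
        out.append(HFOEvent(ev.channel, ev.start, ev.end,
                            ev.n_contributing_spikes,
                            "rejected_artifact" if hit else "HFO"))
    return out


def events_frame(events: list[HFOEvent]) -> pd.DataFrame:
    """TSV-ready table: channel, start_s, end_s, status (+ spike count)."""
    return pd.DataFrame(
        [{"channel": e.channel, "start_s": e.start, "end_s": e.end,
          "status": e.status, "n_spikes": e.n_contributing_spikes}
         for e in events],
        columns=["channel", "start_s", "end_s", "status", "n_spikes"],
    )
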