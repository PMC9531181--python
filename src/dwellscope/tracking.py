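"""Linking detections into single-punctum traces and censoring them.

Surface-immobilized molecules are nearly stationary, so linking is a greedy
nearest-neighbour assignment within a small radius, tolerant of up to three
missing frames per trace (fluorophore blinking or a transiently failed fit).

Four exclusion rules then censor traces whose dwell time cannot be trusted:

1. boundary   — traces touching the first or last movie frame (the binding
                or unbinding time was not observed);
2. single_frame — traces confined to one frame (likely nonspecific sticking
                or a fluorescent impurity);
3. concurrent_proximity — both members of any concurrent pair of traces
                closer than 1 um (signals may be confounded);
4. repeated_site — all traces that share an x-y site at non-overlapping
                times (the uniqueness of the binding events is uncertain).

Each removal carries a machine-readable reason.  The dwell time of a kept
trace is the inclusive frame span times the frame interval; bridged gap
frames count toward the dwell by default (the punctum is deemed present
while dark).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import Detection

__all__ = [
    "TrackingParams",
    "Trace",
    "DwellSet",
    "link_traces",
    "filter_traces",
    "extract_dwells",
    "pool_dwells",
]


@dataclass(frozen=True)
class TrackingParams:
    link_radius_px: float = 2.0
    max_gap_frames: int = 3
    exclusion_radius_um: float = 1.0
    same_site_radius_px: float = 2.0

    def __post_init__(self) -> None:
        if self.link_radius_px <= 0 or self.exclusion_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.same_site_radius_px <= 0:
            raise ValueError("same_site_radius_px must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class Trace:
    """Time-ordered detections of one punctum."""

    trace_id: int
    detections: list[Detection] = field(default_factory=list)
    status: str = "open"
    reason: str | None = None

    @property
    def first_frame(self) -> int:
        return self.detections[0].frame

    @property
    def last_frame(self) -> int:
        return self.detections[-1].frame

    @property
    def dwell_frames(self) -> int:
        return self.last_frame - self.first_frame + 1

    @property
    def n_gaps_bridged(self) -> int:
        return self.dwell_frames - len(self.detections)

    @property
    def centroid_x_px(self) -> float:
        return float(np.mean([d.x_px for d in self.detections]))

    @property
    def centroid_y_px(self) -> float:
        return float(np.mean([d.y_px for d in self.detections]))


@dataclass
class DwellSet:
    """Pooled dwell times (seconds) with per-trace provenance."""

    dwell_s: np.ndarray
    table: pd.DataFrame  # columns: movie_id, trace_id, dwell_s

    def __len__(self) -> int:
        return len(self.dwell_s)


def link_traces(
    detections: list[Detection], params: TrackingParams, n_frames: int
) -> list[Trace]:
    """Greedy nearest-neighbour linking with gap tolerance.

    Detections must be sorted by frame.  A trace stays linkable through up to
    ``max_gap_frames`` consecutive missing frames; equidistant assignments are
    broken deterministically by (distance, trace id, detection index).  Every
    detection joins exactly one trace.
    """
    by_frame: dict[int, list[Detection]] = {}
    last_frame_seen = -1
    for d in detections:
        if d.frame < last_frame_seen:
            raise ValueError("detections must be sorted by frame")
        last_frame_seen = max(last_frame_seen, d.frame)
        by_frame.setdefault(d.frame, []).append(d)

    traces: list[Trace] = []
    open_traces: list[Trace] = []
    for f in range(n_frames):
        open_traces = [
            t for t in open_traces if f <= t.last_frame + params.max_gap_frames + 1
        ]
        dets_f = by_frame.get(f, [])
        if dets_f:
            pairs: list[tuple[float, int, int, int]] = []
            if open_traces:
                tx = np.array([t.detections[-1].x_px for t in open_traces])
                ty = np.array([t.detections[-1].y_px for t in open_traces])
                dx = np.array([d.x_px for d in dets_f])
                dy = np.array([d.y_px for d in dets_f])
                d2 = (tx[:, None] - dx[None, :]) ** 2 + (ty[:, None] - dy[None, :]) ** 2
                ti_idx, di_idx = np.nonzero(d2 <= params.link_radius_px**2)
                pairs = [
                    (float(np.sqrt(d2[ti, di])), open_traces[ti].trace_id, int(di), int(ti))
                    for ti, di in zip(ti_idx, di_idx)
                ]
            pairs.sort()
            used_traces: set[int] = set()
            used_dets: set[int] = set()
            for dist, _tid, di, ti in pairs:
                if ti in used_traces or di in used_dets:
                    continue
                used_traces.add(ti)
                used_dets.add(di)
                open_traces[ti].detections.append(dets_f[di])
            for di, d in enumerate(dets_f):
                if di not in used_dets:
                    tr = Trace(trace_id=len(traces), detections=[d])
                    traces.append(tr)
                    open_traces.append(tr)
    traces.sort(key=lambda t: (t.first_frame, t.trace_id))
    return traces


def filter_traces(
    traces: list[Trace],
    params: TrackingParams,
    n_frames: int,
    pixel_size_um: float,
) -> list[Trace]:
    """Apply the four exclusion rules; returns the same traces, status set.

    Each rule is evaluated against the full pre-filter trace set, so the kept
    set does not depend on rule order; the order only determines which reason
    a multiply-condemned trace records.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    excl_px = params.exclusion_radius_um / pixel_size_um
    n = len(traces)
    cx = np.array([t.centroid_x_px for t in traces])
    cy = np.array([t.centroid_y_px for t in traces])
    first = np.array([t.first_frame for t in traces])
    last = np.array([t.last_frame for t in traces])

    bad_boundary = (first == 0) | (last == n_frames - 1)
    bad_single = first == last
    if n > 1:
        d2 = (cx[:, None] - cx[None, :]) ** 2 + (cy[:, None] - cy[None, :]) ** 2
        np.fill_diagonal(d2, np.inf)
        overlap = (first[:, None] <= last[None, :]) & (first[None, :] <= last[:, None])
        bad_proximity = np.any(overlap & (d2 < excl_px**2), axis=1)
        bad_site = np.any(
            (~overlap) & (d2 <= params.same_site_radius_px**2), axis=1
        )
    else:
        bad_proximity = np.zeros(n, dtype=bool)
        bad_site = np.zeros(n, dtype=bool)

    for i, t in enumerate(traces):
        if bad_boundary[i]:
            t.status, t.reason = "removed", "boundary"
        elif bad_single[i]:
            t.status, t.reason = "removed", "single_frame"
        elif bad_proximity[i]:
            t.status, t.reason = "removed", "concurrent_proximity"
        elif bad_site[i]:
            t.status, t.reason = "removed", "repeated_site"
        else:
            t.status, t.reason = "kept", None
    return traces


def extract_dwells(
    traces: list[Trace],
    frame_interval_s: float,
    movie_id: str = "movie",
    include_gap_frames: bool = True,
) -> DwellSet:
    """Dwell times of kept traces, in seconds.

    ``include_gap_frames=True`` (default) counts bridged dark frames toward
    the dwell; with ``False`` only frames with an actual detection count.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    kept = [t for t in traces if t.status == "kept"]
    if not kept:
        warnings.warn("no kept traces; empty dwell set", stacklevel=2)
    rows = []
    for t in kept:
        frames = t.dwell_frames if include_gap_frames else len(t.detections)
        rows.append(
            {"movie_id": movie_id, "trace_id": t.trace_id, "dwell_s": frames * frame_interval_s}
        )
    table = pd.DataFrame(rows, columns=["movie_id", "trace_id", "dwell_s"])
    return DwellSet(dwell_s=table["dwell_s"].to_numpy(dtype=float), table=table)


def pool_dwells(dwell_sets: list[DwellSet]) -> DwellSet:
    """Concatenate dwell sets from multiple movies, keeping provenance."""
    if not dwell_sets:
        raise ValueError("nothing to pool")
    table = pd.concat([d.table for d in dwell_sets], ignore_index=True)
    return DwellSet(dwell_s=table["dwell_s"].to_numpy(dtype=float), table=table)


def traces_to_dataframe(traces: list[Trace]) -> pd.DataFrame:
    """Flatten traces into the traces CSV schema."""
    return pd.DataFrame(
        {
            "trace_id": [t.trace_id for t in traces],
            "first_frame": [t.first_frame for t in traces],
            "last_frame": [t.last_frame for t in traces],
            "centroid_x_px": [t.centroid_x_px for t in traces],
            "centroid_y_px": [t.centroid_y_px for t in traces],
            "n_gaps_bridged": [t.n_gaps_bridged for t in traces],
            "status": [t.status for t in traces],
            "reason": [t.reason for t in traces],
        }
    )
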