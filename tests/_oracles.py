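"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's
implementation paths: quantized-dwell expectations by numerical summation,
trace censoring by direct enumeration over the ground-truth event table, and
composition entropy via scipy.  These provide the reference answers the
pipeline is checked against.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def quantized_dwell_mean(tau_s: float, frame_interval_s: float, min_frames: int = 2,
                         k_max: int | None = None) -> float:
    """E[max(min_frames, ceil(T/dt)) * dt] for T ~ Exponential(tau), by summation."""
    dt = frame_interval_s
    if k_max is None:
        k_max = max(int(200 * tau_s / dt), 1000)
    total = 0.0
    for k in range(1, k_max + 1):
        p = math.exp(-(k - 1) * dt / tau_s) - math.exp(-k * dt / tau_s)
        total += max(min_frames, k) * dt * p
    # tail beyond k_max (negligible by construction)
    total += (k_max + tau_s / dt) * dt * math.exp(-k_max * dt / tau_s)
    return total


def entropy_bits(sequence: str) -> float:
    """Composition entropy in bits via scipy (independent of the package)."""
    _, counts = np.unique(list(sequence), return_counts=True)
    return float(stats.entropy(counts, base=2))


def visible_span(t_on: float, t_off: float, dt: float, n_frames: int):
    """First/last frame covered for at least half the frame, by direct scan."""
    first = last = None
    lo = max(0, int(t_on / dt) - 1)
    hi = min(n_frames, int(t_off / dt) + 2)
    for i in range(lo, hi):
        cover = min(t_off, (i + 1) * dt) - max(t_on, i * dt)
        if cover >= 0.5 * dt:
            if first is None:
                first = i
            last = i
    if first is None:
        return None
    return first, last


def brute_force_kept_events(
    truth,
    n_frames: int,
    frame_interval_s: float,
    pixel_size_um: float,
    exclusion_radius_um: float = 1.0,
    same_site_radius_px: float = 2.0,
):
    """Apply the four trace-exclusion rules directly to the ground truth.

    Returns the kept events as a list of (first_frame, last_frame, x_px, y_px)
    tuples.  Pure O(n^2) enumeration, no linking involved.
    """
    events = []
    for ev in truth:
        span = visible_span(ev.t_on_s, ev.t_off_s, frame_interval_s, n_frames)
        if span is not None:
            events.append((span[0], span[1], ev.x_px, ev.y_px))

    excl_px = exclusion_radius_um / pixel_size_um
    n = len(events)
    removed = [False] * n
    for i, (fi, li, xi, yi) in enumerate(events):
        if fi == 0 or li == n_frames - 1 or fi == li:
            removed[i] = True
    for i in range(n):
        fi, li, xi, yi = events[i]
        for j in range(i + 1, n):
            fj, lj, xj, yj = events[j]
            dist = math.hypot(xi - xj, yi - yj)
            overlap = fi <= lj and fj <= li
            if overlap and dist < excl_px:
                removed[i] = removed[j] = True
            if (not overlap) and dist <= same_site_radius_px:
                removed[i] = removed[j] = True
    return [ev for ev, r in zip(events, removed) if not r]
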