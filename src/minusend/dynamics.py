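"""Kymograph construction and dynamic-instability statistics.

A kymograph is a position-vs-time image resampled along a path through a
movie; microtubule end-position tracks digitized from kymographs are
segmented into growth/shrinkage/pause phases from sliding-window
velocities, from which the plus-end growth rate (mean ± s.d. over growth
events) and the catastrophe frequency (growth→shrinkage switches per
unit growth time, with relative standard error 1/sqrt(N_cat)) are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .simulate import Track

__all__ = [
    "Phase",
    "PhaseSegmentation",
    "make_kymograph",
    "segment_phases",
    "growth_rate",
    "catastrophe_frequency",
]


@dataclass
class Phase:
    """One contiguous phase of a track."""

    t_start: float
    t_end: float
    kind: str  # growth | shrink | pause
    velocity: float  # µm/min, least-squares slope over the phase

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class PhaseSegmentation:
    """Phases covering a track, with catastrophe bookkeeping.

    ``n_catastrophes`` counts growth→shrink transitions;
    ``total_growth_time`` sums growth-phase durations (pauses excluded,
    the per-growth-time convention for catastrophe frequency).
    """

    phases: list[Phase]
    n_catastrophes: int
    total_growth_time: float
    flagged: bool = False

    def __post_init__(self) -> None:
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.t_end - b.t_start) > 1e-9:
                raise ValueError("phases must be contiguous")
        recount = sum(1 for a, b in zip(self.phases, self.phases[1:])
                      if a.kind == "growth" and b.kind == "shrink")
        if recount != self.n_catastrophes:
            raise ValueError("n_catastrophes inconsistent with phases")


def make_kymograph(stack: np.ndarray,
                   path: Sequence[tuple[float, float]], width: int = 1,
                   projection: str = "max",
                   step_px: float = 1.0) -> np.ndarray:
    """Resample a movie along a polyline into a (time x arclength) image.

    ``path`` is a polyline of (x, y) pixel coordinates; at each frame the
    stack is sampled bilinearly at ``step_px`` arclength steps along the
    path, across a band of ``width`` pixels normal to it, and projected
    by maximum (default) or mean across the band.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if width < 1:
        raise ValueError("width must be >= 1")
    if projection not in ("max", "mean"):
        raise ValueError("projection must be 'max' or 'mean'")
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("path must have at least two vertices")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("degenerate (zero-length) path")

    # arclength-parameterized sample points and unit normals
    s_knots = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, total + step_px / 2, step_px)
    x = np.interp(s, s_knots, pts[:, 0])
    y = np.interp(s, s_knots, pts[:, 1])
    # tangent per sample from the segment it falls in
    idx = np.clip(np.searchsorted(s_knots, s, side="right") - 1, 0,
                  len(seg) - 1)
    tx = seg[idx, 0] / seg_len[idx]
    ty = seg[idx, 1] / seg_len[idx]
    nx, ny = -ty, tx

    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    # coordinates (band, sample): rows=y, cols=x for map_coordinates
    xs = x[None, :] + offsets[:, None] * nx[None, :]
    ys = y[None, :] + offsets[:, None] * ny[None, :]

    T = stack.shape[0]
    kymo = np.empty((T, s.size))
    coords = np.stack([ys.ravel(), xs.ravel()])
    for t in range(T):
        band = ndimage.map_coordinates(stack[t], coords, order=1,
                                       mode="nearest"
                                       ).reshape(width, s.size)
        kymo[t] = band.max(axis=0) if projection == "max" \
            else band.mean(axis=0)
    return kymo


def _pointwise_velocity(track: Track) -> np.ndarray:
    """Central-difference velocity per sample (µm/min), one-sided at the
    ends."""
    p, dt = track.positions, track.frame_interval
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) / (2.0 * dt)
    v[0] = (p[1] - p[0]) / dt
    v[-1] = (p[-1] - p[-2]) / dt
    return v * 60.0


def segment_phases(track: Track, v_threshold: float = 0.3,
                   min_phase_s: float | None = None) -> PhaseSegmentation:
    """Segment a track into growth/shrink/pause phases.

    Per-sample sliding-window (central-difference) velocities are
    classified by sign against ``v_threshold`` (µm/min): above it growth,
    below its negative shrinkage, otherwise pause.  Adjacent same-type
    runs are merged; runs shorter than ``min_phase_s`` (default 3 frames)
    are absorbed into the longer neighbouring run, iteratively.  Phase
    velocities are per-phase least-squares slopes.  A track shorter than
    ``min_phase_s`` yields a single flagged phase.
    """
    n = len(track)
    if n < 3:
        raise ValueError("track needs at least 3 points")
    dt = track.frame_interval
    if min_phase_s is None:
        min_phase_s = 3.0 * dt
    min_pts = max(int(round(min_phase_s / dt)), 1)

    v = _pointwise_velocity(track)
    kinds = np.where(v > v_threshold, 0,
                     np.where(v < -v_threshold, 1, 2))  # g, s, p

    # run-length encode
    runs: list[tuple[int, int, int]] = []  # (kind, start, stop_exclusive)
    start = 0
    for i in range(1, n + 1):
        if i == n or kinds[i] != kinds[start]:
            runs.append((int(kinds[start]), start, i))
            start = i

    flagged = False
    if (n - 1) * dt < min_phase_s:
        runs = [(int(np.bincount(kinds).argmax()), 0, n)]
        flagged = True
    else:
        # absorb short runs into the longer neighbour until stable
        changed = True
        while changed and len(runs) > 1:
            changed = False
            lengths = [r[2] - r[1] for r in runs]
            i = int(np.argmin(lengths))
            if lengths[i] < min_pts:
                left = runs[i - 1] if i > 0 else None
                right = runs[i + 1] if i < len(runs) - 1 else None
                if left is not None and (right is None or
                                         (left[2] - left[1])
                                         >= (right[2] - right[1])):
                    runs[i - 1] = (left[0], left[1], runs[i][2])
                else:
                    runs[i + 1] = (right[0], runs[i][1], right[2])
                del runs[i]
                # re-merge adjacent same-kind runs
                j = 0
                while j < len(runs) - 1:
                    if runs[j][0] == runs[j + 1][0]:
                        runs[j] = (runs[j][0], runs[j][1], runs[j + 1][2])
                        del runs[j + 1]
                    else:
                        j += 1
                changed = True

    names = {0: "growth", 1: "shrink", 2: "pause"}
    phases: list[Phase] = []
    t = track.times
    for kind, a, b in runs:
        # phase boundary midway between the adjoining samples
        t0 = t[a] if a == 0 else 0.5 * (t[a - 1] + t[a])
        t1 = t[b - 1] if b == n else 0.5 * (t[b - 1] + t[b])
        seg_t = t[a:b]
        seg_p = track.positions[a:b]
        if seg_t.size >= 2:
            slope = np.polyfit(seg_t, seg_p, 1)[0] * 60.0
        else:
            slope = v[a]
        phases.append(Phase(float(t0), float(t1), names[kind],
                            float(slope)))
    n_cat = sum(1 for a, b in zip(phases, phases[1:])
                if a.kind == "growth" and b.kind == "shrink")
    growth_time = sum(p.duration for p in phases if p.kind == "growth")
    return PhaseSegmentation(phases, n_cat, growth_time, flagged=flagged)


def growth_rate(segs: Sequence[PhaseSegmentation]
                ) -> tuple[float, float, int]:
    """Mean ± s.d. growth velocity (µm/min) over growth events, and the
    number of events."""
    vels = [p.velocity for s in segs for p in s.phases
            if p.kind == "growth"]
    if not vels:
        raise ValueError("no growth phases")
    v = np.asarray(vels)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd, v.size


def catastrophe_frequency(segs: Sequence[PhaseSegmentation]
                          ) -> tuple[float, float]:
    """Catastrophe frequency and its relative standard error.

    f = (pooled catastrophes) / (pooled growth time) in s^-1; the
    relative standard error is 1/sqrt(N_cat), from the Poisson count of
    observed switches.  With zero catastrophes f = 0 and the relative SE
    is undefined (NaN).
    """
    n_cat = sum(s.n_catastrophes for s in segs)
    growth_time = sum(s.total_growth_time for s in segs)
    if growth_time <= 0:
        raise ValueError("zero total growth time")
    if n_cat == 0:
        return 0.0, float("nan")
    return n_cat / growth_time, 1.0 / np.sqrt(n_cat)
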