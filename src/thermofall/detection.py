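"""Human-presence detection, iterative barycenter positioning and tracking.

A human shows up in the background-subtracted frame as a compact patch of
pixels ≥ 1 °C above background.  Detection marks, around every local
temperature maximum, the 5x5-neighborhood pixels that clear the threshold;
if the largest 8-connected marked area holds at least ``N_H`` pixels
(default 8) a human is declared present.

The hottest pixel is a biased position estimate (clothing, posture, noise),
so the position is refined by iterating the intensity-weighted centroid of
the 5x5 neighborhood around the current center until it stops moving.
Successive barycenters yield per-step moving distance, direction and speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocessing import ForegroundFrame

DEFAULT_THRESHOLD_C = 1.0
DEFAULT_N_H = 8
DEFAULT_NEIGHBORHOOD = 5
DEFAULT_TOL_PX = 0.5
DEFAULT_MAX_ITER = 20
DEFAULT_MAX_JUMP_PX = 8.0

_STRUCT_8CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionResult:
    detected: bool
    marked_mask: np.ndarray  # (24, 32) bool
    peak: tuple[int, int] | None  # hottest pixel of the decisive area
    marked_count: int  # pixel count of the largest marked area


@dataclass(frozen=True)
class Barycenter:
    coords: tuple[float, float]  # (row, col)
    iterations: int
    converged: bool


@dataclass
class Track:
    """Time-ordered barycenters with per-step kinematics."""

    barycenters: list[Barycenter] = field(default_factory=list)
    moving_distance: list[float] = field(default_factory=list)  # px, 0.0 first step
    direction: list[float] = field(default_factory=list)  # radians (atan2 drow,dcol)
    speed: list[float] = field(default_factory=list)  # px/s

    def __len__(self) -> int:
        return len(self.barycenters)


def _local_maxima_seeds(delta: np.ndarray, threshold_c: float, size: int) -> list[tuple[int, int]]:
    """Pixels that are 5x5-neighborhood maxima and clear the threshold.

    Ties inside a neighborhood are broken by row-major scan order: of
    equal-valued pixels sharing a window, only the earliest is a seed.
    """
    footprint_max = ndimage.maximum_filter(delta, size=size, mode="constant", cval=-np.inf)
    candidates = np.argwhere((delta >= threshold_c) & (delta == footprint_max))
    half = size // 2
    rows, cols = delta.shape
    seeds = []
    for r, c in candidates:
        r0, r1 = max(0, r - half), min(rows, r + half + 1)
        c0, c1 = max(0, c - half), min(cols, c + half + 1)
        window = delta[r0:r1, c0:c1]
        tied = np.argwhere(window == delta[r, c])
        first = tied[0]  # argwhere is row-major sorted
        if (r0 + first[0], c0 + first[1]) == (r, c):
            seeds.append((int(r), int(c)))
    return seeds


def detect_human(
    fg: ForegroundFrame,
    threshold_c: float = DEFAULT_THRESHOLD_C,
    N_H: int = DEFAULT_N_H,
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
    count_mode: str = "largest_area",
) -> DetectionResult:
    """Presence decision on one foreground frame.

    ``count_mode='largest_area'`` (default) applies the size test to the
    largest 8-connected marked area; ``'global'`` counts all marked pixels.
    """
    if count_mode not in ("largest_area", "global"):
        raise ValueError("count_mode must be 'largest_area' or 'global'")
    delta = fg.delta
    marked = np.zeros(delta.shape, dtype=bool)
    seeds = _local_maxima_seeds(delta, threshold_c, neighborhood)
    half = neighborhood // 2
    rows, cols = delta.shape
    for r, c in seeds:
        r0, r1 = max(0, r - half), min(rows, r + half + 1)
        c0, c1 = max(0, c - half), min(cols, c + half + 1)
        window = delta[r0:r1, c0:c1]
        marked[r0:r1, c0:c1] |= window >= threshold_c
    if not marked.any():
        return DetectionResult(False, marked, None, 0)

    if count_mode == "global":
        count = int(marked.sum())
        area_mask = marked
    else:
        labels, n = ndimage.label(marked, structure=_STRUCT_8CONN)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        area_mask = labels == best
        count = int(sizes[best - 1])

    detected = count >= N_H
    masked = np.where(area_mask, delta, -np.inf)
    peak = tuple(int(v) for v in np.unravel_index(np.argmax(masked), delta.shape))
    return DetectionResult(detected, marked, peak, count)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def refine_barycenter(
    fg: ForegroundFrame,
    start: tuple[int, int],
    neighborhood: int = DEFAULT_NEIGHBORHOOD,
    tol: float = DEFAULT_TOL_PX,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Barycenter:
    """Iterated intensity-weighted centroid around the current center.

    Each step recenters the ``neighborhood`` x ``neighborhood`` box on the
    (half-away-from-zero) rounded current estimate and takes the weighted
    centroid of the foreground values in the box; stops when the estimate
    moves less than ``tol`` pixels or after ``max_iter`` steps.
    """
    if neighborhood % 2 != 1 or neighborhood < 1:
        raise ValueError("neighborhood must be a positive odd integer")
    delta = fg.delta
    rows, cols = delta.shape
    r, c = float(start[0]), float(start[1])
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"start {start} outside the {rows}x{cols} grid")
    half = neighborhood // 2
    for it in range(1, max_iter + 1):
        ri, ci = _round_half_away(r), _round_half_away(c)
        r0, r1 = max(0, ri - half), min(rows, ri + half + 1)
        c0, c1 = max(0, ci - half), min(cols, ci + half + 1)
        window = delta[r0:r1, c0:c1]
        mass = window.sum()
        if mass <= 0:
            raise ValueError("no mass in neighborhood")
        rr, cc = np.mgrid[r0:r1, c0:c1]
        new_r = float((window * rr).sum() / mass)
        new_c = float((window * cc).sum() / mass)
        moved = math.hypot(new_r - r, new_c - c)
        r, c = new_r, new_c
        if moved < tol:
            return Barycenter((r, c), iterations=it, converged=True)
    return Barycenter((r, c), iterations=max_iter, converged=False)


def update_track(track: Track, b: Barycenter, frame_rate_hz: float = 15.0) -> Track:
    """Append a barycenter and derive step distance, direction and speed.

    Mutates and returns ``track``.  The first step has distance 0 and
    direction 0 by convention.
    """
    if track.barycenters:
        pr, pc = track.barycenters[-1].coords
        dr, dc = b.coords[0] - pr, b.coords[1] - pc
        dist = math.hypot(dr, dc)
        direction = math.atan2(dr, dc)
    else:
        dist, direction = 0.0, 0.0
    track.barycenters.append(b)
    track.moving_distance.append(dist)
    track.direction.append(direction)
    track.speed.append(dist * frame_rate_hz)
    return track


def associate(
    track: Track, candidates: list[Barycenter], max_jump_px: float = DEFAULT_MAX_JUMP_PX
) -> Barycenter | None:
    """Nearest-barycenter association with a max-jump gate.

    Returns the candidate closest to the track head, or None when all
    candidates exceed the gate (or the list is empty).  An empty track
    accepts the first candidate.
    """
    if not candidates:
        return None
    if not track.barycenters:
        return candidates[0]
    pr, pc = track.barycenters[-1].coords
    dists = [math.hypot(b.coords[0] - pr, b.coords[1] - pc) for b in candidates]
    i = int(np.argmin(dists))
    return candidates[i] if dists[i] <= max_jump_px else None
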