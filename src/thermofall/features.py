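"""The six per-frame features feeding the LSTM classifier.

Per frame of a window, for one tracked target:

1. moving distance — barycenter displacement from the previous frame (px);
2. area size — target mask pixel count;
3. area change rate — area divided by the previous frame's area;
4. highest temperature on the target (°C above background);
5. average temperature on the target;
6. directional distribution ratio — long/short axis ratio of the standard
   deviational ellipse of the target's pixel coordinates, an elongation
   signature that separates upright from lying postures.

A window of T frames yields a 6 x T feature matrix (row order as above).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .detection import Track
from .segmentation import TargetRegion

FEATURE_NAMES: tuple[str, ...] = (
    "moving_distance",
    "area_size",
    "area_change_rate",
    "max_temp",
    "mean_temp",
    "directional_ratio",
)

#: Collinear pixel sets have a zero minor axis; the ratio is capped to keep
#: the feature finite.
RATIO_CAP = 50.0


@dataclass
class FeatureMatrix:
    """6 x T feature matrix; column t derives from frame t of the window."""

    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(FEATURE_NAMES):
            raise ValueError(f"feature matrix must be {len(FEATURE_NAMES)} x T")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_table(self, path: str | Path) -> None:
        """Plain-text export: one row per feature, one column per frame."""
        with open(Path(path), "w") as fh:
            for name, row in zip(FEATURE_NAMES, self.values):
                fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def area_change_rate(area_n: int, area_prev: int) -> float:
    """Ratio of this frame's target area to the previous frame's.

    The first frame of a window has no predecessor, and a vanished target
    has zero area; both degenerate cases return 1.0 (no change).
    """
    if area_n < 0 or area_prev < 0:
        raise ValueError("areas must be non-negative")
    if area_prev == 0:
        return 1.0
    return area_n / area_prev


def directional_ratio(region: TargetRegion, weighted: bool = False) -> float:
    """Long/short axis ratio of the region's standard deviational ellipse.

    The axes are the square roots of the eigenvalues of the (optionally
    temperature-weighted) covariance of the pixel coordinates about their
    mean center.  A single pixel returns 1.0; a zero minor axis (collinear
    pixels) returns :data:`RATIO_CAP`.
    """
    coords = np.argwhere(region.mask).astype(np.float64)
    if coords.shape[0] == 0:
        raise ValueError("empty region")
    if coords.shape[0] == 1:
        return 1.0
    if weighted:
        w = region.sub_frame[region.mask].astype(np.float64)
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            w = np.ones(coords.shape[0])
    else:
        w = np.ones(coords.shape[0])
    center = (coords * w[:, None]).sum(axis=0) / w.sum()
    d = coords - center
    cov = (d * w[:, None]).T @ d / w.sum()
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    d_s, d_l = np.sqrt(np.maximum(eigvals, 0.0))
    if d_s <= 1e-12:
        return RATIO_CAP
    return min(float(d_l / d_s), RATIO_CAP)


def extract_features(
    regions: Sequence[TargetRegion | None],
    track: Track,
    weighted_ellipse: bool = False,
) -> FeatureMatrix:
    """Build the 6 x T matrix for one target over one window.

    ``regions[t]`` is the target's region in frame t (None when detection
    missed it); ``track`` holds the corresponding barycenters.  A missing
    frame carries the previous feature column forward; the number of gaps
    is recorded on the returned matrix as ``gap_count``.
    """
    T = len(regions)
    if T == 0:
        raise ValueError("empty window")
    if len(track) != T:
        raise ValueError(f"track length {len(track)} != window length {T}")
    values = np.zeros((len(FEATURE_NAMES), T))
    prev_area = 0
    prev_col: np.ndarray | None = None
    gaps = 0
    for t, region in enumerate(regions):
        if region is None or region.area == 0:
            if prev_col is not None:
                values[:, t] = prev_col
            else:  # window starts with a miss: all-neutral column
                values[:, t] = [0.0, 0.0, 1.0, 0.0, 0.0, 1.0]
            gaps += 1
            prev_col = values[:, t].copy()
            continue
        on_target = region.sub_frame[region.mask]
        area = region.area
        values[0, t] = track.moving_distance[t] if t > 0 else 0.0
        values[1, t] = area
        values[2, t] = area_change_rate(area, prev_area if t > 0 else 0)
        values[3, t] = float(on_target.max())
        values[4, t] = float(on_target.mean())
        values[5, t] = directional_ratio(region, weighted=weighted_ellipse)
        prev_area = area
        prev_col = values[:, t].copy()
    fm = FeatureMatrix(values)
    fm.gap_count = gaps  # type: ignore[attr-defined]
    return fm


def window_feature_matrix(fg_windows: np.ndarray, frame_rate_hz: float = 15.0,
                          weighted_ellipse: bool = False) -> FeatureMatrix:
    """Convenience: run segmentation + tracking + feature extraction on a
    ``(T, 24, 32)`` stack of foreground frames (°C above background) for the
    largest target per frame."""
    from .detection import Barycenter, detect_human, refine_barycenter, update_track
    from .preprocessing import ForegroundFrame
    from .segmentation import split_targets

    T = fg_windows.shape[0]
    regions: list[TargetRegion | None] = []
    track = Track()
    for t in range(T):
        fg = ForegroundFrame(delta=fg_windows[t], source_index=t)
        regs = split_targets(fg)
        if regs:
            region = max(regs, key=lambda r: r.area)
            regions.append(region)
            det = detect_human(fg)
            start = det.peak if det.peak is not None else tuple(
                int(v) for v in np.argwhere(region.mask)[0]
            )
            try:
                b = refine_barycenter(fg, start)
            except ValueError:
                rr, cc = np.argwhere(region.mask).mean(axis=0)
                b = Barycenter((float(rr), float(cc)), iterations=1, converged=True)
        else:
            regions.append(None)
            # hold position: repeat last barycenter (or grid center)
            if track.barycenters:
                b = track.barycenters[-1]
            else:
                b = Barycenter((fg_windows.shape[1] / 2, fg_windows.shape[2] / 2),
                               iterations=1, converged=True)
        update_track(track, b, frame_rate_hz=frame_rate_hz)
    return extract_features(regions, track, weighted_ellipse=weighted_ellipse)
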