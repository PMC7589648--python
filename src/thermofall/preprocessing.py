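"""Frame denoising and adaptive background subtraction.

Each raw frame is smoothed with the smallest normalized Gaussian kernel

    1/16  1/8  1/16
    1/8   1/4  1/8
    1/16  1/8  1/16

and a per-pixel background estimate is maintained as an exponential moving
average, ``BG_i = alpha * BG_{i-1} + (1 - alpha) * FG_i`` with ``alpha``
close to 1 (default 0.999).  The background is seeded with the mean of an
initial target-free stretch of frames; static warm clutter (monitors,
equipment) is absorbed into the background and vanishes from the
foreground.  At 15 Hz and alpha = 0.999 a newly stationary object migrates
into the background with a time constant of roughly 1/((1-alpha)*15) ≈ 67 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import GeometryError, ThermalFrame

#: Normalized 3x3 Gaussian kernel (sums to 1).
GAUSSIAN_KERNEL_3X3 = np.array(
    [
        [1 / 16, 1 / 8, 1 / 16],
        [1 / 8, 1 / 4, 1 / 8],
        [1 / 16, 1 / 8, 1 / 16],
    ]
)

#: scipy.ndimage border mode; replicate-edge avoids spurious cold borders on
#: a 24x32 grid.
DEFAULT_BORDER_MODE = "nearest"


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel exponential-moving-average background estimate.

    Attributes
    ----------
    bg
        ``(24, 32)`` background temperatures in °C.
    alpha
        EMA memory, strictly inside (0, 1).  Larger = slower adaptation.
    n_init
        Number of frames averaged to seed the model.
    """

    bg: np.ndarray
    alpha: float = 0.999
    n_init: int = 1

    def __post_init__(self) -> None:
        bg = np.asarray(self.bg, dtype=np.float64)
        if not np.all(np.isfinite(bg)):
            raise ValueError("background contains non-finite values")
        object.__setattr__(self, "bg", bg)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be strictly inside (0, 1)")
        if self.n_init < 1:
            raise ValueError("n_init must be positive")


@dataclass(frozen=True)
class ForegroundFrame:
    """°C above background for one frame (optionally floored at 0)."""

    delta: np.ndarray
    source_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=np.float64))


def gaussian_denoise(frame: ThermalFrame, border_mode: str = DEFAULT_BORDER_MODE) -> ThermalFrame:
    """Smooth a frame with the fixed 3x3 Gaussian kernel; shape unchanged."""
    smoothed = ndimage.convolve(frame.values, GAUSSIAN_KERNEL_3X3, mode=border_mode)
    return ThermalFrame(
        smoothed, index=frame.index, frame_rate_hz=frame.frame_rate_hz, shape=frame.shape
    )


def init_background(frames: Sequence[ThermalFrame], alpha: float = 0.999) -> BackgroundModel:
    """Seed the background with the per-pixel mean of target-free frames.

    Frames should already be denoised.  Averaging n frames of per-pixel
    noise sigma leaves residual noise sigma/sqrt(n) in the model.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame to initialize the background")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise GeometryError("initialization frames must share one shape")
    bg = np.mean([f.values for f in frames], axis=0)
    return BackgroundModel(bg=bg, alpha=alpha, n_init=len(frames))


def update_background(model: BackgroundModel, frame: ThermalFrame) -> BackgroundModel:
    """One EMA step: ``bg <- alpha * bg + (1 - alpha) * frame`` (pure)."""
    if frame.values.shape != model.bg.shape:
        raise GeometryError(
            f"frame shape {frame.values.shape} != background shape {model.bg.shape}"
        )
    new_bg = model.alpha * model.bg + (1.0 - model.alpha) * frame.values
    return BackgroundModel(bg=new_bg, alpha=model.alpha, n_init=model.n_init)


def subtract_background(
    model: BackgroundModel, frame: ThermalFrame, clip_negative: bool = True
) -> ForegroundFrame:
    """Foreground = frame − background, floored at 0 by default.

    Detection only reasons about positive excursions (a human is warmer
    than the room), so the floor is on unless a caller needs signed deltas.
    """
    if frame.values.shape != model.bg.shape:
        raise GeometryError(
            f"frame shape {frame.values.shape} != background shape {model.bg.shape}"
        )
    delta = frame.values - model.bg
    if clip_negative:
        delta = np.maximum(delta, 0.0)
    return ForegroundFrame(delta=delta, source_index=frame.index)


def run_preprocessing(
    frames: Sequence[ThermalFrame],
    n_init: int = 150,
    alpha: float = 0.999,
    clip_negative: bool = True,
    update_during_presence: bool = True,
) -> tuple[list[ForegroundFrame], BackgroundModel]:
    """Denoise a frame sequence, build the background from the first
    ``n_init`` frames, and emit foreground frames for the remainder.

    With ``update_during_presence`` (default) the EMA update runs on every
    frame, target present or not; alpha near 1 makes human transit
    negligible.  Disabling it freezes the model after initialization.
    """
    if len(frames) <= n_init:
        raise ValueError(
            f"need more than n_init={n_init} frames, got {len(frames)}"
        )
    denoised = [gaussian_denoise(f) for f in frames]
    model = init_background(denoised[:n_init], alpha=alpha)
    out: list[ForegroundFrame] = []
    for f in denoised[n_init:]:
        out.append(subtract_background(model, f, clip_negative=clip_negative))
        if update_during_presence:
            model = update_background(model, f)
    return out, model
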