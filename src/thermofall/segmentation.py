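"""Otsu binarization and connected-component target separation.

For multi-occupant scenes the foreground is quantized to 8-bit levels,
binarized at the Otsu threshold (the level maximizing between-class
variance), and split into 8-connected components.  Each sufficiently large
component becomes one target, copied into its own sub-frame whose
non-target pixels are set to the scene's lowest value, so that downstream
classification sees each person alone.  Touching occupants merge into a
single component — a documented failure mode of resolution this low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing import ForegroundFrame

#: Foreground temperatures are clipped to [0, CLIP_HIGH_C] °C before 8-bit
#: quantization: a human's internal temperature spread stays within ~5 °C.
CLIP_HIGH_C = 5.0

_STRUCTS = {8: np.ones((3, 3), dtype=bool), 4: ndimage.generate_binary_structure(2, 1)}


@dataclass(frozen=True)
class TargetRegion:
    """One segmented target.

    ``sub_frame`` equals the source frame on ``mask`` and the scene's
    minimum value elsewhere.
    """

    mask: np.ndarray  # (24, 32) bool, 8-connected
    sub_frame: np.ndarray  # (24, 32) float
    target_id: int

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def quantize_8bit(delta: np.ndarray, clip_high_c: float = CLIP_HIGH_C) -> np.ndarray:
    """Map foreground °C linearly onto integer levels 0..255 (clip at 0 and
    at ``clip_high_c``)."""
    scaled = np.clip(delta, 0.0, clip_high_c) * (255.0 / clip_high_c)
    return np.rint(scaled).astype(np.uint8)


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's threshold on 8-bit-quantized values.

    Returns the integer level ``t`` maximizing the between-class variance of
    the split ``{v <= t} / {v > t}``, by exhaustive search over all levels
    with both classes nonempty; ties take the lowest level.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    hist = np.bincount(values.astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than two distinct levels")
    levels = np.arange(hist.size, dtype=np.float64)
    w0 = np.cumsum(hist)
    total = w0[-1]
    m0 = np.cumsum(hist * levels)
    mean_all = m0[-1] / total
    w1 = total - w0
    # between-class variance for threshold t (class 0 = levels <= t)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    _ = mean_all  # kept for clarity of derivation
    return int(np.argmax(sigma_b))


def split_targets(
    fg: ForegroundFrame,
    min_pixels: int = 8,
    connectivity: int = 8,
    clip_high_c: float = CLIP_HIGH_C,
) -> list[TargetRegion]:
    """Binarize a foreground frame and split it into per-target sub-frames.

    Components smaller than ``min_pixels`` (default: the human-size
    threshold ``N_H``) are dropped.  An empty or degenerate scene yields an
    empty list.  Target ids are assigned in row-major order of each
    component's first pixel.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    delta = fg.delta
    q = quantize_8bit(delta, clip_high_c)
    try:
        t = otsu_threshold(q)
    except ValueError:
        return []  # flat scene: nothing to segment
    binary = q > t
    labels, n = ndimage.label(binary, structure=_STRUCTS[connectivity])
    fill = float(delta.min())
    regions: list[TargetRegion] = []
    tid = 0
    for k in range(1, n + 1):
        mask = labels == k
        if int(mask.sum()) < min_pixels:
            continue
        sub = np.where(mask, delta, fill)
        regions.append(TargetRegion(mask=mask, sub_frame=sub, target_id=tid))
        tid += 1
    return regions


def count_targets(fg: ForegroundFrame, **kwargs) -> int:
    """Number of distinct human-sized targets in a frame."""
    return len(split_targets(fg, **kwargs))
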