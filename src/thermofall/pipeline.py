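"""End-to-end glue: recordings -> foreground stacks -> classifier inputs.

The per-frame stages (denoise, background subtraction, detection,
segmentation, feature extraction) live in their own modules; this module
chains them over whole recordings and datasets, producing the arrays the
classifiers consume:

* raw path:      ``(n, T, 24, 32)`` normalized foreground windows (3D CNN);
* feature path:  ``(n, T, 6)`` feature sequences (LSTM).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .classifiers import normalize_window
from .features import window_feature_matrix
from .io import FrameWindow, MotionLabel, Recording, centered_window
from .preprocessing import (
    BackgroundModel,
    gaussian_denoise,
    init_background,
    subtract_background,
)
from .simulate import GroundTruth, SceneConfig, render_background_frames


def background_from_scene(
    scene: SceneConfig, n_init: int = 150, seed: int | None = None
) -> BackgroundModel:
    """Build a background model from a target-free rendering of the scene.

    Mirrors deployment, where the model is seeded from a stretch of frames
    recorded while the room is empty.
    """
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    frames = [gaussian_denoise(f) for f in render_background_frames(scene, n_init, rng)]
    return init_background(frames)


def recording_foreground(
    rec: Recording, model: BackgroundModel, clip_negative: bool = True
) -> np.ndarray:
    """Denoise and background-subtract a recording; ``(n, rows, cols)`` °C
    above background.  The model is held frozen (a 3-s recording moves the
    0.999-EMA background by well under the noise floor)."""
    out = np.empty((len(rec),) + model.bg.shape)
    for i, f in enumerate(rec.frames):
        fg = subtract_background(model, gaussian_denoise(f), clip_negative=clip_negative)
        out[i] = fg.delta
    return out


def _one_window(fg_stack: np.ndarray, T: int) -> np.ndarray:
    start = (fg_stack.shape[0] - T) // 2
    return fg_stack[start : start + T]


def _spatial_shift(window: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate every frame of a window by (dr, dc) pixels, zero-filled."""
    out = np.zeros_like(window)
    T, H, W = window.shape
    r0, r1 = max(dr, 0), min(H + dr, H)
    c0, c1 = max(dc, 0), min(W + dc, W)
    out[:, r0:r1, c0:c1] = window[:, r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def dataset_to_windows(
    dataset: Sequence[tuple[Recording, GroundTruth]],
    model: BackgroundModel,
    T: int = 15,
    train_offsets: Sequence[int] = (0,),
    augment_shift_px: int = 0,
    augment_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized foreground windows for the raw (3D CNN) path.

    One centered window per recording by default; ``train_offsets`` adds
    temporally shifted copies (offsets in frames relative to center), and a
    positive ``augment_shift_px`` applies a random spatial translation to
    each non-central copy — the raw-window classifier has no built-in
    translation invariance, so shifted copies stand in for repetitions
    performed at other places in the room.  Returns ``(X, y, groups)`` with
    ``y`` label strings and ``groups`` subject ids.
    """
    rng = np.random.default_rng(augment_seed)
    Xs, ys, gs = [], [], []
    for rec, _gt in dataset:
        fg = recording_foreground(rec, model)
        center = (fg.shape[0] - T) // 2
        for off in train_offsets:
            start = int(np.clip(center + off, 0, fg.shape[0] - T))
            vals = fg[start : start + T]
            if augment_shift_px > 0 and off != 0:
                dr, dc = rng.integers(-augment_shift_px, augment_shift_px + 1, 2)
                vals = _spatial_shift(vals, int(dr), int(dc))
            w = FrameWindow(vals, label=rec.label, units="delta_c")
            Xs.append(normalize_window(w).values)
            ys.append(str(rec.label))
            gs.append(rec.subject_id or "s?")
    return np.asarray(Xs, dtype=np.float32), np.asarray(ys), np.asarray(gs)


def dataset_to_features(
    dataset: Sequence[tuple[Recording, GroundTruth]],
    model: BackgroundModel,
    T: int = 15,
    train_offsets: Sequence[int] = (0,),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """6-feature sequences for the LSTM path; layout ``(n, T, 6)``."""
    Xs, ys, gs = [], [], []
    for rec, _gt in dataset:
        fg = recording_foreground(rec, model)
        center = (fg.shape[0] - T) // 2
        for off in train_offsets:
            start = int(np.clip(center + off, 0, fg.shape[0] - T))
            fm = window_feature_matrix(fg[start : start + T], frame_rate_hz=rec.frame_rate_hz)
            Xs.append(fm.values.T)  # (T, 6) step-major
            ys.append(str(rec.label))
            gs.append(rec.subject_id or "s?")
    return np.asarray(Xs, dtype=np.float32), np.asarray(ys), np.asarray(gs)
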