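"""Thermal frame / recording data model, container I/O and window extraction.

Conventions fixed here and used everywhere else in the package:

* a frame is a row-major ``(24, 32)`` float array of temperatures in °C,
  0-based ``(row, col)`` indexing with row 0 at the top;
* temperatures must lie in the sensor operating range [-40, 85] °C;
* the eight motion classes have one canonical ordering (:data:`MOTION_LABELS`)
  that every confusion matrix and probability vector follows;
* frame timestamps are derived (``index / frame_rate``), never stored.

Recordings are stored one per file as NumPy ``.npz`` archives holding the
frame stack plus a JSON metadata record (geometry, frame rate, units, label,
subject); a plain CSV export (one 24-line block per frame) is provided for
eyeballing.  Dataset manifests are tab-separated tables with columns
``path, label, subject_id``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: (rows, cols) of the thermopile array.
GRID_SHAPE: tuple[int, int] = (24, 32)

#: Sensor operating range in °C; values outside are rejected as corrupt.
TEMP_RANGE_C: tuple[float, float] = (-40.0, 85.0)

#: Canonical class order.  Every label vector, probability vector and
#: confusion matrix in the package uses this order.
MOTION_LABELS: tuple[str, ...] = (
    "falling",
    "sit2stand",
    "stand2sit",
    "sitting",
    "standing",
    "bowing",
    "crouching",
    "walking",
)

LABEL_TO_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(MOTION_LABELS)}

DEFAULT_FRAME_RATE_HZ: float = 15.0

_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Malformed container file."""


class GeometryError(ValueError):
    """Frame shape does not match the expected sensor geometry."""


class MotionLabel(str):
    """One of the eight motion classes (a validated string).

    Instances compare equal to their plain-string value, so ``"falling"``
    may be used interchangeably after validation.
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "MotionLabel":
        if value not in LABEL_TO_INDEX:
            raise ValueError(
                f"unknown motion label {value!r}; expected one of {MOTION_LABELS}"
            )
        return super().__new__(cls, value)

    @property
    def index(self) -> int:
        return LABEL_TO_INDEX[str(self)]


def _validate_values(values: np.ndarray, *, shape: tuple[int, int]) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != shape:
        raise GeometryError(
            f"frame shape {values.shape} != expected {shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("frame contains non-finite temperatures")
    lo, hi = TEMP_RANGE_C
    if values.min() < lo or values.max() > hi:
        raise ValueError(
            f"temperatures outside sensor range [{lo}, {hi}] °C: "
            f"min={values.min():.2f}, max={values.max():.2f}"
        )
    return values


@dataclass(frozen=True)
class ThermalFrame:
    """One temperature image.

    Parameters
    ----------
    values
        ``(24, 32)`` array of temperatures in °C.
    index
        Non-negative frame number within its recording.
    frame_rate_hz
        Acquisition rate; only used to derive :attr:`timestamp_s`.
    shape
        Sensor geometry override (rows, cols); default ``(24, 32)``.
    """

    values: np.ndarray
    index: int = 0
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    shape: tuple[int, int] = GRID_SHAPE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _validate_values(self.values, shape=self.shape)
        )
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def timestamp_s(self) -> float:
        """Seconds since the first frame (``index / frame_rate``)."""
        return self.index / self.frame_rate_hz


@dataclass
class Recording:
    """An ordered sequence of frames with shared metadata."""

    frames: list[ThermalFrame]
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    label: MotionLabel | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if self.label is not None and not isinstance(self.label, MotionLabel):
            self.label = MotionLabel(self.label)
        for i, f in enumerate(self.frames):
            if f.index != i:
                raise ValueError(
                    f"frame indices must increase by 1 from 0; frame {i} has index {f.index}"
                )
            if f.shape != self.frames[0].shape:
                raise GeometryError("all frames in a recording must share one shape")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ThermalFrame]:
        return iter(self.frames)

    def stack(self) -> np.ndarray:
        """All frames as one ``(n_frames, rows, cols)`` array (a copy)."""
        if not self.frames:
            return np.empty((0,) + GRID_SHAPE)
        return np.stack([f.values for f in self.frames])

    @classmethod
    def from_stack(
        cls,
        stack: np.ndarray,
        frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
        label: str | None = None,
        subject_id: str | None = None,
    ) -> "Recording":
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 3:
            raise GeometryError("stack must be (n_frames, rows, cols)")
        shape = stack.shape[1:]
        frames = [
            ThermalFrame(stack[i], index=i, frame_rate_hz=frame_rate_hz, shape=shape)
            for i in range(stack.shape[0])
        ]
        lab = MotionLabel(label) if label is not None else None
        return cls(frames, frame_rate_hz=frame_rate_hz, label=lab, subject_id=subject_id)


@dataclass
class FrameWindow:
    """``T`` consecutive frames forming one classification sample.

    ``units`` records what the values mean: ``"celsius"`` for raw sensor
    temperatures, ``"delta_c"`` for °C above background, ``"normalized"``
    for [0, 1] grayscale ready for a classifier.
    """

    values: np.ndarray
    label: MotionLabel | None = None
    units: str = "celsius"
    subject_id: str | None = None

    _UNIT_CHOICES = ("celsius", "delta_c", "normalized")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError("window values must be (T, rows, cols)")
        if self.units not in self._UNIT_CHOICES:
            raise ValueError(f"units must be one of {self._UNIT_CHOICES}")
        if self.label is not None and not isinstance(self.label, MotionLabel):
            self.label = MotionLabel(self.label)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Container I/O


def write_recording(rec: Recording, path: str | Path, overwrite: bool = False) -> None:
    """Write a recording to an ``.npz`` container.

    Refuses to clobber an existing file unless ``overwrite`` is set.  The
    recording is validated (shape, finiteness, temperature range) before any
    bytes are written.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    stack = rec.stack()  # frames were validated at construction
    meta = {
        "format_version": _FORMAT_VERSION,
        "rows": int(stack.shape[1]) if len(rec) else GRID_SHAPE[0],
        "cols": int(stack.shape[2]) if len(rec) else GRID_SHAPE[1],
        "frame_rate_hz": rec.frame_rate_hz,
        "units": "celsius",
        "label": str(rec.label) if rec.label is not None else None,
        "subject_id": rec.subject_id,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, frames=stack, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    try:
        with np.load(path) as npz:
            if "frames" not in npz or "meta" not in npz:
                raise FormatError(f"{path}: missing 'frames' or 'meta' record")
            stack = npz["frames"]
            meta = json.loads(bytes(npz["meta"]).decode())
    except (OSError, ValueError) as exc:
        if isinstance(exc, (FormatError, GeometryError)):
            raise
        raise FormatError(f"{path}: not a recording container ({exc})") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported format version {meta.get('format_version')}")
    expected = (meta["rows"], meta["cols"])
    if stack.ndim != 3 or stack.shape[1:] != expected:
        raise GeometryError(
            f"{path}: frame geometry {stack.shape[1:]} != header {expected}"
        )
    return Recording.from_stack(
        stack,
        frame_rate_hz=meta["frame_rate_hz"],
        label=meta["label"],
        subject_id=meta["subject_id"],
    )


def export_csv(rec: Recording, path: str | Path) -> None:
    """Human-inspectable CSV export: one 24-line block per frame, blank line
    between frames, '# frame i' comment heading each block."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# thermofall recording, {len(rec)} frames @ {rec.frame_rate_hz} Hz\n")
        for f in rec.frames:
            fh.write(f"# frame {f.index}\n")
            for row in f.values:
                fh.write(",".join(f"{v:.4f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Window extraction


def extract_windows(rec: Recording, T: int = 15, stride: int = 1) -> list[FrameWindow]:
    """Slice a recording into windows of ``T`` frames at the given stride.

    Start indices are ``0, stride, 2*stride, ...``; the count is
    ``floor((L - T) / stride) + 1``.  Each window inherits the recording's
    label and subject.
    """
    if T <= 0 or stride <= 0:
        raise ValueError("T and stride must be positive")
    L = len(rec)
    if T > L:
        raise ValueError(f"window length {T} exceeds recording length {L}; need ≥ {T} frames")
    stack = rec.stack()
    out = []
    for start in range(0, L - T + 1, stride):
        out.append(
            FrameWindow(
                stack[start : start + T],
                label=rec.label,
                units="celsius",
                subject_id=rec.subject_id,
            )
        )
    return out


def centered_window(rec: Recording, T: int = 15) -> FrameWindow:
    """The single window of length ``T`` centered in the recording.

    Evaluation counts one sample per recorded repetition, so a 3-s,
    45-frame recording contributes exactly one centered 15-frame window.
    """
    L = len(rec)
    if T > L:
        raise ValueError(f"window length {T} exceeds recording length {L}")
    start = (L - T) // 2
    stack = rec.stack()
    return FrameWindow(
        stack[start : start + T], label=rec.label, units="celsius",
        subject_id=rec.subject_id,
    )


# ---------------------------------------------------------------------------
# Manifests


def write_manifest(rows: Sequence[tuple[str, str, str]] | pd.DataFrame,
                   path: str | Path) -> None:
    """Write a dataset manifest (TSV with columns path, label, subject_id)."""
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows, columns=["path", "label", "subject_id"])
    rows.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"path", "label", "subject_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest missing columns {required - set(df.columns)}")
    for lab in df["label"]:
        MotionLabel(lab)  # validates
    return df
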