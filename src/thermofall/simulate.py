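"""Seeded synthetic thermal-scene generator.

Real participant recordings behind this kind of system are not public, so
the package ships a generator that emulates what the overhead 32x24
thermopile sees: a uniform room at ~25 °C, optional static warm equipment,
per-pixel Gaussian sensor noise at the sensor's NETD (0.1-0.25 K), and one
warm human blob per person modelled as an anisotropic 2-D Gaussian
temperature excess, truncated at 1 °C above background (so the blob has a
crisp support) and peaking 4-6 °C above it (internal spread ≤ 5 °C).

Eight scripted motion classes drive the blob's center, size, elongation
and orientation over a 3-s, 45-frame recording:

* ``falling``   - upright blob displaces ~3-4 px while growing and
  elongating into a lying blob over 0.7-1.0 s, then stays static;
* ``sit2stand`` - medium blob shrinks to upright size over 0.7-1.0 s;
* ``stand2sit`` - the reverse;
* ``sitting`` / ``standing`` / ``crouching`` - static blobs of distinct
  sizes with small jitter;
* ``bowing``    - upright blob elongates moderately and shifts ~1.5 px;
* ``walking``   - blob translates continuously at ~1.5-2.5 px/frame with a
  wandering heading, elongated along the direction of travel.

Every draw flows from one ``numpy.random.Generator``, so a (config, seed)
pair reproduces a dataset exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GRID_SHAPE, MOTION_LABELS, MotionLabel, Recording, ThermalFrame

#: Blob temperature excess above background is truncated below this value.
TRUNCATE_EXCESS_C = 1.0

#: Peak excess range: peak temperature 29-31 °C over a 25 °C background,
#: keeping the on-support spread (peak − truncation) within 5 °C.
PEAK_EXCESS_RANGE_C = (4.0, 6.0)


@dataclass(frozen=True)
class EquipmentSpot:
    """Static warm clutter (e.g. a monitor): a small Gaussian bump."""

    row: float
    col: float
    excess_c: float = 15.0
    sigma_px: float = 1.0
    on_from_frame: int = 0  # switch-on frame; always-on by default


@dataclass(frozen=True)
class SceneConfig:
    rows: int = GRID_SHAPE[0]
    cols: int = GRID_SHAPE[1]
    background_c: float = 25.0
    noise_sigma_k: float = 0.2
    frame_rate_hz: float = 15.0
    duration_s: float = 3.0
    equipment_spots: tuple[EquipmentSpot, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_sigma_k <= 1.0:
            raise ValueError("noise sigma must be a small non-negative value (K)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass
class MotionScript:
    """Per-frame blob parameters for one person.

    All trajectory arrays have exactly ``duration * rate`` frames.  The
    blob is an anisotropic Gaussian with standard deviations
    ``sigma_long >= sigma_short`` (px) along/across the ``theta`` axis.
    """

    label: MotionLabel
    centers: np.ndarray  # (n, 2) float (row, col)
    sigma_long: np.ndarray  # (n,)
    sigma_short: np.ndarray  # (n,)
    theta: np.ndarray  # (n,) radians
    peak_excess_c: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = self.centers.shape[0]
        for arr in (self.sigma_long, self.sigma_short, self.theta, self.peak_excess_c):
            if arr.shape[0] != n:
                raise ValueError("all trajectory arrays must share one length")
        if np.any(self.peak_excess_c < TRUNCATE_EXCESS_C):
            raise ValueError("peak excess must stay ≥ the 1 °C truncation level")
        if np.any(self.peak_excess_c - TRUNCATE_EXCESS_C > 5.0 + 1e-9):
            raise ValueError("blob internal spread must stay within 5 °C")

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]


@dataclass
class GroundTruth:
    """What the simulator knows that the pipeline must recover."""

    labels: list[MotionLabel]
    centers: np.ndarray  # (k, n, 2)
    areas: np.ndarray  # (k, n) noise-free support pixel counts
    n_targets: int


# ---------------------------------------------------------------------------
# Blob rendering


def _blob_excess(
    rows: int, cols: int, center: tuple[float, float],
    s_long: float, s_short: float, theta: float, peak: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    # rotate into the blob's principal frame (theta measured from the col axis)
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    q = (u / s_long) ** 2 + (v / s_short) ** 2
    e = peak * np.exp(-0.5 * q)
    return np.where(e >= TRUNCATE_EXCESS_C, e, 0.0)


def _equipment_field(scene: SceneConfig, frame_idx: int) -> np.ndarray:
    out = np.zeros((scene.rows, scene.cols))
    for spot in scene.equipment_spots:
        if frame_idx < spot.on_from_frame:
            continue
        out += _blob_excess(
            scene.rows, scene.cols, (spot.row, spot.col),
            spot.sigma_px, spot.sigma_px, 0.0, spot.excess_c,
        )
    return out


def render_recording(
    scene: SceneConfig,
    scripts: Sequence[MotionScript],
    rng: np.random.Generator | None = None,
    allow_clipping: bool = False,
    subject_id: str | None = None,
) -> tuple[Recording, GroundTruth]:
    """Render scripts into a noisy recording plus its ground truth.

    Raises when a blob center leaves the grid unless ``allow_clipping``.
    A single-script recording carries that script's label.
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    n = scene.n_frames
    for s in scripts:
        if s.n_frames != n:
            raise ValueError(f"script has {s.n_frames} frames, scene needs {n}")
        if not allow_clipping:
            r, c = s.centers[:, 0], s.centers[:, 1]
            if r.min() < 0 or c.min() < 0 or r.max() > scene.rows - 1 or c.max() > scene.cols - 1:
                raise ValueError("blob center leaves the grid; set allow_clipping=True to permit")
    frames = np.empty((n, scene.rows, scene.cols))
    k = len(scripts)
    centers = np.zeros((k, n, 2))
    areas = np.zeros((k, n), dtype=np.int64)
    for i in range(n):
        field_c = np.full((scene.rows, scene.cols), scene.background_c)
        field_c += _equipment_field(scene, i)
        for j, s in enumerate(scripts):
            e = _blob_excess(
                scene.rows, scene.cols, tuple(s.centers[i]),
                float(s.sigma_long[i]), float(s.sigma_short[i]),
                float(s.theta[i]), float(s.peak_excess_c[i]),
            )
            field_c += e
            centers[j, i] = s.centers[i]
            areas[j, i] = int((e >= TRUNCATE_EXCESS_C).sum())
        if scene.noise_sigma_k > 0:
            field_c = field_c + rng.normal(0.0, scene.noise_sigma_k, field_c.shape)
        frames[i] = field_c
    label = scripts[0].label if len(scripts) == 1 else None
    rec = Recording.from_stack(
        frames, frame_rate_hz=scene.frame_rate_hz,
        label=str(label) if label else None, subject_id=subject_id,
    )
    gt = GroundTruth(
        labels=[s.label for s in scripts], centers=centers, areas=areas, n_targets=k
    )
    return rec, gt


def render_background_frames(
    scene: SceneConfig, n: int, rng: np.random.Generator | None = None
) -> list[ThermalFrame]:
    """Target-free frames (background + equipment + noise) for model init."""
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    frames = []
    for i in range(n):
        field_c = np.full((scene.rows, scene.cols), scene.background_c)
        field_c += _equipment_field(scene, i)
        if scene.noise_sigma_k > 0:
            field_c = field_c + rng.normal(0.0, scene.noise_sigma_k, field_c.shape)
        frames.append(ThermalFrame(field_c, index=i, frame_rate_hz=scene.frame_rate_hz))
    return frames


# ---------------------------------------------------------------------------
# Motion scripts

_UPRIGHT = 1.3  # sigma (px) of a standing person seen from above
_SITTING = 2.0
_CROUCH = 1.6
_LYING_LONG, _LYING_SHORT = 4.0, 1.5


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3 - 2 * t)


def _jitter_walk(rng: np.random.Generator, n: int, step: float) -> np.ndarray:
    return np.cumsum(rng.normal(0.0, step, size=(n, 2)), axis=0)


def make_script(
    label: str,
    scene: SceneConfig,
    rng: np.random.Generator,
    center: tuple[float, float] | None = None,
    style: dict | None = None,
    margin: float = 7.0,
) -> MotionScript:
    """Build one randomized per-frame script for the given class.

    ``style`` carries optional per-subject multipliers (``size``, ``speed``,
    ``warmth``) emulating body-size and gait differences; ``margin`` is the
    spawn keep-out border in pixels.
    """
    label = MotionLabel(label)
    n = scene.n_frames
    style = style or {}
    size = style.get("size", 1.0)
    speed_mult = style.get("speed", 1.0)
    peak = rng.uniform(*PEAK_EXCESS_RANGE_C) * style.get("warmth", 1.0)
    peak = float(np.clip(peak, TRUNCATE_EXCESS_C + 1.0, TRUNCATE_EXCESS_C + 5.0))
    if center is None:
        center = (
            rng.uniform(margin, scene.rows - 1 - margin),
            rng.uniform(margin, scene.cols - 1 - margin),
        )
    theta0 = rng.uniform(0, 2 * math.pi)
    t = np.arange(n)
    # transition window for the one-motion classes: 0.7-1.0 s, placed so it
    # straddles the middle of the recording (the classified clip is the
    # centered window, one per repetition)
    dur = int(round(rng.uniform(0.7, 1.0) * scene.frame_rate_hz))
    mid = n // 2
    lo = max(1, mid - dur + 2)
    hi = max(lo + 1, mid - 2)
    start = rng.integers(lo, hi)
    ramp = _smoothstep((t - start) / max(dur, 1))

    centers = np.tile(np.asarray(center, dtype=np.float64), (n, 1))
    theta = np.full(n, theta0)
    peaks = np.full(n, peak)

    if label == "falling":
        fall_len = rng.uniform(2.5, 4.0) * speed_mult
        direction = np.array([math.sin(theta0), math.cos(theta0)])
        centers = centers + ramp[:, None] * fall_len * direction
        s_long = (_UPRIGHT + ramp * (_LYING_LONG - _UPRIGHT)) * size
        s_short = (_UPRIGHT + ramp * (_LYING_SHORT - _UPRIGHT)) * size
    elif label == "sit2stand":
        s_long = (_SITTING + ramp * (_UPRIGHT - _SITTING)) * size
        s_short = s_long.copy()
        centers = centers + ramp[:, None] * 0.5 * np.array([math.sin(theta0), math.cos(theta0)])
    elif label == "stand2sit":
        s_long = (_UPRIGHT + ramp * (_SITTING - _UPRIGHT)) * size
        s_short = s_long.copy()
        centers = centers + ramp[:, None] * 0.5 * np.array([math.sin(theta0), math.cos(theta0)])
    elif label == "sitting":
        s_long = np.full(n, _SITTING * size)
        s_short = s_long * rng.uniform(0.9, 1.0)
        centers = centers + _jitter_walk(rng, n, 0.03)
    elif label == "standing":
        s_long = np.full(n, _UPRIGHT * size)
        s_short = s_long * rng.uniform(0.9, 1.0)
        centers = centers + _jitter_walk(rng, n, 0.03)
    elif label == "bowing":
        s_long = (_UPRIGHT + ramp * (2.6 * size - _UPRIGHT))
        s_short = np.full(n, _UPRIGHT * size)
        centers = centers + ramp[:, None] * 1.5 * np.array([math.sin(theta0), math.cos(theta0)])
    elif label == "crouching":
        s_long = np.full(n, _CROUCH * size)
        s_short = s_long * rng.uniform(0.9, 1.0)
        centers = centers + _jitter_walk(rng, n, 0.05)
    elif label == "walking":
        speed = rng.uniform(1.5, 2.5) * speed_mult  # px/frame
        heading = theta0 + np.cumsum(rng.normal(0.0, 0.08, n))
        pos = np.zeros((n, 2))
        pos[0] = center
        lo = np.array([3.0, 3.0])
        hi = np.array([scene.rows - 4.0, scene.cols - 4.0])
        for i in range(1, n):
            step = speed * np.array([math.sin(heading[i]), math.cos(heading[i])])
            cand = pos[i - 1] + step
            for ax in (0, 1):  # reflect off the walkable margin
                if cand[ax] < lo[ax] or cand[ax] > hi[ax]:
                    heading[i:] += math.pi / 2
                    cand[ax] = np.clip(cand[ax], lo[ax], hi[ax])
            pos[i] = cand
        centers = pos
        theta = heading
        s_long = np.full(n, 1.7 * size)
        s_short = np.full(n, 1.2 * size)
    else:  # pragma: no cover - MotionLabel already validates
        raise ValueError(label)

    s_long, s_short = np.maximum(s_long, s_short), np.minimum(s_long, s_short)
    return MotionScript(
        label=label, centers=centers, sigma_long=s_long,
        sigma_short=s_short, theta=theta, peak_excess_c=peaks,
    )


# ---------------------------------------------------------------------------
# Datasets


def subject_styles(n_subjects: int, rng: np.random.Generator) -> list[dict]:
    """Per-subject systematic multipliers (body size, pace, warmth)."""
    return [
        {
            "size": float(rng.uniform(0.9, 1.1)),
            "speed": float(rng.uniform(0.85, 1.15)),
            "warmth": float(rng.uniform(0.95, 1.05)),
        }
        for _ in range(n_subjects)
    ]


def make_dataset(
    n_per_class: int,
    scene: SceneConfig,
    seed: int | None = None,
    n_subjects: int = 8,
) -> list[tuple[Recording, GroundTruth]]:
    """A balanced labelled dataset: ``n_per_class`` recordings per class.

    Positions, directions and per-subject styles are randomized; recordings
    are assigned to ``n_subjects`` synthetic subjects in rotation.  Output
    is a pure function of ``(n_per_class, scene, seed, n_subjects)``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be ≥ 1")
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    styles = subject_styles(n_subjects, rng)
    out: list[tuple[Recording, GroundTruth]] = []
    for label in MOTION_LABELS:
        for i in range(n_per_class):
            subj = i % n_subjects
            script = make_script(label, scene, rng, style=styles[subj])
            rec, gt = render_recording(
                scene, [script], rng=rng, subject_id=f"s{subj:02d}"
            )
            out.append((rec, gt))
    return out


def make_multitarget_scene(
    k_targets: int,
    scene: SceneConfig,
    seed: int | None = None,
    one_falls: bool = True,
    min_separation_px: float = 10.0,
    max_tries: int = 500,
    spawn_margin_px: float = 5.0,
    spawn_centers: Sequence[tuple[float, float]] | None = None,
) -> tuple[Recording, GroundTruth]:
    """A scene with 1-3 people; optionally one falls while the rest walk.

    Spawn points (and walking boxes) keep all pairs at least
    ``min_separation_px`` apart for the whole recording.  Passing explicit
    ``spawn_centers`` pins the spawns and skips the separation check —
    placing two people adjacent this way reproduces the touching-targets
    merge failure.
    """
    if not 1 <= k_targets <= 3:
        raise ValueError("k_targets must be between 1 and 3")
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    pinned = spawn_centers is not None
    if pinned and len(spawn_centers) != k_targets:
        raise ValueError("need one spawn center per target")
    labels = [
        "falling" if (one_falls and j == 0) else "walking" for j in range(k_targets)
    ]
    walk_cap = 2.0  # walkers in a shared scene pace on the spot (px drift)
    # per-target worst-case center excursion from its spawn
    allowance = [4.0 if lab == "falling" else walk_cap for lab in labels]
    lo_r, hi_r = spawn_margin_px, scene.rows - 1 - spawn_margin_px
    lo_c, hi_c = spawn_margin_px, scene.cols - 1 - spawn_margin_px
    for _ in range(max_tries):
        if pinned:
            spawns = [np.asarray(c, dtype=np.float64) for c in spawn_centers]
        else:
            # choose spawns from a 1-px candidate grid, keeping each new
            # target outside every placed target's separation+movement disc
            rr, cc = np.meshgrid(
                np.arange(math.ceil(lo_r), math.floor(hi_r) + 1),
                np.arange(math.ceil(lo_c), math.floor(hi_c) + 1),
                indexing="ij",
            )
            grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
            spawns = []
            feasible = True
            for j in range(k_targets):
                ok_cells = np.ones(grid.shape[0], dtype=bool)
                for i, s in enumerate(spawns):
                    need = min_separation_px + allowance[j] + allowance[i]
                    ok_cells &= np.linalg.norm(grid - s, axis=1) >= need
                if not ok_cells.any():
                    feasible = False
                    break
                pick = rng.integers(ok_cells.sum())
                spawns.append(grid[np.flatnonzero(ok_cells)[pick]])
            if not feasible:
                continue
        scripts: list[MotionScript] = []
        for j, lab in enumerate(labels):
            script = make_script(
                lab, scene, rng, center=tuple(spawns[j]), margin=spawn_margin_px
            )
            if lab == "walking":
                # confine the walk near its spawn to preserve separation
                drift = script.centers - script.centers[0]
                norm = np.linalg.norm(drift, axis=1)
                scale = np.where(norm > walk_cap, walk_cap / np.maximum(norm, 1e-9), 1.0)
                script.centers = script.centers[0] + drift * scale[:, None]
            scripts.append(script)
        if not pinned:  # trajectory-level safety check
            sep_ok = all(
                np.linalg.norm(scripts[a].centers - scripts[b].centers, axis=1).min()
                >= min_separation_px
                for a in range(k_targets)
                for b in range(a + 1, k_targets)
            )
            if not sep_ok:
                continue
        return render_recording(scene, scripts, rng=rng)
    raise ValueError(
        f"could not place {k_targets} targets ≥ {min_separation_px} px apart "
        f"in {max_tries} tries"
    )
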