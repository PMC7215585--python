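"""Optogenetic stimulation schedules and pattern masks.

Four protocols are generated here:

* **probing movies** — random-dot frames in which a handful of grid positions
  light up per frame and every position is stimulated an exact number of times
  (used to build cross-correlogram connectivity maps);
* **random dot movies (RDMs)** — frames each lighting a uniformly random dot
  subset, played for tens of minutes to suppress synchronized network bursts;
* **tetanus trains** — a full pattern pulsed at high frequency (the learning
  stimulus);
* **test sessions** — the candidate patterns presented repeatedly in a random
  order, with trial labels.

All schedules are plain timed frames: an onset, an on-duration and a set of
lit row-major grid positions, so they serialize losslessly to JSON.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "StimulusSchedule",
    "PatternMask",
    "make_probing_schedule",
    "make_rdm_schedule",
    "make_tetanus_schedule",
    "make_test_schedule",
    "make_pattern",
    "balance_luminance",
    "BUILTIN_PATTERNS",
]


@dataclass(frozen=True)
class Frame:
    onset_ms: float
    on_ms: float
    positions: tuple[int, ...]
    intensity: float = 1.0


@dataclass
class StimulusSchedule:
    """Ordered stimulation frames on a (rows, cols) grid."""

    frames: list[Frame]
    grid_shape: tuple[int, int]
    total_duration_ms: float

    def __post_init__(self) -> None:
        n = self.grid_shape[0] * self.grid_shape[1]
        prev = -np.inf
        for k, f in enumerate(self.frames):
            if f.onset_ms <= prev:
                raise ValueError(f"frame {k}: onsets must be strictly increasing")
            prev = f.onset_ms
            if len(set(f.positions)) != len(f.positions):
                raise ValueError(f"frame {k}: duplicate positions within frame")
            for p in f.positions:
                if not 0 <= p < n:
                    raise ValueError(f"frame {k}: position {p} outside grid")
        if self.frames:
            last = self.frames[-1]
            if self.total_duration_ms < last.onset_ms + last.on_ms:
                raise ValueError("total_duration_ms shorter than last frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_positions(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def onsets(self) -> np.ndarray:
        return np.array([f.onset_ms for f in self.frames])

    def onsets_for_position(self, position: int) -> np.ndarray:
        """Onset times of every frame in which ``position`` is lit."""
        return np.array([f.onset_ms for f in self.frames if position in f.positions])

    def positions_used(self) -> np.ndarray:
        used = sorted({p for f in self.frames for p in f.positions})
        return np.array(used, dtype=int)

    def position_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_positions, dtype=int)
        for f in self.frames:
            for p in f.positions:
                counts[p] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "total_duration_ms": self.total_duration_ms,
            "frames": [
                {
                    "onset_ms": f.onset_ms,
                    "on_ms": f.on_ms,
                    "positions": list(map(int, f.positions)),
                    "intensity": f.intensity,
                }
                for f in self.frames
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        frames = [
            Frame(
                float(f["onset_ms"]),
                float(f["on_ms"]),
                tuple(int(p) for p in f["positions"]),
                float(f.get("intensity", 1.0)),
            )
            for f in d["frames"]
        ]
        return cls(frames, tuple(d["grid_shape"]), float(d["total_duration_ms"]))


@dataclass
class PatternMask:
    """A binary stimulus image on the pattern grid."""

    name: str
    mask: np.ndarray
    intensity: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("pattern mask has no lit cell")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def lit_positions(self) -> tuple[int, ...]:
        """Row-major indices of lit cells."""
        return tuple(int(i) for i in np.flatnonzero(self.mask.ravel()))


# ---------------------------------------------------------------------------
# Probing movies


def make_probing_schedule(
    grid_shape: tuple[int, int] = (16, 16),
    n_reps: int = 20,
    dots_per_frame: int = 5,
    frame_ms: float = 100.0,
    on_ms: float = 40.0,
    seed: int = 0,
    intensity: float = 1.0,
) -> StimulusSchedule:
    """Balanced random-dot probing movie.

    Every grid position is stimulated exactly ``n_reps`` times, ``dots_per_frame``
    distinct positions per frame, frames spaced ``frame_ms`` apart. The multiset
    of position slots is shuffled and packed sequentially into frames; within-frame
    duplicates are repaired by swapping with a compatible later slot, which keeps
    per-position counts exactly balanced.
    """
    n_pos = grid_shape[0] * grid_shape[1]
    if dots_per_frame > n_pos:
        raise ValueError("dots_per_frame exceeds grid size")
    total = n_pos * n_reps
    if total % dots_per_frame != 0:
        raise ValueError("grid size * n_reps must be divisible by dots_per_frame")
    n_frames = total // dots_per_frame
    rng = np.random.default_rng(seed)

    slots = np.repeat(np.arange(n_pos), n_reps)
    for _ in range(100):  # full-reshuffle fallback; virtually never loops twice
        rng.shuffle(slots)
        grid = slots.reshape(n_frames, dots_per_frame)
        if _repair_duplicates(grid, rng):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to build a duplicate-free probing schedule")

    frames = [
        Frame(k * frame_ms, on_ms, tuple(int(p) for p in sorted(grid[k])), intensity)
        for k in range(n_frames)
    ]
    return StimulusSchedule(frames, grid_shape, n_frames * frame_ms)


def _repair_duplicates(grid: np.ndarray, rng: np.random.Generator) -> bool:
    """Swap within-frame duplicate slots with compatible later slots, in place."""
    n_frames, d = grid.shape
    for f in range(n_frames):
        guard = 0
        while True:
            row = grid[f]
            vals, counts = np.unique(row, return_counts=True)
            dups = vals[counts > 1]
            if dups.size == 0:
                break
            guard += 1
            if guard > 10 * d:
                return False
            v = dups[0]
            j = int(np.flatnonzero(row == v)[-1])  # keep the first copy
            swapped = False
            for g in range(f + 1, n_frames):
                other = grid[g]
                if v in other:  # moving v into g would duplicate there
                    continue
                cand = np.flatnonzero(~np.isin(other, row))
                if cand.size:
                    m = int(cand[0])
                    grid[f, j], grid[g, m] = grid[g, m], grid[f, j]
                    swapped = True
                    break
            if not swapped:
                return False
    return True


# ---------------------------------------------------------------------------
# Random dot movies (burst suppression)


def make_rdm_schedule(
    grid_shape: tuple[int, int] = (10, 10),
    dots_per_frame: int = 25,
    frame_hz: float = 10.0,
    on_ms: float = 50.0,
    duration_s: float = 1800.0,
    seed: int = 0,
    intensity: float = 1.0,
) -> StimulusSchedule:
    """Random dot movie: each frame lights ``dots_per_frame`` uniform random dots."""
    n_pos = grid_shape[0] * grid_shape[1]
    if dots_per_frame > n_pos:
        raise ValueError("dots_per_frame exceeds grid size")
    frame_ms = 1000.0 / frame_hz
    if on_ms > frame_ms:
        raise ValueError("on_ms longer than the frame period")
    n_frames = int(np.floor(duration_s * frame_hz))
    if n_frames == 0:
        warnings.warn("duration shorter than one frame: empty schedule")
        return StimulusSchedule([], grid_shape, 0.0)
    rng = np.random.default_rng(seed)
    frames = [
        Frame(
            k * frame_ms,
            on_ms,
            tuple(int(p) for p in np.sort(rng.choice(n_pos, dots_per_frame, replace=False))),
            intensity,
        )
        for k in range(n_frames)
    ]
    return StimulusSchedule(frames, grid_shape, n_frames * frame_ms)


# ---------------------------------------------------------------------------
# Tetanus trains (learning stimulus)


def make_tetanus_schedule(
    pattern: PatternMask,
    freq_hz: float = 50.0,
    duty_frac: float = 0.5,
    n_trials: int = 60,
    trial_interval_s: float = 9.0,
    train_s: float = 1.0,
) -> StimulusSchedule:
    """High-frequency full-pattern pulse trains.

    Each trial delivers ``freq_hz * train_s`` pulses of the whole pattern at exact
    multiples of the pulse period; trials are spaced ``train_s + trial_interval_s``
    onset-to-onset with no trailing interval after the last trial.
    """
    if not 0 < duty_frac < 1:
        raise ValueError("duty_frac must be in (0, 1)")
    pulses_per_trial = freq_hz * train_s
    if abs(pulses_per_trial - round(pulses_per_trial)) > 1e-9:
        raise ValueError("freq_hz * train_s must be an integer pulse count")
    pulses_per_trial = int(round(pulses_per_trial))
    period_ms = 1000.0 / freq_hz
    on_ms = duty_frac * period_ms
    positions = pattern.lit_positions()

    frames: list[Frame] = []
    trial_span_ms = (train_s + trial_interval_s) * 1000.0
    for tr in range(n_trials):
        t0 = tr * trial_span_ms
        for p in range(pulses_per_trial):
            frames.append(Frame(t0 + p * period_ms, on_ms, positions, pattern.intensity))
    # Session span: n_trials * (train + interval) - interval (no trailing rest).
    total = (n_trials - 1) * trial_span_ms + train_s * 1000.0
    return StimulusSchedule(frames, pattern.grid_shape, total)


# ---------------------------------------------------------------------------
# Test sessions (pattern presentation with labels)


def make_test_schedule(
    patterns: list[PatternMask],
    n_trials_per: int = 10,
    interval_s: float = 10.0,
    on_ms: float = 100.0,
    seed: int = 0,
) -> tuple[StimulusSchedule, list[str]]:
    """Present each pattern ``n_trials_per`` times in seeded random order.

    Returns the schedule plus the per-frame pattern labels. At least two
    patterns are required (the familiarity metric needs control patterns).
    """
    if len(patterns) < 2:
        raise ValueError("need at least two patterns (controls required)")
    shapes = {p.grid_shape for p in patterns}
    if len(shapes) != 1:
        raise ValueError("patterns must share one grid shape")
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(patterns)), n_trials_per)
    rng.shuffle(order)
    interval_ms = interval_s * 1000.0
    frames = [
        Frame(k * interval_ms, on_ms, patterns[i].lit_positions(), patterns[i].intensity)
        for k, i in enumerate(order)
    ]
    labels = [patterns[i].name for i in order]
    sched = StimulusSchedule(frames, patterns[0].grid_shape, len(order) * interval_ms)
    return sched, labels


# ---------------------------------------------------------------------------
# Built-in pattern masks

# Normalized stroke lists ((x0,y0) -> (x1,y1) segments and circles) rasterized
# onto any grid. These are sketch-like stand-ins for the car-front, dog-face
# and human-face line drawings. The three sketches occupy different regions of
# the field with near-equal lit-cell counts and near-equal pairwise overlaps:
# strongly shared strokes between two patterns would correlate their evoked
# responses and structurally bias multiclass decoding toward the third.

_CAR_STROKES = {
    "lines": [
        (0.08, 0.68, 0.92, 0.68),  # hood line
        (0.08, 0.68, 0.12, 0.90),
        (0.92, 0.68, 0.88, 0.90),
        (0.12, 0.90, 0.88, 0.90),  # bumper
        (0.22, 0.68, 0.32, 0.50),
        (0.78, 0.68, 0.68, 0.50),
        (0.32, 0.50, 0.68, 0.50),  # roof
        (0.22, 0.78, 0.36, 0.78),  # headlights
        (0.64, 0.78, 0.78, 0.78),
    ],
    "circles": [(0.24, 0.95, 0.04), (0.76, 0.95, 0.04)],  # wheels
}

_DOG_STROKES = {
    "lines": [
        (0.72, 0.06, 0.98, 0.32),  # diamond head
        (0.98, 0.32, 0.72, 0.58),
        (0.72, 0.58, 0.46, 0.32),
        (0.46, 0.32, 0.72, 0.06),
        (0.56, 0.02, 0.52, 0.22),  # ears
        (0.88, 0.02, 0.92, 0.22),
        (0.50, 0.42, 0.62, 0.40),  # whiskers
        (0.82, 0.40, 0.94, 0.42),
        (0.64, 0.50, 0.80, 0.50),  # mouth
    ],
    "circles": [
        (0.65, 0.25, 0.03),  # eyes
        (0.79, 0.25, 0.03),
        (0.72, 0.37, 0.045),  # nose
    ],
}

_HUMAN_STROKES = {
    "lines": [
        (0.30, 0.28, 0.26, 0.40),  # nose
        (0.26, 0.40, 0.34, 0.42),
        (0.20, 0.50, 0.40, 0.50),  # mouth
        (0.12, 0.12, 0.48, 0.12),  # hair line
        (0.16, 0.22, 0.26, 0.21),  # brows
        (0.34, 0.21, 0.44, 0.22),
    ],
    "circles": [
        (0.30, 0.32, 0.27),  # face oval
        (0.22, 0.26, 0.035),  # eyes
        (0.38, 0.26, 0.035),
    ],
}

BUILTIN_PATTERNS: dict[str, dict] = {
    "car": _CAR_STROKES,
    "dog": _DOG_STROKES,
    "human": _HUMAN_STROKES,
}


def _rasterize(strokes: dict, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)

    def mark(x: float, y: float) -> None:
        c = min(cols - 1, max(0, int(round(x * (cols - 1)))))
        r = min(rows - 1, max(0, int(round(y * (rows - 1)))))
        mask[r, c] = True

    n_steps = 4 * max(rows, cols)
    for x0, y0, x1, y1 in strokes.get("lines", []):
        for t in np.linspace(0.0, 1.0, n_steps):
            mark(x0 + t * (x1 - x0), y0 + t * (y1 - y0))
    for cx, cy, rad in strokes.get("circles", []):
        for a in np.linspace(0.0, 2 * np.pi, n_steps, endpoint=False):
            mark(cx + rad * np.cos(a), cy + rad * np.sin(a))
    return mask


def make_pattern(
    name: str,
    pattern_grid_shape: tuple[int, int] = (50, 50),
    intensity: float = 1.0,
    mask: np.ndarray | None = None,
) -> PatternMask:
    """A named binary pattern mask: a built-in sketch or a user-supplied mask."""
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        return PatternMask(name, m, intensity)
    if name not in BUILTIN_PATTERNS:
        raise ValueError(
            f"unknown pattern {name!r}; built-ins are {sorted(BUILTIN_PATTERNS)}"
        )
    return PatternMask(name, _rasterize(BUILTIN_PATTERNS[name], pattern_grid_shape), intensity)


def balance_luminance(patterns: list[PatternMask]) -> list[PatternMask]:
    """Tune per-pattern intensity so expected elicited responses match.

    Experiments balance stimulus luminance so each pattern drives a comparable
    baseline network response. With lit-cell counts as the proxy for drive,
    each mask's intensity is scaled to ``min_lit / lit``, equalizing the
    expected number of stimulated connections across patterns.
    """
    min_lit = min(int(p.mask.sum()) for p in patterns)
    return [
        PatternMask(p.name, p.mask, p.intensity * min_lit / int(p.mask.sum()))
        for p in patterns
    ]
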