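"""Assembly of 50 s two-frequency trial movies.

A trial interleaves 65 scrambling cycles (1.3 Hz) of a face and a house
image in a pseudo-random order whose category proportion sets the
trial's certainty level, then applies a global sinusoidal contrast
modulation at 10 Hz on top.  Each image cycle is alpha-blended 50/50
with a "noise" cycle built from the most scrambled frame of the *other*
category's cycle, so low-level statistics are constant across cycles
regardless of which image peaks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .swift import SwiftCycle, generate_cycle, scramble_distance

__all__ = [
    "CycleSchedule",
    "TrialMovie",
    "TrialSpec",
    "assemble_trial",
    "blend",
    "cycle_duration_ms",
    "make_noise_cycle",
    "sample_proportions",
    "schedule_cycles",
]

CATEGORIES = ("face", "house")


def cycle_duration_ms(f2: float = 1.3) -> int:
    """Duration of one scrambling cycle in ms, rounded to the nearest integer."""
    return int(round(1000.0 / f2))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TrialSpec:
    """Design parameters of one trial."""

    duration_s: float = 50.0
    f1: float = 10.0  # contrast (SSVEP) frequency, Hz
    f2: float = 1.3  # scrambling-cycle (SWIFT) frequency, Hz
    p_dominant: float = 0.5  # proportion of cycles showing the dominant category
    dominant: str = "face"
    task_target: str = "face"  # category the observer counts
    display_rate: float = 120.0  # frames per second
    contrast_depth: float = 1.0
    background: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.5 <= self.p_dominant <= 1.0):
            raise ValueError("p_dominant must lie in [0.5, 1]")
        if self.dominant not in CATEGORIES or self.task_target not in CATEGORIES:
            raise ValueError(f"categories must be one of {CATEGORIES}")
        if not (0.0 <= self.contrast_depth <= 1.0):
            raise ValueError("contrast_depth must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        """Complete scrambling cycles per trial: floor(duration * f2)."""
        return int(math.floor(self.duration_s * self.f2 + 1e-9))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.display_rate))


@dataclass
class CycleSchedule:
    """Ordered category labels of a trial's cycles."""

    labels: list[str]

    @property
    def n_cycles(self) -> int:
        return len(self.labels)

    def count(self, category: str) -> int:
        return sum(1 for lab in self.labels if lab == category)

    @property
    def counts(self) -> dict[str, int]:
        return {c: self.count(c) for c in CATEGORIES}


def schedule_cycles(spec: TrialSpec, rng: np.random.Generator) -> CycleSchedule:
    """Uniformly random cycle order with round-half-up dominant count."""
    n = spec.n_cycles
    n_dom = _round_half_up(spec.p_dominant * n)
    other = CATEGORIES[1 - CATEGORIES.index(spec.dominant)]
    labels = np.array([spec.dominant] * n_dom + [other] * (n - n_dom), dtype=object)
    labels = labels[rng.permutation(n)]
    return CycleSchedule(labels=list(labels))


def make_noise_cycle(
    cycle: SwiftCycle, rng: np.random.Generator, frames_per_cycle: int | None = None
) -> SwiftCycle:
    """Scrambling cycle seeded from the most scrambled frame of ``cycle``.

    Carries the low-level statistics of the source cycle but no
    recognizable image at its peak.
    """
    if cycle.frames_per_cycle < 2:
        raise ValueError("cycle must have at least two frames")
    original = cycle.frames[cycle.peak_index]
    dists = [scramble_distance(f, original) for f in cycle.frames]
    seed_frame = cycle.frames[int(np.argmax(dists))]
    return generate_cycle(
        seed_frame,
        frames_per_cycle or cycle.frames_per_cycle,
        rng,
        levels=cycle.levels,
        peak_index=cycle.peak_index,
        source_image_id=f"{cycle.source_image_id}:noise",
    )


def blend(image_cycle: SwiftCycle, noise_cycle: SwiftCycle) -> SwiftCycle:
    """Equal-weight per-frame average of an image cycle and a noise cycle."""
    if image_cycle.frames.shape != noise_cycle.frames.shape:
        raise ValueError(
            f"shape mismatch: {image_cycle.frames.shape} vs {noise_cycle.frames.shape}"
        )
    return SwiftCycle(
        frames=0.5 * image_cycle.frames + 0.5 * noise_cycle.frames,
        peak_index=image_cycle.peak_index,
        source_image_id=f"{image_cycle.source_image_id}+{noise_cycle.source_image_id}",
        levels=image_cycle.levels,
    )


@dataclass
class TrialMovie:
    """Rendered trial: frame stack plus schedule and timing metadata."""

    frames: np.ndarray  # (n_frames, n, n), float32
    contrast_gain: np.ndarray  # per-frame multiplicative gain in [0, 1]
    schedule: CycleSchedule
    spec: TrialSpec
    true_count: int

    def save_npz(self, path: str) -> None:
        np.savez_compressed(
            path,
            frames=self.frames,
            contrast_gain=self.contrast_gain,
            labels=np.array(self.schedule.labels, dtype="U8"),
            true_count=self.true_count,
        )
        meta = {
            "duration_s": self.spec.duration_s,
            "f1": self.spec.f1,
            "f2": self.spec.f2,
            "display_rate": self.spec.display_rate,
            "p_dominant": self.spec.p_dominant,
            "dominant": self.spec.dominant,
            "task_target": self.spec.task_target,
            "true_count": self.true_count,
            "labels": self.schedule.labels,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def assemble_trial(
    spec: TrialSpec,
    face_cycle: SwiftCycle,
    house_cycle: SwiftCycle,
    rng: np.random.Generator,
) -> TrialMovie:
    """Render a trial movie from one face and one house cycle.

    The face cycle is blended with house-derived noise and vice versa,
    cycles are laid out per the random schedule, frames are sampled by
    time (frame at t shows cycle ``floor(t * f2)`` at phase
    ``t * f2 mod 1``), and the contrast gain
    ``(1 - d/2) + (d/2) sin(2 pi f1 t)`` is applied about the grey
    background level.
    """
    if face_cycle.frames.shape != house_cycle.frames.shape:
        raise ValueError("face and house cycles must share shape and length")

    face_noise = make_noise_cycle(face_cycle, rng)
    house_noise = make_noise_cycle(house_cycle, rng)
    shown = {
        "face": blend(face_cycle, house_noise),
        "house": blend(house_cycle, face_noise),
    }

    schedule = schedule_cycles(spec, rng)
    fpc = face_cycle.frames_per_cycle
    peak = face_cycle.peak_index

    t = np.arange(spec.n_frames) / spec.display_rate
    cyc_idx = np.minimum((t * spec.f2).astype(int), spec.n_cycles - 1)
    phase = (t * spec.f2) % 1.0
    # phase 0 of a cycle maps to its peak frame
    frame_idx = (np.round(phase * fpc).astype(int) + peak) % fpc

    d = spec.contrast_depth
    gain = (1.0 - d / 2.0) + (d / 2.0) * np.sin(2.0 * np.pi * spec.f1 * t)

    n = face_cycle.frames.shape[1]
    frames = np.empty((spec.n_frames, n, n), dtype=np.float32)
    label_arr = np.array(schedule.labels, dtype=object)
    for cat in CATEGORIES:
        sel = np.nonzero(label_arr[cyc_idx] == cat)[0]
        if sel.size:
            raw = shown[cat].frames[frame_idx[sel]]
            frames[sel] = (
                spec.background + gain[sel, None, None] * (raw - spec.background)
            ).astype(np.float32)

    return TrialMovie(
        frames=frames,
        contrast_gain=gain,
        schedule=schedule,
        spec=spec,
        true_count=schedule.count(spec.task_target),
    )


def sample_proportions(
    n_trials: int, rng: np.random.Generator, lo: float = 0.5, hi: float = 1.0
) -> np.ndarray:
    """Session-level certainty design: ``n_trials`` distinct proportions.

    Evenly spans [lo, hi] and shuffles, so no proportion repeats within a
    session.
    """
    grid = np.linspace(lo, hi, n_trials)
    return grid[rng.permutation(n_trials)]
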