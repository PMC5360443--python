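"""Multichannel EEG recording container and plain-array I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording"]


@dataclass
class EEGRecording:
    """Channels x samples EEG data in microvolts.

    ``cycle_onsets`` holds the sample index at which each scrambling
    cycle starts; the last cycle is assumed to end where the next would
    begin (or at the end of the recording).
    """

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float  # Hz
    labels: list[str]
    cycle_onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.cycle_onsets = np.asarray(self.cycle_onsets, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def cycle_slices(self) -> list[slice]:
        """Half-open sample ranges of each cycle."""
        on = list(self.cycle_onsets) + [self.n_samples]
        return [slice(int(a), int(b)) for a, b in zip(on[:-1], on[1:])]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            fs=self.fs,
            labels=list(self.labels),
            cycle_onsets=self.cycle_onsets.copy(),
        )

    def save_npz(self, path: str) -> None:
        np.savez_compressed(
            path,
            data=self.data,
            fs=self.fs,
            labels=np.array(self.labels, dtype="U8"),
            cycle_onsets=self.cycle_onsets,
        )

    @classmethod
    def from_npz(cls, path: str) -> "EEGRecording":
        with np.load(path) as z:
            return cls(
                data=z["data"],
                fs=float(z["fs"]),
                labels=[str(x) for x in z["labels"]],
                cycle_onsets=z["cycle_onsets"],
            )
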