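"""Core data containers shared across the pipeline stages.

These are deliberately thin: validated arrays plus the metadata needed to
interpret them (sampling rate, epoch length, start time). Axis convention
follows the waist-worn device: ``y`` is vertical (in line with gravity when
upright), ``x`` horizontal, ``z`` perpendicular.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .errors import ContractError

__all__ = ["RawRecording", "EpochCounts", "WearMask"]


def _as_float_axis(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1:
        raise ContractError(f"axis '{name}' must be one-dimensional")
    return arr


@dataclass
class RawRecording:
    """Uniformly sampled tri-axial acceleration in g.

    Invariants (enforced on construction): the three axes have identical
    length >= 1, every sample is finite, and the sampling rate is a single
    positive number for the whole recording.
    """

    sample_rate_hz: float
    start_time: datetime
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = _as_float_axis(self.x, "x")
        self.y = _as_float_axis(self.y, "y")
        self.z = _as_float_axis(self.z, "z")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ContractError(
                f"axis lengths differ: x={len(self.x)} y={len(self.y)} z={len(self.z)}"
            )
        if len(self.y) < 1:
            raise ContractError("recording must contain at least one sample")
        if not (self.sample_rate_hz > 0):
            raise ContractError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ContractError(
                    f"non-finite sample in axis '{name}' at index {bad}; "
                    "imputation is not performed"
                )

    def __len__(self) -> int:
        return len(self.y)

    @property
    def duration_s(self) -> float:
        return len(self.y) / self.sample_rate_hz

    def axis(self, name: str) -> np.ndarray:
        """Return one axis by name ('x', 'y' or 'z')."""
        try:
            return {"x": self.x, "y": self.y, "z": self.z}[name]
        except KeyError:
            raise ContractError(f"unknown axis '{name}'") from None


@dataclass
class EpochCounts:
    """Integer activity counts per epoch for the three axes.

    With the default configuration (10 Hz output rate, 60 s epochs, clip
    ceiling 128) every count lies in [0, 76_800].
    """

    epoch_length_s: float
    start_time: datetime
    counts_x: np.ndarray
    counts_y: np.ndarray
    counts_z: np.ndarray

    def __post_init__(self) -> None:
        self.counts_x = np.asarray(self.counts_x, dtype=np.int64)
        self.counts_y = np.asarray(self.counts_y, dtype=np.int64)
        self.counts_z = np.asarray(self.counts_z, dtype=np.int64)
        if not (len(self.counts_x) == len(self.counts_y) == len(self.counts_z)):
            raise ContractError("axis count vectors must have identical length")
        for name, arr in (("x", self.counts_x), ("y", self.counts_y), ("z", self.counts_z)):
            if arr.size and arr.min() < 0:
                raise ContractError(f"negative count in axis '{name}'")

    def __len__(self) -> int:
        return len(self.counts_y)

    def epoch_timestamps(self) -> list[datetime]:
        from datetime import timedelta

        return [self.start_time + timedelta(seconds=i * self.epoch_length_s) for i in range(len(self))]


@dataclass
class WearMask:
    """Per-minute wear indicator: 1 = worn during the minute, 0 = non-wear."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.ndim != 1:
            raise ContractError("wear flags must be one-dimensional")
        if self.flags.size and not np.all((self.flags == 0) | (self.flags == 1)):
            raise ContractError("wear flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.flags)

    @property
    def wear_minutes(self) -> int:
        return int(self.flags.sum())

    @property
    def nonwear_minutes(self) -> int:
        return int(len(self.flags) - self.flags.sum())
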