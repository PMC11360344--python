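"""Raw acceleration to activity counts.

The counts algorithm is a fixed per-axis chain applied independently to x, y
and z:

1. down-sample the raw signal to 30 Hz;
2. band-pass filter (rejects gravity/DC, keeps the human-movement band);
3. rescale by 17.127404 (counts per g) and take absolute values;
4. threshold: values above 128 clip to 128, values below 4 zero out
   (the dead-band that suppresses sensor noise);
5. down-sample to 10 Hz;
6. floor each sample to an integer and sum within 60 s epochs.

With the default constants every epoch count is bounded by
128 x 10 Hz x 60 s = 76_800. Counts per minute (CPM) are exactly the epoch
sums for 60 s epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as _sig

from .errors import ContractError
from .filters import ACTIGRAPH_BANDPASS, FilterSpec
from .types import EpochCounts, RawRecording

__all__ = [
    "CountsConfig",
    "downsample_to_filter_rate",
    "bandpass",
    "scale_rectify_threshold",
    "decimate_to_output_rate",
    "epoch_sum",
    "compute_counts",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountsConfig:
    """Constants of the counts chain. Defaults reproduce the disclosed
    ActiGraph pipeline (30 Hz filter rate, 10 Hz output rate, 60 s epochs,
    scale 17.127404 counts/g, clip at 128, dead-band below 4)."""

    fs_filter: float = 30.0
    fs_decimated: float = 10.0
    epoch_length_s: float = 60.0
    scale_factor: float = 17.127404
    clip_ceiling: float = 128.0
    deadband: float = 4.0
    resampler: str = "auto"  # 'auto' | 'decimate' | 'poly'
    discard_warmup_epochs: int = 0  # optionally drop filter start-up transients

    def __post_init__(self) -> None:
        ratio = self.fs_filter / self.fs_decimated
        if abs(ratio - round(ratio)) > 1e-9:
            raise ContractError(
                f"fs_filter ({self.fs_filter}) must be an integer multiple of "
                f"fs_decimated ({self.fs_decimated})"
            )
        if not (self.clip_ceiling > self.deadband > 0):
            raise ContractError(
                f"need clip_ceiling > deadband > 0, got {self.clip_ceiling}, {self.deadband}"
            )
        if self.resampler not in ("auto", "decimate", "poly"):
            raise ContractError(f"unknown resampler '{self.resampler}'")
        if self.discard_warmup_epochs < 0:
            raise ContractError("discard_warmup_epochs must be >= 0")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs_decimated * self.epoch_length_s))

    @property
    def max_count_per_epoch(self) -> int:
        """Hard ceiling on one epoch's count (128 x 10 x 60 = 76_800 by default)."""
        return int(math.floor(self.clip_ceiling) * self.samples_per_epoch)


def downsample_to_filter_rate(
    signal: np.ndarray,
    fs_in: float,
    fs_out: float,
    method: str = "auto",
) -> np.ndarray:
    """Reduce the sampling rate from ``fs_in`` to ``fs_out``.

    When ``fs_in`` is an integer multiple of ``fs_out`` this keeps every
    (fs_in/fs_out)-th sample starting at sample 0 (plain decimation, the
    default behaviour). For non-integer ratios — or with ``method='poly'`` —
    an anti-aliased polyphase resampler is used. The output length is
    floor(n * fs_out / fs_in) in every mode.
    """
    if fs_in < fs_out:
        raise ContractError(f"cannot down-sample from {fs_in} Hz to {fs_out} Hz (fs_in < fs_out)")
    x = np.asarray(signal, dtype=np.float64)
    n_out = int(math.floor(len(x) * fs_out / fs_in))
    ratio = fs_in / fs_out
    integer_ratio = abs(ratio - round(ratio)) < 1e-9
    if method == "decimate" and not integer_ratio:
        raise ContractError(
            f"plain decimation requires an integer rate ratio, got {fs_in}/{fs_out}"
        )
    if integer_ratio and method in ("auto", "decimate"):
        step = int(round(ratio))
        if step == 1:
            return x.copy()
        return x[::step][:n_out]
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return _sig.resample_poly(x, frac.numerator, frac.denominator)[:n_out]


def bandpass(
    signal: np.ndarray,
    spec: FilterSpec = ACTIGRAPH_BANDPASS,
    initial: str = "zero",
) -> np.ndarray:
    """Apply the band-pass filter.

    ``initial='zero'`` (the default) starts from zero internal state.
    ``initial='steady'`` starts from the steady state for the first sample's
    value, as if that value had been applied forever: switching a recording
    on under constant gravity then produces no start-up excursion. The
    initial state is proportional to the first sample, so the filter stays
    linear, and a signal starting at 0 still starts from zero state. The
    full pipeline uses 'steady'; ``CountsConfig.discard_warmup_epochs``
    remains available to drop early epochs regardless.
    """
    spec.validate()
    x = np.asarray(signal, dtype=np.float64)
    if initial == "zero" or len(x) == 0:
        return _sig.lfilter(spec.b, spec.a, x)
    if initial != "steady":
        raise ContractError(f"unknown initial-state mode '{initial}'")
    zi = _sig.lfilter_zi(spec.b, spec.a) * x[0]
    out, _ = _sig.lfilter(spec.b, spec.a, x, zi=zi)
    return out


def scale_rectify_threshold(filtered: np.ndarray, cfg: CountsConfig = CountsConfig()) -> np.ndarray:
    """Rescale to count units, rectify, clip and apply the dead-band.

    Each sample becomes g(|v| * scale) with g(u) = ceiling if u > ceiling,
    0 if u < deadband, else u. Exactly ``deadband`` passes unchanged and
    exactly ``ceiling`` is not clipped (strict inequalities).
    """
    x = np.asarray(filtered, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ContractError("non-finite value in filtered signal")
    v = np.abs(x) * cfg.scale_factor
    v = np.where(v > cfg.clip_ceiling, cfg.clip_ceiling, v)
    v = np.where(v < cfg.deadband, 0.0, v)
    return v


def decimate_to_output_rate(thresholded: np.ndarray, cfg: CountsConfig = CountsConfig()) -> np.ndarray:
    """Keep every (fs_filter/fs_decimated)-th sample starting at index 0."""
    step = int(round(cfg.fs_filter / cfg.fs_decimated))
    return np.asarray(thresholded, dtype=np.float64)[::step]


def epoch_sum(decimated: np.ndarray, cfg: CountsConfig = CountsConfig()) -> np.ndarray:
    """Floor each 10 Hz sample to an integer and sum over whole epochs.

    A trailing partial epoch is dropped (and logged). Returns int64 counts.
    """
    x = np.asarray(decimated, dtype=np.float64)
    if x.size and x.min() < 0:
        raise ContractError("epoch_sum input must be non-negative")
    block = cfg.samples_per_epoch
    n_epochs = len(x) // block
    dropped = len(x) - n_epochs * block
    if dropped:
        log.info("epoch_sum: dropping trailing partial epoch of %d samples", dropped)
    whole = np.floor(x[: n_epochs * block]).astype(np.int64)
    return whole.reshape(n_epochs, block).sum(axis=1)


def _axis_counts(axis: np.ndarray, fs_in: float, cfg: CountsConfig, spec: FilterSpec) -> np.ndarray:
    method = "decimate" if cfg.resampler == "decimate" else (
        "poly" if cfg.resampler == "poly" else "auto")
    down = downsample_to_filter_rate(axis, fs_in, cfg.fs_filter, method=method)
    filt = bandpass(down, spec, initial="steady")
    thresh = scale_rectify_threshold(filt, cfg)
    dec = decimate_to_output_rate(thresh, cfg)
    return epoch_sum(dec, cfg)


def compute_counts(
    raw: RawRecording,
    cfg: CountsConfig = CountsConfig(),
    spec: FilterSpec = ACTIGRAPH_BANDPASS,
) -> EpochCounts:
    """Run the full counts chain on all three axes of a recording.

    Each axis is processed independently through the five stages above.
    A recording shorter than one epoch yields empty counts with a warning.
    """
    if raw.duration_s < cfg.epoch_length_s:
        log.warning(
            "recording (%.1f s) is shorter than one %.0f s epoch; no counts produced",
            raw.duration_s, cfg.epoch_length_s,
        )
    per_axis = {
        name: _axis_counts(raw.axis(name), raw.sample_rate_hz, cfg, spec)
        for name in ("x", "y", "z")
    }
    counts = EpochCounts(
        epoch_length_s=cfg.epoch_length_s,
        start_time=raw.start_time,
        counts_x=per_axis["x"],
        counts_y=per_axis["y"],
        counts_z=per_axis["z"],
    )
    if cfg.discard_warmup_epochs and len(counts):
        k = min(cfg.discard_warmup_epochs, len(counts))
        log.info("discarding %d warm-up epoch(s)", k)
        from datetime import timedelta

        counts = EpochCounts(
            epoch_length_s=cfg.epoch_length_s,
            start_time=counts.start_time + timedelta(seconds=k * cfg.epoch_length_s),
            counts_x=counts.counts_x[k:],
            counts_y=counts.counts_y[k:],
            counts_z=counts.counts_z[k:],
        )
    ceiling = cfg.max_count_per_epoch
    for arr in (counts.counts_x, counts.counts_y, counts.counts_z):
        assert arr.size == 0 or arr.max() <= ceiling  # structural bound of the chain
    return counts
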