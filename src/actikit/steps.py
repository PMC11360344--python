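"""Zero-crossing step detection on the band-passed vertical axis.

The step path shares the first stages of the counts path — down-sample to
30 Hz, band-pass, rescale by 17.127404 — but keeps the *signed* signal:
no rectification, clipping or dead-band. A step is one full excursion of
the filtered signal: a descent through zero reaching at or below -4 (scaled
units), followed by an ascent through zero reaching at or above +4.

Formally a two-state machine over the scaled signal:

* UNARMED: arm when the signal, having been >= 0, descends to <= -4
  ("been >= 0" holds at the start of the recording);
* ARMED: count one step and return to UNARMED when the signal, having been
  <= 0, ascends to >= +4.

Because arming requires a value <= -4 (hence <= 0) and a counted step leaves
the signal >= +4 (hence >= 0), the "having been" preconditions are satisfied
on every state entry, so detection reduces to alternately seeking the
descending and ascending thresholds, starting with the descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import bandpass, downsample_to_filter_rate
from .errors import ContractError
from .filters import ACTIGRAPH_BANDPASS, FilterSpec
from .types import RawRecording, WearMask

__all__ = ["StepConfig", "preprocess_for_steps", "detect_steps", "count_steps"]


@dataclass(frozen=True)
class StepConfig:
    fs_filter: float = 30.0
    scale_factor: float = 17.127404
    descend_threshold: float = -4.0
    ascend_threshold: float = 4.0
    axis: str = "y"

    def __post_init__(self) -> None:
        if not (self.descend_threshold < 0 < self.ascend_threshold):
            raise ContractError(
                "need descend_threshold < 0 < ascend_threshold, got "
                f"{self.descend_threshold}, {self.ascend_threshold}"
            )
        if self.axis not in ("x", "y", "z"):
            raise ContractError(f"unknown axis '{self.axis}'")


def preprocess_for_steps(
    raw_axis: np.ndarray,
    fs_in: float,
    cfg: StepConfig = StepConfig(),
    spec: FilterSpec = ACTIGRAPH_BANDPASS,
) -> np.ndarray:
    """Down-sample to 30 Hz, band-pass, and rescale — signed output.

    All three stages are linear, so superposition holds; a constant (gravity)
    input decays to zero through the band-pass. Unlike the counts path, the
    filter state is initialised to the steady state for the first sample's
    value, so switching the recording on under constant gravity produces no
    start-up excursion that the detector could mistake for a step. The
    initial state is proportional to that first sample, which preserves
    linearity, and a signal starting at zero still starts from zero state.
    """
    down = downsample_to_filter_rate(raw_axis, fs_in, cfg.fs_filter)
    return bandpass(down, spec, initial="steady") * cfg.scale_factor


def detect_steps(scaled: np.ndarray, cfg: StepConfig = StepConfig()) -> int:
    """Count steps in a signed scaled signal with the two-state machine.

    Vectorised: only samples at or beyond a threshold can change state, so
    the signal is compressed to that event sequence and walked alternately
    (descent first).
    """
    x = np.asarray(scaled, dtype=np.float64)
    if x.size and not np.all(np.isfinite(x)):
        raise ContractError("non-finite value in step-detection input")
    events = np.where(x <= cfg.descend_threshold, -1, np.where(x >= cfg.ascend_threshold, 1, 0))
    events = events[events != 0]
    if events.size == 0:
        return 0
    # Collapse repeats: consecutive identical events cannot change state.
    events = events[np.concatenate(([True], events[1:] != events[:-1]))]
    # Alternating walk starting UNARMED: the first -1 arms; each subsequent
    # +1 after a -1 is one step. After collapsing, events strictly alternate,
    # so steps = number of (-1, +1) pairs.
    if events[0] == 1:
        events = events[1:]  # a leading ascent with no prior arm is ignored
    return int(len(events) // 2)


def count_steps(
    raw: RawRecording,
    cfg: StepConfig = StepConfig(),
    spec: FilterSpec = ACTIGRAPH_BANDPASS,
    mask: WearMask | None = None,
) -> int:
    """Steps in a recording: preprocess the configured axis, then detect.

    With ``mask`` given, samples falling in non-wear minutes are zeroed in
    the scaled signal before detection, so excursions there cannot count;
    by default all minutes are counted.
    """
    scaled = preprocess_for_steps(raw.axis(cfg.axis), raw.sample_rate_hz, cfg, spec)
    if mask is not None:
        per_min = int(round(cfg.fs_filter * 60))
        for i in np.flatnonzero(mask.flags == 0):
            scaled[i * per_min : (i + 1) * per_min] = 0.0
    return detect_steps(scaled, cfg)
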