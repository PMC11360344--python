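"""End-to-end convenience: raw recording -> epoch counts -> wear mask ->
summary, wired exactly as the standard workflow (counts, then Troiano on
y-axis CPM, then Freedson categorisation and totals over wear minutes,
steps from the same band-passed vertical signal)."""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .counts import compute_counts
from .metrics import ActivitySummary, summarize
from .steps import count_steps
from .types import EpochCounts, RawRecording, WearMask
from .wear import troiano_wear_mask

__all__ = ["process_recording"]

log = logging.getLogger(__name__)


def process_recording(
    raw: RawRecording, run: RunConfig | None = None
) -> tuple[EpochCounts, WearMask, ActivitySummary]:
    """Run the full pipeline on a recording and return all three artifacts."""
    run = run or RunConfig()
    spec = run.filter_spec
    epochs = compute_counts(raw, run.counts, spec)
    if run.wear_mode == "troiano":
        mask = troiano_wear_mask(epochs.counts_y, run.troiano)
    else:
        mask = WearMask(np.ones(len(epochs), dtype=np.int8))
    steps = count_steps(raw, run.steps, spec)
    summary = summarize(epochs, mask, run.scheme, steps=steps)
    log.info(
        "processed %.1f min: %d wear min, %d steps, y-total %d",
        raw.duration_s / 60.0, summary.wear_minutes, steps, summary.total_counts_y,
    )
    return epochs, mask, summary
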