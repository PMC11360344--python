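"""Troiano (2007) non-wear detection on 60 s vertical-axis epoch counts.

A non-wear interval is at least ``min_nonwear_minutes`` (default 60)
consecutive minutes of zero counts, allowing interruptions of at most
``max_interruption_minutes`` (default 2) consecutive minutes each with counts
strictly between 0 and ``interruption_count_ceiling`` (default 100). Any
minute at or above the ceiling terminates the interval. Interpretation
choices (shared with the brute-force test oracle):

* "between 0 and 100" is strict: a count of exactly 100 terminates a window,
  a count of 0 extends it as a zero minute;
* interruption minutes inside a qualifying interval are flagged non-wear —
  the rule classifies the whole interval;
* interruptions are strictly interior: a qualifying interval starts and ends
  on a zero-count minute;
* separate interruptions are each allowed if a zero minute lies between
  them; consecutive interruption minutes count jointly against the limit;
* intervals touching the start or end of the recording qualify on length
  alone.

The mask is computed from the y (vertical) axis only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .types import EpochCounts, WearMask

__all__ = ["TroianoConfig", "troiano_wear_mask", "apply_mask"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TroianoConfig:
    min_nonwear_minutes: int = 60
    max_interruption_minutes: int = 2
    interruption_count_ceiling: int = 100

    def __post_init__(self) -> None:
        if self.min_nonwear_minutes < 1:
            raise ContractError("min_nonwear_minutes must be >= 1")
        if self.max_interruption_minutes < 0:
            raise ContractError("max_interruption_minutes must be >= 0")
        if self.interruption_count_ceiling <= 0:
            raise ContractError("interruption_count_ceiling must be > 0")


def troiano_wear_mask(cpm_y, cfg: TroianoConfig = TroianoConfig()) -> WearMask:
    """Flag each minute as wear (1) or non-wear (0) from y-axis CPM.

    A minute is non-wear iff it lies inside a maximal qualifying interval
    under the rule described in the module docstring. Linear scan: candidate
    intervals start at a zero minute and extend until a hard break (count at
    or above the ceiling, or an interruption run longer than allowed), then
    are trimmed back to their last zero minute.
    """
    cpm = np.asarray(cpm_y)
    if cpm.ndim != 1:
        raise ContractError("cpm_y must be one-dimensional")
    if cpm.size and cpm.min() < 0:
        raise ContractError("cpm_y must be non-negative")

    n = len(cpm)
    flags = np.ones(n, dtype=np.int8)
    ceiling = cfg.interruption_count_ceiling
    i = 0
    while i < n:
        if cpm[i] != 0:
            i += 1
            continue
        start = i
        last_zero = i
        run = 0
        k = i + 1
        while k < n:
            c = cpm[k]
            if c == 0:
                last_zero = k
                run = 0
            elif c < ceiling:
                run += 1
                if run > cfg.max_interruption_minutes:
                    break
            else:
                break
            k += 1
        if last_zero - start + 1 >= cfg.min_nonwear_minutes:
            flags[start : last_zero + 1] = 0
        # No zero minute in (start, k] can begin a longer interval: it would
        # hit the same hard break. Resume past the break point.
        i = k + 1

    mask = WearMask(flags)
    if mask.nonwear_minutes:
        log.info("Troiano: flagged %d of %d minutes as non-wear", mask.nonwear_minutes, n)
    return mask


def apply_mask(epochs: EpochCounts, mask: WearMask) -> tuple[EpochCounts, int]:
    """Restrict epoch counts to wear minutes.

    All three axes are filtered identically and order is preserved. Returns
    the restricted epochs and the wear time in minutes (the kept length).
    """
    if len(mask) != len(epochs):
        raise ContractError(
            f"mask length {len(mask)} != number of epochs {len(epochs)}"
        )
    keep = mask.flags.astype(bool)
    restricted = EpochCounts(
        epoch_length_s=epochs.epoch_length_s,
        start_time=epochs.start_time,
        counts_x=epochs.counts_x[keep],
        counts_y=epochs.counts_y[keep],
        counts_z=epochs.counts_z[keep],
    )
    return restricted, int(keep.sum())
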