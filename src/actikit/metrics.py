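"""Intensity categorisation, vector magnitude and method-comparison errors.

Each wear minute's CPM maps to one Freedson Adult (1998) intensity category:

====================  ===============
category              CPM (inclusive)
====================  ===============
sedentary             0 - 99
light                 100 - 1951
moderate              1952 - 5724
vigorous              5725 - 9498
very vigorous         >= 9499
====================  ===============

The boundaries anchor to MET levels (moderate ~ 3 METs). They ship as a
named, overridable :class:`CutPointScheme`.

Vector magnitude combines the three axes. Two quantities are reported: the
Euclidean norm of the axis *totals* (the headline total), and the sum over
epochs of per-epoch norms sqrt(x_i^2 + y_i^2 + z_i^2) (the conventional
per-epoch aggregate). They differ whenever activity is spread over epochs;
both are emitted, clearly named.

Percent error between two processing methods is
100 * |reference - candidate| / |reference|, displayed to 2 decimals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .types import EpochCounts, WearMask
from .wear import apply_mask

__all__ = [
    "CutPointScheme",
    "FREEDSON_ADULT_1998",
    "CATEGORIES",
    "ActivitySummary",
    "classify_cpm",
    "classify_cpm_vector",
    "vector_magnitude_total",
    "per_epoch_vector_magnitude_total",
    "summarize",
    "percent_error",
    "comparison_table",
]

log = logging.getLogger(__name__)

CATEGORIES = ("sedentary", "light", "moderate", "vigorous", "very_vigorous")


@dataclass(frozen=True)
class CutPointScheme:
    """Ordered CPM intervals partitioning [0, inf) into intensity categories.

    ``boundaries`` is a list of (label, lower, upper) with inclusive integer
    bounds; the last upper bound is None (unbounded).
    """

    name: str
    boundaries: tuple[tuple[str, int, int | None], ...]

    def __post_init__(self) -> None:
        if not self.boundaries:
            raise ContractError("cut-point scheme needs at least one interval")
        if self.boundaries[0][1] != 0:
            raise ContractError("first interval must start at 0")
        for (la, lo_a, hi_a), (lb, lo_b, hi_b) in zip(self.boundaries, self.boundaries[1:]):
            if hi_a is None or lo_b != hi_a + 1:
                raise ContractError(
                    f"intervals '{la}' and '{lb}' must abut with no gap or overlap"
                )
        if self.boundaries[-1][2] is not None:
            raise ContractError("last interval must be unbounded above")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _, _ in self.boundaries)

    def lower_bounds(self) -> np.ndarray:
        return np.array([lo for _, lo, _ in self.boundaries], dtype=np.int64)


FREEDSON_ADULT_1998 = CutPointScheme(
    name="freedson_adult_1998",
    boundaries=(
        ("sedentary", 0, 99),
        ("light", 100, 1951),
        ("moderate", 1952, 5724),
        ("vigorous", 5725, 9498),
        ("very_vigorous", 9499, None),
    ),
)


def classify_cpm(cpm: int, scheme: CutPointScheme = FREEDSON_ADULT_1998) -> str:
    """Category label of a single CPM value."""
    if cpm < 0:
        raise ContractError(f"CPM must be non-negative, got {cpm}")
    idx = int(np.searchsorted(scheme.lower_bounds(), cpm, side="right")) - 1
    return scheme.labels[idx]


def classify_cpm_vector(cpm, scheme: CutPointScheme = FREEDSON_ADULT_1998) -> np.ndarray:
    """Vectorised :func:`classify_cpm`: array of labels, one per minute."""
    arr = np.asarray(cpm, dtype=np.int64)
    if arr.size and arr.min() < 0:
        raise ContractError("CPM must be non-negative")
    idx = np.searchsorted(scheme.lower_bounds(), arr, side="right") - 1
    return np.array(scheme.labels, dtype=object)[idx]


def vector_magnitude_total(total_x: float, total_y: float, total_z: float) -> float:
    """Euclidean norm of the per-axis count totals."""
    if min(total_x, total_y, total_z) < 0:
        raise ContractError("axis totals must be non-negative")
    return float(math.sqrt(total_x**2 + total_y**2 + total_z**2))


def per_epoch_vector_magnitude_total(epochs: EpochCounts) -> float:
    """Sum over epochs of sqrt(x_i^2 + y_i^2 + z_i^2) — the per-epoch variant."""
    return float(
        np.sqrt(
            epochs.counts_x.astype(np.float64) ** 2
            + epochs.counts_y.astype(np.float64) ** 2
            + epochs.counts_z.astype(np.float64) ** 2
        ).sum()
    )


@dataclass
class ActivitySummary:
    """Totals of one processed recording, computed over wear minutes only."""

    total_counts_x: int
    total_counts_y: int
    total_counts_z: int
    vector_magnitude_total: float
    vector_magnitude_per_epoch_total: float
    total_steps: int
    wear_minutes: int
    minutes_per_category: dict[str, int]
    percent_per_category: dict[str, float]

    def __post_init__(self) -> None:
        if sum(self.minutes_per_category.values()) != self.wear_minutes:
            raise ContractError("category minutes must sum to wear minutes")
        if self.wear_minutes > 0:
            total_pct = sum(self.percent_per_category.values())
            if abs(total_pct - 100.0) > 1e-9:
                raise ContractError(f"percentages must sum to 100, got {total_pct!r}")

    def to_dict(self) -> dict:
        return {
            "total_counts_x": self.total_counts_x,
            "total_counts_y": self.total_counts_y,
            "total_counts_z": self.total_counts_z,
            "vector_magnitude_total": self.vector_magnitude_total,
            "vector_magnitude_per_epoch_total": self.vector_magnitude_per_epoch_total,
            "total_steps": self.total_steps,
            "wear_minutes": self.wear_minutes,
            "minutes_per_category": dict(self.minutes_per_category),
            "percent_per_category": dict(self.percent_per_category),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ActivitySummary":
        return cls(**{k: data[k] for k in (
            "total_counts_x", "total_counts_y", "total_counts_z",
            "vector_magnitude_total", "vector_magnitude_per_epoch_total",
            "total_steps", "wear_minutes",
            "minutes_per_category", "percent_per_category",
        )})


def summarize(
    epochs: EpochCounts,
    mask: WearMask,
    scheme: CutPointScheme = FREEDSON_ADULT_1998,
    steps: int = 0,
) -> ActivitySummary:
    """Build the activity summary from 60 s epoch counts and a wear mask.

    Non-wear minutes are removed before any total: axis totals, vector
    magnitudes, and the per-category minutes (assigned from y-axis CPM) all
    run over wear minutes only. Percentages are minutes in category / wear
    minutes x 100; with zero wear time they are reported as 0 with a warning.
    """
    worn, wear_minutes = apply_mask(epochs, mask)
    labels = classify_cpm_vector(worn.counts_y, scheme)
    minutes = {lbl: int(np.sum(labels == lbl)) for lbl in scheme.labels}
    if wear_minutes > 0:
        percents = {lbl: 100.0 * m / wear_minutes for lbl, m in minutes.items()}
    else:
        log.warning("zero wear minutes: category percentages undefined, reporting 0")
        percents = {lbl: 0.0 for lbl in scheme.labels}
    tx = int(worn.counts_x.sum())
    ty = int(worn.counts_y.sum())
    tz = int(worn.counts_z.sum())
    return ActivitySummary(
        total_counts_x=tx,
        total_counts_y=ty,
        total_counts_z=tz,
        vector_magnitude_total=vector_magnitude_total(tx, ty, tz),
        vector_magnitude_per_epoch_total=per_epoch_vector_magnitude_total(worn),
        total_steps=int(steps),
        wear_minutes=wear_minutes,
        minutes_per_category=minutes,
        percent_per_category=percents,
    )


def percent_error(reference: float, candidate: float) -> float:
    """100 * |reference - candidate| / |reference|; NaN when reference is 0."""
    if reference == 0:
        return float("nan")
    return 100.0 * abs(reference - candidate) / abs(reference)


def _metric_rows(summary: Mapping) -> dict[str, float]:
    """Flatten a summary mapping into the standard comparison-report rows."""
    rows = {
        "total_y_axis_counts": summary["total_counts_y"],
        "total_vector_magnitude_counts": summary["vector_magnitude_total"],
        "total_step_counts": summary["total_steps"],
    }
    minutes = summary["minutes_per_category"]
    for cat in CATEGORIES:
        rows[f"minutes_{cat}"] = minutes.get(cat, 0)
    return rows


def comparison_table(
    summary_a: Mapping | Sequence[Mapping],
    summary_b: Mapping | Sequence[Mapping],
    mode: str = "error_of_means",
) -> pd.DataFrame:
    """Side-by-side comparison of two processing methods.

    ``summary_a``/``summary_b`` are single summary mappings or parallel
    sequences of per-recording summaries. Rows follow the conventional
    report order (y-axis counts, vector magnitude, steps, category minutes).

    mode='error_of_means' compares the means of the two methods;
    mode='mean_of_errors' averages per-recording percent errors, which can
    differ from the error of the means when recordings vary.
    """
    if mode not in ("error_of_means", "mean_of_errors"):
        raise ContractError(f"unknown comparison mode '{mode}'")
    seq_a = [summary_a] if isinstance(summary_a, Mapping) else list(summary_a)
    seq_b = [summary_b] if isinstance(summary_b, Mapping) else list(summary_b)
    if len(seq_a) != len(seq_b):
        raise ContractError("method A and B need the same number of summaries")
    rows_a = [_metric_rows(s) for s in seq_a]
    rows_b = [_metric_rows(s) for s in seq_b]
    keys = list(rows_a[0])
    for r in rows_a + rows_b:
        missing = [k for k in keys if k not in r]
        if missing:
            raise ContractError(f"summaries missing metric keys: {missing}")

    records = []
    for key in keys:
        va = np.array([r[key] for r in rows_a], dtype=float)
        vb = np.array([r[key] for r in rows_b], dtype=float)
        mean_a, mean_b = va.mean(), vb.mean()
        if mode == "error_of_means":
            err = percent_error(mean_a, mean_b)
        else:
            per_unit = [percent_error(a, b) for a, b in zip(va, vb)]
            err = float(np.nanmean(per_unit)) if per_unit else float("nan")
        records.append(
            {
                "metric": key,
                "method_a": round(mean_a, 1),
                "method_b": round(mean_b, 1),
                "percent_error": round(err, 2) if math.isfinite(err) else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records, columns=["metric", "method_a", "method_b", "percent_error"])
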