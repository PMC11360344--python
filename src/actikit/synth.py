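"""Seeded synthetic raw recordings with ground truth.

The generator emulates the salient features of a free-living waist-worn
recording so every pipeline stage can be exercised without device data:

* ``nonwear_still`` — device off-body/perfectly still: exactly (0, 1, 0) g
  (gravity on the vertical y axis), producing zero counts and letting the
  Troiano rule fire;
* ``sedentary`` — worn but inactive: gravity plus small Gaussian noise;
* ``walk`` — gait bout: a single sinusoid at the step frequency on y (one
  full cycle per step, so the true step count is exact) plus small noise;
* ``vigorous`` — high-intensity bout: larger multi-harmonic oscillation.

Segments are concatenated in order; identical protocol + seed yields
bit-identical output. Ground truth carries per-minute intent labels, the
true step count (sum over walk segments of round(step_frequency x
duration)), and the segment table with start offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .errors import ContractError, FormatError
from .types import RawRecording

__all__ = [
    "Segment",
    "SyntheticProtocol",
    "GroundTruth",
    "generate_recording",
    "write_protocol",
    "read_protocol",
    "write_ground_truth",
    "read_ground_truth",
]

SEGMENT_KINDS = ("nonwear_still", "sedentary", "walk", "vigorous")

# Intent label of each segment kind in the ground truth.
_KIND_LABEL = {
    "nonwear_still": "nonwear",
    "sedentary": "sedentary",
    "walk": "moderate",
    "vigorous": "vigorous",
}

_DEFAULT_START = datetime(2021, 6, 1, 0, 0, 0)


@dataclass(frozen=True)
class Segment:
    """One protocol segment. Amplitudes are in g; noise is the per-axis
    Gaussian standard deviation in g."""

    kind: str
    duration_s: float
    amplitude_g: float = 0.0
    noise_sd_g: float = 0.0
    step_frequency_hz: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ContractError(f"unknown segment kind '{self.kind}'")
        if not (self.duration_s > 0):
            raise ContractError(f"segment duration must be > 0, got {self.duration_s}")
        if self.noise_sd_g < 0:
            raise ContractError("noise_sd_g must be >= 0")
        if self.amplitude_g < 0:
            raise ContractError("amplitude_g must be >= 0")
        if self.kind == "walk":
            f = self.step_frequency_hz
            if f is None or not (0.5 < f < 3.5):
                raise ContractError(
                    f"walk segments need step_frequency_hz in (0.5, 3.5), got {f}"
                )


def still(duration_s: float) -> Segment:
    return Segment("nonwear_still", duration_s)


def sedentary(duration_s: float, noise_sd_g: float = 0.02) -> Segment:
    return Segment("sedentary", duration_s, noise_sd_g=noise_sd_g)


def walk(
    duration_s: float,
    step_frequency_hz: float = 2.0,
    amplitude_g: float = 0.35,
    noise_sd_g: float = 0.01,
) -> Segment:
    return Segment("walk", duration_s, amplitude_g, noise_sd_g, step_frequency_hz)


def vigorous(
    duration_s: float,
    amplitude_g: float = 1.0,
    base_frequency_hz: float = 2.5,
    noise_sd_g: float = 0.03,
) -> Segment:
    return Segment("vigorous", duration_s, amplitude_g, noise_sd_g, base_frequency_hz)


@dataclass(frozen=True)
class SyntheticProtocol:
    segments: tuple[Segment, ...]
    sample_rate_hz: float = 60.0
    seed: int | None = 0  # None = caller must draw one before generating
    start_time: datetime = _DEFAULT_START

    def __post_init__(self) -> None:
        if not self.segments:
            raise ContractError("protocol needs at least one segment")
        if not (self.sample_rate_hz > 0):
            raise ContractError("sample_rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


@dataclass
class GroundTruth:
    """Per-minute intent labels, true step count, and the segment plan."""

    per_minute_labels: list[str]
    true_steps: int
    segment_table: list[dict]
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_minute_labels": list(self.per_minute_labels),
            "true_steps": self.true_steps,
            "segment_table": list(self.segment_table),
            "seed": self.seed,
        }


def _segment_samples(seg: Segment, fs: float, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) array of x, y, z acceleration in g for one segment."""
    n = int(round(seg.duration_s * fs))
    t = np.arange(n) / fs
    out = np.zeros((n, 3))
    out[:, 1] = 1.0  # gravity on the vertical axis
    if seg.kind == "nonwear_still":
        return out
    if seg.kind == "walk":
        out[:, 1] += seg.amplitude_g * np.sin(2 * np.pi * seg.step_frequency_hz * t)
    elif seg.kind == "vigorous":
        f = seg.step_frequency_hz if seg.step_frequency_hz else 2.5
        out[:, 1] += seg.amplitude_g * (
            np.sin(2 * np.pi * f * t) + 0.5 * np.sin(4 * np.pi * f * t)
        )
        out[:, 0] += 0.4 * seg.amplitude_g * np.sin(2 * np.pi * f * t + 1.0)
        out[:, 2] += 0.3 * seg.amplitude_g * np.sin(2 * np.pi * f * t + 2.0)
    if seg.noise_sd_g > 0:
        out += rng.normal(0.0, seg.noise_sd_g, size=out.shape)
    return out


def generate_recording(protocol: SyntheticProtocol) -> tuple[RawRecording, GroundTruth]:
    """Render a protocol into a raw recording plus its ground truth.

    Deterministic per (protocol, seed). Minute labels follow the segment
    occupying the majority of each whole minute (earliest segment wins ties);
    trailing partial minutes are not labelled.
    """
    if protocol.seed is None:
        raise ContractError("protocol seed is unset; draw one before generating")
    fs = protocol.sample_rate_hz
    rng = np.random.default_rng(protocol.seed)
    chunks = []
    table = []
    offset_s = 0.0
    true_steps = 0
    for seg in protocol.segments:
        chunks.append(_segment_samples(seg, fs, rng))
        entry = {"kind": seg.kind, "start_s": offset_s, "duration_s": seg.duration_s,
                 "amplitude_g": seg.amplitude_g, "noise_sd_g": seg.noise_sd_g}
        if seg.kind == "walk":
            entry["step_frequency_hz"] = seg.step_frequency_hz
            true_steps += int(round(seg.step_frequency_hz * seg.duration_s))
        table.append(entry)
        offset_s += seg.duration_s
    data = np.concatenate(chunks, axis=0)
    recording = RawRecording(
        sample_rate_hz=fs,
        start_time=protocol.start_time,
        x=data[:, 0], y=data[:, 1], z=data[:, 2],
    )

    n_minutes = int(len(data) // (fs * 60))
    labels = []
    for m in range(n_minutes):
        lo, hi = m * 60.0, (m + 1) * 60.0
        best_label, best_overlap = "sedentary", -1.0
        for entry in table:
            s0 = entry["start_s"]
            s1 = s0 + entry["duration_s"]
            overlap = min(hi, s1) - max(lo, s0)
            if overlap > best_overlap + 1e-9:
                best_overlap = overlap
                best_label = _KIND_LABEL[entry["kind"]]
        labels.append(best_label)

    truth = GroundTruth(
        per_minute_labels=labels,
        true_steps=true_steps,
        segment_table=table,
        seed=protocol.seed,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Protocol JSON round-trip

def write_protocol(protocol: SyntheticProtocol, path: str | Path) -> None:
    doc = {
        "sample_rate_hz": protocol.sample_rate_hz,
        "seed": protocol.seed,
        "start_time": protocol.start_time.isoformat(),
        "segments": [
            {k: v for k, v in {
                "kind": s.kind,
                "duration_s": s.duration_s,
                "amplitude_g": s.amplitude_g,
                "noise_sd_g": s.noise_sd_g,
                "step_frequency_hz": s.step_frequency_hz,
            }.items() if v is not None}
            for s in protocol.segments
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise FormatError(f"protocol JSON: missing field '{key}' in {context}")
    return mapping[key]


def read_protocol(path: str | Path) -> SyntheticProtocol:
    """Load a protocol JSON; schema violations name the offending field."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"protocol JSON is not valid JSON: {exc}") from None
    segments = []
    raw_segments = _require(doc, "segments", "protocol")
    if not isinstance(raw_segments, list) or not raw_segments:
        raise FormatError("protocol JSON: 'segments' must be a non-empty list")
    for i, seg in enumerate(raw_segments):
        ctx = f"segments[{i}]"
        kind = _require(seg, "kind", ctx)
        duration = _require(seg, "duration_s", ctx)
        try:
            segments.append(
                Segment(
                    kind=kind,
                    duration_s=duration,
                    amplitude_g=seg.get("amplitude_g", 0.0),
                    noise_sd_g=seg.get("noise_sd_g", 0.0),
                    step_frequency_hz=seg.get("step_frequency_hz"),
                )
            )
        except ContractError as exc:
            raise FormatError(f"protocol JSON: invalid {ctx}: {exc}") from None
    start_raw = doc.get("start_time")
    start = datetime.fromisoformat(start_raw) if start_raw else _DEFAULT_START
    try:
        return SyntheticProtocol(
            segments=tuple(segments),
            sample_rate_hz=doc.get("sample_rate_hz", 60.0),
            seed=int(doc["seed"]) if "seed" in doc else None,
            start_time=start,
        )
    except ContractError as exc:
        raise FormatError(f"protocol JSON: {exc}") from None


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return GroundTruth(
        per_minute_labels=list(_require(doc, "per_minute_labels", "ground truth")),
        true_steps=int(_require(doc, "true_steps", "ground truth")),
        segment_table=list(doc.get("segment_table", [])),
        seed=int(doc.get("seed", 0)),
    )
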