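"""Selection of analyzable sleep segments from an annotated recording.

Only sleep-annotated time is analyzed. Ictal intervals are excluded
together with 60 s of padding on each side, and so are annotated artifact
spans and bad channels. The remaining per-channel time is tiled greedily
into 2-min windows; a final remainder is kept when it is at least 30 s.
Subjects with less than 5 min of analyzable sleep are flagged
non-analyzable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _intervals as iv
from .recording import Recording

SEGMENT_MIN_S = 30.0
SEGMENT_MAX_S = 120.0
ICTAL_PAD_S = 60.0
MIN_ANALYZABLE_MIN = 5.0


@dataclass
class AnalysisSegment:
    """One bipolar-channel time window eligible for detection."""

    bipolar_channel: str
    start_s: float
    end_s: float
    samples: np.ndarray
    fs: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SubjectSelectionReport:
    subject_id: str
    total_sleep_min: float
    analyzed_min: float
    n_bipolar_channels_analyzed: int
    excluded_reasons: Counter = field(default_factory=Counter)

    @property
    def analyzable(self) -> bool:
        return self.analyzed_min >= MIN_ANALYZABLE_MIN

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "total_sleep_min": self.total_sleep_min,
            "analyzed_min": self.analyzed_min,
            "n_bipolar_channels_analyzed": self.n_bipolar_channels_analyzed,
            "analyzable": self.analyzable,
            "excluded_reasons": dict(self.excluded_reasons),
        }


def _tile(interval: tuple[float, float]) -> list[tuple[float, float]]:
    """Greedy 2-min tiling; keep a final remainder only if >= 30 s."""
    s, e = interval
    windows = []
    while e - s >= SEGMENT_MAX_S:
        windows.append((s, s + SEGMENT_MAX_S))
        s += SEGMENT_MAX_S
    if e - s >= SEGMENT_MIN_S:
        windows.append((s, e))
    return windows


def select_segments(
    recording: Recording, subject_id: str = "subject"
) -> tuple[list[AnalysisSegment], SubjectSelectionReport]:
    """Apply the sleep/ictal/bad-channel exclusion rules and tile windows.

    Operates on a bipolar (or otherwise re-referenced) recording whose
    annotations are already expressed in its channel labels.
    """
    reasons: Counter = Counter()
    sleep = iv.normalize(recording.intervals("sleep"))
    ictal_padded = iv.pad(recording.intervals("ictal"), ICTAL_PAD_S)

    usable_common = iv.subtract(sleep, ictal_padded)
    if sleep and not usable_common:
        reasons["ictal_exclusion"] += 1

    segments: list[AnalysisSegment] = []
    per_channel_intervals: dict[str, list[tuple[float, float]]] = {}
    for label in recording.channel_labels:
        bad = recording.intervals("bad_channel", channel=label)
        if iv.total(bad) > 0:
            reasons["bad_channel"] += 1
            continue
        artifact = recording.intervals("artifact_span", channel=label)
        usable = iv.subtract(usable_common, artifact)
        windows = [w for interval in usable for w in _tile(interval)]
        if not windows:
            continue
        per_channel_intervals[label] = windows
        idx = recording.channel_index(label)
        for ws, we in windows:
            i0 = int(round(ws * recording.fs))
            i1 = int(round(we * recording.fs))
            segments.append(
                AnalysisSegment(
                    bipolar_channel=label,
                    start_s=ws,
                    end_s=we,
                    samples=recording.samples[idx, i0:i1],
                    fs=recording.fs,
                )
            )

    # analyzed time = union over channels of segment windows
    all_windows = [w for ws in per_channel_intervals.values() for w in ws]
    analyzed_min = iv.total(all_windows) / 60.0
    report = SubjectSelectionReport(
        subject_id=subject_id,
        total_sleep_min=iv.total(sleep) / 60.0,
        analyzed_min=analyzed_min,
        n_bipolar_channels_analyzed=len(per_channel_intervals),
        excluded_reasons=reasons,
    )
    if not report.analyzable:
        reasons["insufficient_sleep"] += 1
    return segments, report


def analyzed_channel_minutes(segments: list[AnalysisSegment]) -> dict[str, float]:
    """Total analyzed minutes per bipolar channel."""
    out: dict[str, float] = {}
    for seg in segments:
        out[seg.bipolar_channel] = out.get(seg.bipolar_channel, 0.0) + seg.duration_s / 60.0
    return out
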