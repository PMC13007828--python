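"""In-memory container for a multichannel scalp EEG recording.

All signal amplitudes are in microvolts (uV) and all times in seconds.
Annotations carry the interval labels the segment-selection logic consumes:
``sleep``, ``ictal``, ``bad_channel`` and ``artifact_span``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ANNOTATION_LABELS = ("sleep", "ictal", "bad_channel", "artifact_span")


@dataclass(frozen=True)
class Annotation:
    """One labeled time interval, optionally restricted to a channel.

    ``channel=None`` means the annotation applies to every channel.
    """

    label: str
    channel: str | None
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(
                f"unknown annotation label {self.label!r}; "
                f"expected one of {ANNOTATION_LABELS}"
            )
        if not self.end_s > self.start_s:
            raise ValueError(
                f"annotation interval must have end > start, got "
                f"[{self.start_s}, {self.end_s}]"
            )


@dataclass
class Recording:
    """Multichannel EEG: ``samples`` is (n_channels, n_times) in uV."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for ann in self.annotations:
            if ann.end_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"annotation {ann} extends past recording end "
                    f"({self.duration_s:.3f} s)"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording "
                f"(have {self.channel_labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            channel_labels=list(self.channel_labels),
            annotations=list(self.annotations),
        )

    def intervals(self, label: str, channel: str | None = None) -> list[tuple[float, float]]:
        """All annotated intervals with ``label`` that apply to ``channel``.

        Channel-specific annotations are included only when they match
        ``channel``; global annotations (``channel=None``) always apply.
        """
        out = []
        for ann in self.annotations:
            if ann.label != label:
                continue
            if ann.channel is None or channel is None or ann.channel == channel:
                out.append((ann.start_s, ann.end_s))
        return sorted(out)
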