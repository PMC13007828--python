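"""Synthetic neonatal scalp EEG and cohort rate tables.

Two levels of simulation:

* **Signal level** — colored (1/f^beta) Gaussian background at >= 1 kHz
  with transient ripple-band oscillations (Tukey-windowed sinusoids) and
  labeled artifacts (broadband jumps, 110-140 Hz muscle bursts,
  high-amplitude ripple-like transients) placed by a homogeneous Poisson
  process per channel. Every injected event is returned in a ground-truth
  ledger so detector sensitivity and false-detection rates can be scored.

* **Cohort level** — per-subject HFA rates (events/min/channel) drawn from
  gamma (default) or lognormal distributions moment-matched to the group
  means/SDs of the clinical study being emulated, with group labels
  (seizure/healthy, etiology, EEG background grade, hypothermia, 1-year
  outcome) attached so the full statistical analysis plan can run.

Event amplitudes are peak-to-peak in uV. Injected ripple amplitude is
calibrated per channel from a target SNR: the detector defines SNR as the
ripple-band envelope peak of the event over the median ripple-band
envelope of the background, so an event injected at SNR s has peak-to-peak
amplitude ``2 * s * median_envelope``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from . import filters
from .recording import Annotation, Recording

RIPPLE_KIND = "ripple"
ARTIFACT_KINDS = ("jump_artifact", "muscle_artifact", "high_amplitude_transient")


class SimSpecError(ValueError):
    """Invalid simulation specification."""


class PlacementError(RuntimeError):
    """Raised when non-overlapping event placement is infeasible."""


@dataclass(frozen=True)
class SignalSimSpec:
    """Parameters of one simulated recording.

    Defaults emulate the acquisition and event statistics the detector is
    designed for: 1024 Hz sampling, 24 (bipolar-equivalent) channels,
    steep 1/f^2 background typical of neonatal sleep EEG scaled to 20 uV
    RMS, ripples at 0.2 events/min/channel with SNR 8-12 (peak-to-peak
    well below the 40 uV artifact ceiling), and sparse artifacts.
    """

    duration_s: float = 600.0
    n_channels: int = 24
    fs: float = 1024.0
    background_exponent: float = 2.0
    background_rms: float = 20.0
    background_floor_rms: float = 1.0  # white (amplifier/tonic-EMG) floor
    event_rate: float = 0.2  # ripples per minute per channel
    event_freq_range: tuple[float, float] = (100.0, 200.0)
    event_duration_range: tuple[float, float] = (40.0, 80.0)  # ms
    event_snr_range: tuple[float, float] = (8.0, 12.0)
    artifact_rates: dict = field(
        default_factory=lambda: {
            "jump_artifact": 0.05,
            "muscle_artifact": 0.1,
            "high_amplitude_transient": 0.05,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise SimSpecError("duration and fs must be positive")
        if self.fs < 1000:
            raise SimSpecError(
                f"fs must be >= 1000 Hz for ripple-band analysis, got {self.fs}"
            )
        lo, hi = self.event_freq_range
        if not (80.0 <= lo < hi <= 250.0):
            raise SimSpecError(
                f"event_freq_range must lie within [80, 250] Hz, got {self.event_freq_range}"
            )
        if self.event_rate < 0 or any(r < 0 for r in self.artifact_rates.values()):
            raise SimSpecError("all event rates must be >= 0")
        if self.n_channels < 1:
            raise SimSpecError("need at least one channel")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected event, sufficient for detector scoring."""

    channel: str
    onset_s: float
    offset_s: float
    center_freq: float
    n_cycles: int
    amplitude: float  # peak-to-peak uV
    kind: str
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise SimSpecError("event offset must exceed onset")
        if self.kind == RIPPLE_KIND:
            if self.offset_s - self.onset_s < 0.020 or self.n_cycles < 4:
                raise SimSpecError(
                    "ripple events must last >= 20 ms and contain >= 4 cycles"
                )
        elif self.kind not in ARTIFACT_KINDS:
            raise SimSpecError(f"unknown event kind {self.kind!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def generate_background(spec: SignalSimSpec, rng: np.random.Generator | None = None) -> Recording:
    """Zero-mean colored Gaussian noise with PSD proportional to f^-beta.

    Spectral shaping is flat below 0.5 Hz (the slope applies from 0.5 Hz
    up) so the variance stays finite for steep exponents; each channel is
    scaled to ``background_rms``. A white noise floor of
    ``background_floor_rms`` emulates amplifier noise and tonic EMG,
    which dominate real scalp recordings at ripple-band frequencies.
    The whole recording carries one sleep annotation by default.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    shaping = np.ones_like(freqs)
    above = freqs > 0.5
    shaping[above] = (freqs[above] / 0.5) ** (-spec.background_exponent / 2.0)
    shaping[0] = 0.0  # zero mean
    samples = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        white = rng.normal(size=n)
        colored = np.fft.irfft(np.fft.rfft(white) * shaping, n=n)
        sd = colored.std()
        if sd > 0:
            colored *= spec.background_rms / sd
        if spec.background_floor_rms > 0:
            colored += rng.normal(scale=spec.background_floor_rms, size=n)
        samples[ch] = colored
    labels = [f"ch{c + 1:02d}" for c in range(spec.n_channels)]
    return Recording(
        samples=samples,
        fs=spec.fs,
        channel_labels=labels,
        annotations=[Annotation("sleep", None, 0.0, n / spec.fs)],
    )


def _ripple_template(
    fs: float, duration_s: float, freq: float, amplitude_p2p: float,
    phase: float = 0.0, taper: float = 0.25,
) -> np.ndarray:
    n = max(int(round(duration_s * fs)), 2)
    t = np.arange(n) / fs
    return (amplitude_p2p / 2.0) * tukey(n, taper) * np.sin(2 * np.pi * freq * t + phase)


def _event_slice(recording: Recording, event: GroundTruthEvent) -> tuple[int, int, int]:
    if event.onset_s < 0 or event.offset_s > recording.duration_s + 1e-9:
        raise SimSpecError(
            f"event [{event.onset_s:.3f}, {event.offset_s:.3f}] s outside "
            f"recording of {recording.duration_s:.3f} s"
        )
    ch = recording.channel_index(event.channel)
    i0 = int(round(event.onset_s * recording.fs))
    i1 = int(round(event.offset_s * recording.fs))
    return ch, i0, i1


def inject_ripple(
    recording: Recording, event: GroundTruthEvent, copy: bool = True,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Add a Tukey-windowed sinusoid on the event's channel and interval."""
    if event.kind != RIPPLE_KIND:
        raise SimSpecError(f"inject_ripple got kind {event.kind!r}")
    out = recording.copy() if copy else recording
    ch, i0, i1 = _event_slice(out, event)
    phase = rng.uniform(0, 2 * np.pi) if rng is not None else 0.0
    template = _ripple_template(
        out.fs, event.duration_s, event.center_freq, event.amplitude, phase
    )
    out.samples[ch, i0 : i0 + len(template)] += template
    return out


def inject_artifact(
    recording: Recording, event: GroundTruthEvent, copy: bool = True,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Add one artifact of the event's kind.

    jump_artifact: rectangular baseline shift of `amplitude` uV spanning
    the event (sharp broadband edges at onset and offset).
    muscle_artifact: Tukey-windowed noise burst band-limited to 110-140 Hz,
    scaled so its peak-to-peak is ~`amplitude`.
    high_amplitude_transient: ripple-like oscillation whose peak-to-peak
    amplitude is at or above the 40 uV rejection ceiling.
    """
    if event.kind not in ARTIFACT_KINDS:
        raise SimSpecError(f"inject_artifact got kind {event.kind!r}")
    out = recording.copy() if copy else recording
    ch, i0, i1 = _event_slice(out, event)
    n = max(i1 - i0, 2)
    if event.kind == "jump_artifact":
        out.samples[ch, i0:i1] += event.amplitude
    elif event.kind == "muscle_artifact":
        rng = rng if rng is not None else np.random.default_rng(0)
        burst = rng.normal(size=n)
        # band-limit by FFT masking to 110-140 Hz
        spec = np.fft.rfft(burst)
        f = np.fft.rfftfreq(n, d=1.0 / out.fs)
        spec[(f < 110) | (f > 140)] = 0.0
        burst = np.fft.irfft(spec, n=n) * tukey(n, 0.25)
        p2p = burst.max() - burst.min()
        if p2p > 0:
            burst *= event.amplitude / p2p
        out.samples[ch, i0:i1] += burst
    else:  # high_amplitude_transient
        if event.amplitude < 40.0:
            raise SimSpecError(
                "high_amplitude_transient must have peak-to-peak >= 40 uV"
            )
        template = _ripple_template(
            out.fs, event.duration_s, event.center_freq, event.amplitude
        )
        out.samples[ch, i0 : i0 + len(template)] += template
    return out


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    duration_s: float,
    event_dur_s: callable,
    occupied: list[tuple[float, float]],
    guard_s: float = 0.25,
    edge_s: float = 1.0,
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Uniform placement with rejection of overlaps (guard gap between events)."""
    placed = []
    for _ in range(n_events):
        dur = event_dur_s()
        for _try in range(max_tries):
            onset = rng.uniform(edge_s, duration_s - edge_s - dur)
            iv = (onset - guard_s, onset + dur + guard_s)
            if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
                occupied.append(iv)
                placed.append((onset, onset + dur))
                break
        else:
            raise PlacementError(
                f"could not place event of {dur:.3f} s without overlap after "
                f"{max_tries} tries (rates too high for {duration_s:.0f} s)"
            )
    return placed


def generate_recording(
    spec: SignalSimSpec,
) -> tuple[Recording, list[GroundTruthEvent]]:
    """Background plus Poisson-placed ripples and artifacts per channel.

    Ripple amplitudes are calibrated from the drawn SNR and the channel's
    measured ripple-band envelope median, so the ground-truth SNR matches
    the detector's definition. Returns the recording and the event ledger.
    """
    rng = np.random.default_rng(spec.seed)
    rec = generate_background(spec, rng)
    minutes = spec.duration_s / 60.0
    taps = filters.design_ripple_fir(spec.fs)
    events: list[GroundTruthEvent] = []
    occupied: dict[str, list[tuple[float, float]]] = {
        label: [] for label in rec.channel_labels
    }

    env_medians = {
        label: float(np.median(filters.ripple_envelope(rec.channel(label), taps)))
        for label in rec.channel_labels
    }

    # ripples: Poisson per channel at event_rate per minute per channel
    for label in rec.channel_labels:
        n_rip = rng.poisson(spec.event_rate * minutes)
        placed = _place_events(
            rng, n_rip, spec.duration_s,
            lambda: rng.uniform(*spec.event_duration_range) / 1000.0,
            occupied[label],
        )
        for onset, offset in placed:
            freq = rng.uniform(*spec.event_freq_range)
            dur = offset - onset
            # guarantee >= 4 cycles (and hence >= 20 ms at ripple freqs)
            min_dur = 4.0 / freq * 1.05
            if dur < min_dur:
                offset = onset + min_dur
                dur = min_dur
            snr = rng.uniform(*spec.event_snr_range)
            amp = 2.0 * snr * env_medians[label]
            ev = GroundTruthEvent(
                channel=label, onset_s=onset, offset_s=offset,
                center_freq=freq, n_cycles=int(freq * dur),
                amplitude=amp, kind=RIPPLE_KIND, snr=snr,
            )
            inject_ripple(rec, ev, copy=False, rng=rng)
            events.append(ev)

    # artifacts: Poisson at the per-recording rates. Jumps and
    # high-amplitude transients are focal (one random channel); muscle
    # bursts are myogenic and hit every channel simultaneously.
    art_durs = {
        "jump_artifact": (0.1, 0.3),
        "muscle_artifact": (0.2, 0.5),
        "high_amplitude_transient": (0.04, 0.08),
    }
    for kind, rate in spec.artifact_rates.items():
        durs = art_durs[kind]
        n_art = rng.poisson(rate * minutes)
        for _ in range(n_art):
            if kind == "muscle_artifact":
                # must avoid events on every channel
                merged = [iv for ivs in occupied.values() for iv in ivs]
                (onset, offset), = _place_events(
                    rng, 1, spec.duration_s, lambda: rng.uniform(*durs), merged
                )
                for label in rec.channel_labels:
                    occupied[label].append((onset - 0.25, offset + 0.25))
                    amp = rng.uniform(20.0, 60.0) * rng.uniform(0.5, 1.0)
                    ev = GroundTruthEvent(
                        channel=label, onset_s=onset, offset_s=offset,
                        center_freq=125.0, n_cycles=max(int(125 * (offset - onset)), 1),
                        amplitude=amp, kind=kind,
                    )
                    inject_artifact(rec, ev, copy=False, rng=rng)
                    events.append(ev)
            else:
                label = rec.channel_labels[rng.integers(len(rec.channel_labels))]
                (onset, offset), = _place_events(
                    rng, 1, spec.duration_s, lambda: rng.uniform(*durs),
                    occupied[label],
                )
                freq = rng.uniform(*spec.event_freq_range)
                amp = (
                    rng.uniform(100.0, 300.0)
                    if kind == "jump_artifact"
                    else rng.uniform(45.0, 80.0)
                )
                ev = GroundTruthEvent(
                    channel=label, onset_s=onset, offset_s=offset,
                    center_freq=freq, n_cycles=max(int(freq * (offset - onset)), 1),
                    amplitude=amp, kind=kind,
                )
                inject_artifact(rec, ev, copy=False, rng=rng)
                events.append(ev)

    events.sort(key=lambda e: (e.channel, e.onset_s))
    return rec, events


def events_to_frame(events: list[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": e.channel, "onset_s": e.onset_s, "offset_s": e.offset_s,
                "kind": e.kind, "center_freq": e.center_freq,
                "amplitude": e.amplitude, "snr": e.snr,
            }
            for e in events
        ],
        columns=["channel", "onset_s", "offset_s", "kind", "center_freq", "amplitude", "snr"],
    )


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

#: Per-group HFA-rate summary statistics (n, mean, SD in events/min/channel)
#: of the clinical cohort the simulator emulates.
REFERENCE_GROUP_MOMENTS: dict[str, tuple[int, float, float]] = {
    "seizure": (47, 0.16, 0.15),
    "healthy": (8, 0.03, 0.02),
    "HIE": (16, 0.15, 0.14),
    "SVL": (14, 0.07, 0.05),
    "genetic": (14, 0.24, 0.19),
    "hie_cooled": (8, 0.17, 0.14),
    "hie_uncooled": (8, 0.14, 0.13),
    "bg_normal": (12, 0.15, 0.14),
    "bg_mild_moderate": (26, 0.16, 0.15),
    "bg_severe": (9, 0.16, 0.14),
    "pne": (11, 0.27, 0.18),
    "normal_dev": (16, 0.11, 0.09),
    "term": (41, 0.15, 0.14),
    "preterm": (6, 0.20, 0.17),
    "died": (9, 0.10, 0.11),
}


@dataclass(frozen=True)
class GroupSpec:
    """One simulated subject group: size, rate moments, and fixed labels."""

    n_subjects: int
    rate_mean: float
    rate_sd: float
    distribution_family: str = "gamma"  # gamma | lognormal | fixed
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise SimSpecError("n_subjects must be >= 0")
        if self.distribution_family not in ("gamma", "lognormal", "fixed"):
            raise SimSpecError(
                f"unknown distribution family {self.distribution_family!r}"
            )
        if self.distribution_family != "fixed":
            if self.rate_mean <= 0 or self.rate_sd <= 0:
                raise SimSpecError(
                    "rate_mean and rate_sd must be > 0 for a stochastic family"
                )
        elif self.rate_mean < 0:
            raise SimSpecError("fixed rate must be >= 0")


@dataclass(frozen=True)
class CohortSimSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0


def _draw_rates(g: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    if g.n_subjects == 0:
        return np.empty(0)
    if g.distribution_family == "fixed":
        return np.full(g.n_subjects, g.rate_mean)
    if g.distribution_family == "gamma":
        shape = (g.rate_mean / g.rate_sd) ** 2
        scale = g.rate_sd**2 / g.rate_mean
        return rng.gamma(shape, scale, size=g.n_subjects)
    # lognormal moment match
    sigma2 = np.log(1.0 + (g.rate_sd / g.rate_mean) ** 2)
    mu = np.log(g.rate_mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=g.n_subjects)


LABEL_COLUMNS = ["group", "etiology", "background_grade", "hypothermia", "outcome", "term"]


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Sample per-subject HFA rates for every group in the spec.

    Returns a table with ``subject_id``, ``rate`` and whatever label
    columns the group specs provide (missing labels filled with the
    "none"/NA conventions of the study cohort schema).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for g in spec.groups:
        rates = _draw_rates(g, rng)
        for r in rates:
            row = {"subject_id": f"s{sid:03d}", "rate": float(r)}
            row.update(g.labels)
            rows.append(row)
            sid += 1
    cols = ["subject_id", "rate"] + [
        c for c in LABEL_COLUMNS if any(c in r for r in rows)
    ]
    return pd.DataFrame(rows, columns=cols)


def two_group_spec(
    name_a: str, name_b: str, seed: int = 0,
    label_column: str = "group",
) -> CohortSimSpec:
    """Two-group cohort spec drawn from the reference moments by name."""
    groups = []
    for name in (name_a, name_b):
        n, m, s = REFERENCE_GROUP_MOMENTS[name]
        groups.append(GroupSpec(n, m, s, labels={label_column: name}))
    return CohortSimSpec(groups=tuple(groups), seed=seed)


def study_cohort_spec(seed: int = 0) -> CohortSimSpec:
    """Joint cohort with the cross-tabulated label structure of the study.

    Rates are drawn per etiology (plus the healthy group); outcome,
    EEG-background grade, hypothermia and term labels are assigned within
    etiology according to the published cross-tabulation. Because the
    outcome groups are etiology mixtures, their marginal moments come out
    close to the printed per-outcome summaries without being forced.
    """
    # (etiology, outcome, count) follow-up cells; "none" = died or lost
    cells = {
        "HIE": [("normal", 6), ("delay", 4), ("PNE", 1), ("none", 5)],
        "SVL": [("normal", 9), ("delay", 1), ("none", 4)],
        "genetic": [("delay", 2), ("PNE", 9), ("none", 3)],
        "other": [("normal", 1), ("delay", 1), ("PNE", 1)],
    }
    backgrounds = {
        "HIE": ["normal"] * 6 + ["mild_moderate"] * 5 + ["severe"] * 5,
        "SVL": ["normal"] * 4 + ["mild_moderate"] * 10,
        "genetic": ["normal"] * 1 + ["mild_moderate"] * 9 + ["severe"] * 4,
        "other": ["normal"] * 1 + ["mild_moderate"] * 2,
    }
    terms = {"HIE": 13, "SVL": 13, "genetic": 13, "other": 2}
    moments = {
        "HIE": REFERENCE_GROUP_MOMENTS["HIE"][1:],
        "SVL": REFERENCE_GROUP_MOMENTS["SVL"][1:],
        "genetic": REFERENCE_GROUP_MOMENTS["genetic"][1:],
        "other": REFERENCE_GROUP_MOMENTS["seizure"][1:],
    }
    groups: list[GroupSpec] = []
    for etio, outcome_cells in cells.items():
        mean, sd = moments[etio]
        idx = 0
        for outcome, count in outcome_cells:
            for _ in range(count):
                labels = {
                    "group": "seizure",
                    "etiology": etio,
                    "outcome": outcome,
                    "background_grade": backgrounds[etio][idx],
                    "hypothermia": etio == "HIE" and idx < 8,
                    "term": idx < terms[etio],
                }
                groups.append(GroupSpec(1, mean, sd, labels=labels))
                idx += 1
    n_h, m_h, s_h = REFERENCE_GROUP_MOMENTS["healthy"]
    groups.append(
        GroupSpec(
            n_h, m_h, s_h,
            labels={
                "group": "healthy", "etiology": "none",
                "background_grade": "normal", "hypothermia": False,
                "outcome": "none", "term": True,
            },
        )
    )
    return CohortSimSpec(groups=tuple(groups), seed=seed)
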