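"""Three-stage ripple-band HFA detector for neonatal scalp EEG.

Stage I (baseline detection): the signal is band-passed with an
equiripple FIR (80-240 Hz passband, 60 dB stopbands below 70 and above
250 Hz). A baseline amplitude threshold is taken as a high percentile of
the Hilbert envelope over "baseline" time, where baseline means windows
whose normalized Stockwell entropy in the ripple band is high (spectrally
flat, i.e. event-free). Events of interest (EoIs) are envelope excursions
above threshold lasting more than 20 ms and containing at least four
rectified-signal peaks above threshold.

Stage II (validation): the Stockwell transform of each EoI (with temporal
context) must show an isolated high-frequency spectral peak: a
local maximum at >= 80 Hz separated from low-frequency activity by a
trough, with peak power at least 10x the trough power.

Stage III (artifact rejection): EoIs with ripple-band peak-to-peak
amplitude >= 40 uV or SNR < 4 are discarded, as is any EoI overlapping a
z-score artifact mask (broadband jump artifacts via the low-passed
first difference; muscle artifacts via the 110-140 Hz band envelope;
flagged where the z-score exceeds the median by five interquartile
ranges, or 15 in absolute value for jumps).

The subject-level HFA rate is the total number of surviving events
divided by the summed analyzed channel-minutes (events/min/channel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import filters
from .montage import BipolarMontage, build_bipolar
from .recording import Recording
from .segments import AnalysisSegment, SubjectSelectionReport, select_segments
from .stockwell import band_entropy_profile, stockwell_transform


class DetectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectionConfig:
    """All detector thresholds; defaults follow the published operating point."""

    passband: tuple[float, float] = (80.0, 240.0)
    stopbands: tuple[float, float] = (70.0, 250.0)
    stopband_attenuation: float = 60.0  # dB
    ripple_band: tuple[float, float] = (80.0, 250.0)
    min_duration: float = 20.0  # ms, strict lower bound on EoI duration
    min_peaks: int = 4
    amplitude_ceiling: float = 40.0  # uV peak-to-peak, reject at >=
    min_snr: float = 4.0  # reject at <
    jump_z_iqr_factor: float = 5.0
    jump_z_abs: float = 15.0
    muscle_band: tuple[float, float] = (110.0, 140.0)
    entropy_window: float = 1.0  # s
    entropy_baseline_fraction: float = 0.9
    baseline_percentile: float = 95.0
    min_baseline_s: float = 5.0
    event_merge_gap: float = 10.0  # ms
    artifact_pad: float = 100.0  # ms
    validation_context: float = 100.0  # ms each side for Stage II
    validation_fmin: float = 40.0  # Hz, Stage II spectrum floor
    peak_trough_ratio: float = 10.0  # Stage II isolation criterion

    def __post_init__(self) -> None:
        if not (
            self.stopbands[0] < self.passband[0]
            and self.passband[1] < self.stopbands[1]
        ):
            raise ValueError("passband must lie strictly inside the stopband gap")
        if self.min_duration <= 0 or self.min_peaks < 1:
            raise ValueError("min_duration must be > 0 and min_peaks >= 1")
        if self.min_snr < 0 or self.amplitude_ceiling <= 0:
            raise ValueError("min_snr must be >= 0 and amplitude_ceiling > 0")


@dataclass
class EoI:
    """Stage-I candidate event, annotated as it moves through the stages."""

    onset_s: float  # relative to segment start
    offset_s: float
    n_peaks: int
    p2p_amplitude: float  # uV, ripple-band
    snr: float = float("nan")
    spectral_peak_freq: float = float("nan")
    stage: str = "candidate"  # candidate | validated | rejected
    rejection_reason: str | None = None

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class HFAEvent:
    """Validated detection (passed all three stages)."""

    subject_id: str
    bipolar_channel: str
    onset_s: float  # absolute recording time
    offset_s: float
    n_peaks: int
    p2p_amplitude: float
    snr: float
    spectral_peak_freq: float


@dataclass
class ArtifactMask:
    """Per-channel boolean masks plus flagged spans with their kinds."""

    masks: dict  # channel label -> bool array (n_times,)
    spans: list  # (channel, kind, start_s, end_s)


@dataclass
class SegmentLog:
    bipolar_channel: str
    start_s: float
    threshold: float
    baseline_s: float
    baseline_fallback: bool
    n_candidates: int
    n_validated: int
    n_accepted: int


def design_ripple_filter(config: DetectionConfig, fs: float) -> np.ndarray:
    """Equiripple FIR meeting the config's band/attenuation spec."""
    return filters.design_ripple_fir(
        fs,
        passband=config.passband,
        stopbands=config.stopbands,
        stopband_atten_db=config.stopband_attenuation,
    )


def baseline_threshold(
    samples: np.ndarray,
    fs: float,
    taps: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
) -> tuple[float, np.ndarray, bool]:
    """Baseline amplitude threshold from ripple-band Stockwell entropy.

    Windows whose normalized entropy is at least
    ``entropy_baseline_fraction`` form the baseline; the threshold is the
    ``baseline_percentile`` of the ripple envelope over baseline samples.
    If less than ``min_baseline_s`` of baseline is found, the whole
    segment is used and the fallback flag is set.

    Returns (threshold_uV, baseline sample mask, fallback flag).
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if np.allclose(samples, 0.0):
        return 0.0, np.ones(n, dtype=bool), False
    env = filters.ripple_envelope(samples, taps)
    entropy = band_entropy_profile(
        samples, fs, window_s=config.entropy_window, band=config.ripple_band
    )
    win = int(round(config.entropy_window * fs))
    mask = np.zeros(n, dtype=bool)
    for w, h in enumerate(entropy):
        if h >= config.entropy_baseline_fraction:
            mask[w * win : (w + 1) * win] = True
    fallback = mask.sum() / fs < config.min_baseline_s
    if fallback:
        mask = np.ones(n, dtype=bool)
    threshold = float(np.percentile(env[mask], config.baseline_percentile))
    return threshold, mask, fallback


def detect_eoi(
    envelope: np.ndarray,
    band_signal: np.ndarray,
    threshold: float,
    fs: float,
    config: DetectionConfig = DetectionConfig(),
) -> list[EoI]:
    """Stage-I candidates: supra-threshold envelope runs with enough peaks.

    Runs separated by less than ``event_merge_gap`` are merged (a single
    sub-threshold sample should not split one oscillation in two). A run
    qualifies when it lasts strictly more than ``min_duration`` and the
    rectified band signal has at least ``min_peaks`` local maxima above
    threshold inside it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    above = envelope > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]])) + 1  # exclusive

    gap = config.event_merge_gap / 1000.0 * fs
    merged = [[int(run_starts[0]), int(run_ends[0])]]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    min_dur_samples = config.min_duration / 1000.0 * fs
    out: list[EoI] = []
    rect = np.abs(band_signal)
    for s, e in merged:
        if e - s <= min_dur_samples:
            continue
        peaks, _ = find_peaks(rect[s:e], height=threshold)
        if len(peaks) < config.min_peaks:
            continue
        seg = band_signal[s:e]
        out.append(
            EoI(
                onset_s=s / fs,
                offset_s=e / fs,
                n_peaks=int(len(peaks)),
                p2p_amplitude=float(seg.max() - seg.min()),
            )
        )
    return out


def validate_hf_peak(
    samples: np.ndarray,
    fs: float,
    eoi: EoI,
    config: DetectionConfig = DetectionConfig(),
) -> bool:
    """Stage II: require an isolated high-frequency spectral peak.

    The Stockwell transform is computed on the event plus
    ``validation_context`` on each side, over ``validation_fmin`` up to
    the ripple-band ceiling. The event's time-averaged power spectrum
    must have a local maximum at or above the ripple-band floor (80 Hz),
    and the minimum power between the low-frequency range and that peak
    (the trough) must be at least ``peak_trough_ratio`` times smaller
    than the peak. Records ``spectral_peak_freq`` on the EoI.
    """
    n = len(samples)
    ctx = int(round(config.validation_context / 1000.0 * fs))
    i0 = max(int(round(eoi.onset_s * fs)) - ctx, 0)
    i1 = min(int(round(eoi.offset_s * fs)) + ctx, n)
    window = samples[i0:i1]
    if np.allclose(window, 0.0):
        return False
    fmax = min(config.ripple_band[1], fs / 2 - 1)
    tf = stockwell_transform(window, fs, config.validation_fmin, fmax)
    # average power over the event samples only (context excluded)
    e0 = int(round(eoi.onset_s * fs)) - i0
    e1 = int(round(eoi.offset_s * fs)) - i0
    spec = tf.power[:, e0:e1].mean(axis=1)
    freqs = tf.freqs
    hf = freqs >= config.ripple_band[0]
    if not hf.any() or spec[hf].max() <= 0:
        return False
    # candidate peak: largest HF local maximum
    hf_idx = np.flatnonzero(hf)
    peak_rel = int(np.argmax(spec[hf_idx]))
    peak_i = hf_idx[peak_rel]
    is_local_max = (peak_i == 0 or spec[peak_i] >= spec[peak_i - 1]) and (
        peak_i == len(spec) - 1 or spec[peak_i] >= spec[peak_i + 1]
    )
    # a peak at the very top edge of the band is not "isolated"
    if peak_i == len(spec) - 1:
        is_local_max = False
    if not is_local_max:
        return False
    trough = spec[: peak_i + 1].min()
    if trough <= 0:
        ratio = np.inf
    else:
        ratio = spec[peak_i] / trough
    if ratio < config.peak_trough_ratio:
        return False
    eoi.spectral_peak_freq = float(freqs[peak_i])
    return True


def compute_snr(
    eoi: EoI, envelope: np.ndarray, baseline_mask: np.ndarray, fs: float
) -> float:
    """SNR = event envelope peak / median baseline envelope (linear)."""
    i0 = int(round(eoi.onset_s * fs))
    i1 = int(round(eoi.offset_s * fs))
    peak = float(envelope[i0:i1].max())
    baseline_median = float(np.median(envelope[baseline_mask]))
    if baseline_median == 0.0:
        eoi.snr = float("inf")
        eoi.rejection_reason = "zero_baseline"
        return eoi.snr
    eoi.snr = peak / baseline_median
    return eoi.snr


def _zscore_flags(
    values: np.ndarray, iqr_factor: float, z_abs: float | None
) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros(len(values), dtype=bool)
    z = (values - values.mean()) / sd
    q1, med, q3 = np.percentile(z, [25, 50, 75])
    flags = z > med + iqr_factor * (q3 - q1)
    if z_abs is not None:
        flags |= np.abs(z) >= z_abs
    return flags


def _pad_mask(mask: np.ndarray, pad_samples: int) -> np.ndarray:
    if not mask.any() or pad_samples <= 0:
        return mask
    idx = np.flatnonzero(mask)
    out = np.zeros(len(mask), dtype=bool)
    for i in idx:
        out[max(i - pad_samples, 0) : i + pad_samples + 1] = True
    return out


def _spans_from_mask(
    mask: np.ndarray, fs: float, label: str, kind: str
) -> list[tuple[str, str, float, float]]:
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]])) + 1
    return [(label, kind, s / fs, e / fs) for s, e in zip(run_starts, run_ends)]


def zscore_artifact_mask(
    recording: Recording, config: DetectionConfig = DetectionConfig()
) -> ArtifactMask:
    """Jump and muscle artifact masks via z-score thresholds.

    Jump artifacts are broadband, so they carry energy below the ripple
    band where genuine ripples carry none: each channel is low-passed
    below the filter's lower stopband edge and the rectified first
    difference is z-scored. Samples where a channel's |z| reaches
    ``jump_z_abs`` are flagged on that channel (a focal electrode jump),
    and samples where the cross-channel median z exceeds its median by
    ``jump_z_iqr_factor`` IQRs are flagged on every channel.

    Muscle artifacts: the 110-140 Hz band envelope is z-scored per
    channel and aggregated across channels by the median; myogenic
    bursts hit many electrodes at once, so a focal ripple-band event on
    one channel leaves the cross-channel median untouched while genuine
    muscle activity raises it. Flagged where the median z exceeds its
    own median by ``jump_z_iqr_factor`` IQRs.

    Flagged samples are padded by ``artifact_pad`` on each side.
    """
    from scipy.signal import butter, sosfiltfilt

    pad = int(round(config.artifact_pad / 1000.0 * recording.fs))
    n_ch = recording.n_channels
    n = recording.n_times
    labels = recording.channel_labels

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    lp = butter(4, config.stopbands[0], btype="lowpass", fs=recording.fs, output="sos")
    jump_z = np.empty((n_ch, n))
    muscle_z = np.empty((n_ch, n))
    for i, label in enumerate(labels):
        x = recording.channel(label)
        low = sosfiltfilt(lp, x)
        jump_z[i] = zscore(np.abs(np.diff(low, prepend=low[0])))
        env = filters.hilbert_envelope(
            filters.butter_bandpass(x, recording.fs, config.muscle_band)
        )
        muscle_z[i] = zscore(env)

    def median_flags(z: np.ndarray) -> np.ndarray:
        agg = np.median(z, axis=0)
        q1, med, q3 = np.percentile(agg, [25, 50, 75])
        return agg > med + config.jump_z_iqr_factor * (q3 - q1)

    jump_common = _pad_mask(median_flags(jump_z), pad)
    muscle_common = _pad_mask(median_flags(muscle_z), pad)

    masks: dict[str, np.ndarray] = {}
    spans: list[tuple[str, str, float, float]] = []
    for i, label in enumerate(labels):
        focal_jump = _pad_mask(np.abs(jump_z[i]) >= config.jump_z_abs, pad)
        jump = jump_common | focal_jump
        masks[label] = jump | muscle_common
        spans += _spans_from_mask(jump, recording.fs, label, "jump")
        spans += _spans_from_mask(muscle_common, recording.fs, label, "muscle")
    return ArtifactMask(masks=masks, spans=spans)


def stage3_reject(
    eois: list[EoI],
    mask: np.ndarray | None,
    fs: float,
    config: DetectionConfig = DetectionConfig(),
    mask_offset_s: float = 0.0,
) -> tuple[list[EoI], list[EoI]]:
    """Amplitude-ceiling, SNR and artifact-overlap gates.

    ``mask`` is the recording-level artifact mask for this channel;
    ``mask_offset_s`` maps segment-relative EoI times onto it. An EoI
    sharing any sample with the mask is rejected. SNR exactly at the
    cutoff is kept (the criterion is strictly "< min_snr").
    Returns (accepted, rejected).
    """
    accepted, rejected = [], []
    for e in eois:
        if e.p2p_amplitude >= config.amplitude_ceiling:
            e.stage, e.rejection_reason = "rejected", "amplitude"
        elif not np.isfinite(e.snr) or e.snr < config.min_snr:
            e.stage, e.rejection_reason = "rejected", "snr"
        elif mask is not None:
            i0 = int(round((e.onset_s + mask_offset_s) * fs))
            i1 = int(round((e.offset_s + mask_offset_s) * fs))
            i0, i1 = max(i0, 0), min(i1, len(mask))
            if mask[i0:i1].any():
                e.stage, e.rejection_reason = "rejected", "artifact_overlap"
        if e.rejection_reason:
            rejected.append(e)
        else:
            e.stage = "accepted"
            accepted.append(e)
    return accepted, rejected


def detect_segment(
    segment: AnalysisSegment,
    taps: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
    channel_mask: np.ndarray | None = None,
) -> tuple[list[EoI], SegmentLog]:
    """Run all three stages on one analysis segment."""
    fs = segment.fs
    band = filters.bandpass_fir(segment.samples, taps)
    env = filters.hilbert_envelope(band)
    threshold, baseline_mask, fallback = baseline_threshold(
        segment.samples, fs, taps, config
    )
    candidates = detect_eoi(env, band, threshold, fs, config)
    validated: list[EoI] = []
    for eoi in candidates:
        if validate_hf_peak(segment.samples, fs, eoi, config):
            eoi.stage = "validated"
            compute_snr(eoi, env, baseline_mask, fs)
            validated.append(eoi)
        else:
            eoi.stage, eoi.rejection_reason = "rejected", "no_hf_peak"
    accepted, _ = stage3_reject(
        validated, channel_mask, fs, config, mask_offset_s=segment.start_s
    )
    log = SegmentLog(
        bipolar_channel=segment.bipolar_channel,
        start_s=segment.start_s,
        threshold=threshold,
        baseline_s=float(baseline_mask.sum() / fs) if not fallback else 0.0,
        baseline_fallback=fallback,
        n_candidates=len(candidates),
        n_validated=len(validated),
        n_accepted=len(accepted),
    )
    return accepted, log


def detect_subject(
    recording: Recording,
    montage: BipolarMontage | None = None,
    config: DetectionConfig = DetectionConfig(),
    subject_id: str = "subject",
    apply_montage: bool = True,
) -> tuple[list[HFAEvent], dict, SubjectSelectionReport, list[SegmentLog]]:
    """Full pipeline over one recording.

    When ``apply_montage`` is false the recording's channels are treated
    as already re-referenced (as synthetic recordings are). The subject
    rate is total accepted events divided by the summed analyzed
    channel-minutes (events/min/channel); with equal time on every
    channel this equals events-per-minute divided by channel count.
    """
    bipolar = build_bipolar(recording, montage) if apply_montage else recording
    segments, report = select_segments(bipolar, subject_id=subject_id)
    if not report.analyzable:
        raise DetectionError(
            f"subject {subject_id} has {report.analyzed_min:.2f} analyzable "
            f"min (< 5); selection report: {report.to_dict()}"
        )
    taps = design_ripple_filter(config, bipolar.fs)
    mask = zscore_artifact_mask(bipolar, config)
    events: list[HFAEvent] = []
    logs: list[SegmentLog] = []
    channel_minutes = 0.0
    for seg in segments:
        accepted, log = detect_segment(
            seg, taps, config, channel_mask=mask.masks.get(seg.bipolar_channel)
        )
        logs.append(log)
        channel_minutes += seg.duration_s / 60.0
        for e in accepted:
            events.append(
                HFAEvent(
                    subject_id=subject_id,
                    bipolar_channel=seg.bipolar_channel,
                    onset_s=seg.start_s + e.onset_s,
                    offset_s=seg.start_s + e.offset_s,
                    n_peaks=e.n_peaks,
                    p2p_amplitude=e.p2p_amplitude,
                    snr=e.snr,
                    spectral_peak_freq=e.spectral_peak_freq,
                )
            )
    rate = len(events) / channel_minutes if channel_minutes > 0 else 0.0
    record = {
        "subject_id": subject_id,
        "rate": rate,
        "n_events": len(events),
        "channel_minutes": channel_minutes,
        "n_channels": report.n_bipolar_channels_analyzed,
    }
    return events, record, report, logs


def events_to_frame(events: list[HFAEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": e.subject_id, "channel": e.bipolar_channel,
                "onset_s": e.onset_s, "offset_s": e.offset_s,
                "n_peaks": e.n_peaks, "p2p_uV": e.p2p_amplitude,
                "snr": e.snr, "peak_freq_hz": e.spectral_peak_freq,
            }
            for e in events
        ],
        columns=[
            "subject", "channel", "onset_s", "offset_s",
            "n_peaks", "p2p_uV", "snr", "peak_freq_hz",
        ],
    )
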