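"""EDF input/output and annotation sidecars.

Recordings are exchanged as plain EDF (16-bit, 1-second data records,
physical units uV) plus a CSV annotation sidecar with columns
``label,channel,start_s,end_s`` (empty channel = applies to all).
Reading goes through MNE; writing uses a self-contained minimal EDF
writer. Non-EEG service leads (ECG, EMG, respiration, ...) are dropped
on read by label pattern, and recordings sampled below 1 kHz are
rejected because ripple-band (80-250 Hz) analysis needs the headroom.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from pathlib import Path

import numpy as np

from .recording import Annotation, Recording

MIN_FS = 1000.0

#: label patterns of extracerebral service leads dropped on read
NON_EEG_PATTERNS = (
    r"ecg", r"ekg", r"emg", r"eog", r"resp", r"pneu", r"thorax",
    r"abdo", r"sao2", r"spo2", r"pulse", r"photic", r"status", r"annotation",
)


class RecordingIOError(RuntimeError):
    pass


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as plain EDF (int16, 1-s records, uV units).

    The sampling rate must be an integer (samples per 1-s record) and
    the signal is truncated to whole seconds. Physical scaling is per
    channel from the data range, so round-trip error is bounded by
    range/2^16.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise RecordingIOError(f"EDF writer needs integer fs, got {fs}")
    fs = int(round(fs))
    n_records = recording.n_times // fs
    if n_records < 1:
        raise RecordingIOError("recording shorter than one 1-s EDF record")
    n_ch = recording.n_channels
    data = recording.samples[:, : n_records * fs]

    phys_min, phys_max, digital = [], [], []
    for ch in range(n_ch):
        lo, hi = float(data[ch].min()), float(data[ch].max())
        if hi - lo < 1e-6:
            lo, hi = lo - 1.0, hi + 1.0
        # EDF headers hold 8-char decimals; round outward to keep data inside
        lo = float(np.floor(lo * 100) / 100)
        hi = float(np.ceil(hi * 100) / 100)
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (data[ch] - lo) / (hi - lo) * 65535.0 - 32768.0
        digital.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate X X X X", 80),
            _ascii_field(now.strftime("%d.%m.%y"), 8),
            _ascii_field(now.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (n_ch + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field("1", 8),
            _ascii_field(n_ch, 4),
        ]
    )
    sig_header = b"".join(
        [_ascii_field(lbl, 16) for lbl in recording.channel_labels]
        + [_ascii_field("", 80)] * n_ch
        + [_ascii_field("uV", 8)] * n_ch
        + [_ascii_field(f"{v:.8g}"[:8], 8) for v in phys_min]
        + [_ascii_field(f"{v:.8g}"[:8], 8) for v in phys_max]
        + [_ascii_field(-32768, 8)] * n_ch
        + [_ascii_field(32767, 8)] * n_ch
        + [_ascii_field("", 80)] * n_ch
        + [_ascii_field(fs, 8)] * n_ch
        + [_ascii_field("", 32)] * n_ch
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec_i in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch][rec_i * fs : (rec_i + 1) * fs].tobytes())


def _is_eeg_label(label: str) -> bool:
    low = label.lower()
    return not any(re.search(pat, low) for pat in NON_EEG_PATTERNS)


def read_recording(path, annotation_path=None) -> Recording:
    """Read an EDF/EDF+ file (plus optional annotation sidecar).

    Drops extracerebral leads by label pattern, converts to uV, and
    raises if the sampling rate is below 1 kHz (analysis inclusion
    criterion).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # unreadable/corrupt file
        raise RecordingIOError(f"could not read EDF {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    if fs < MIN_FS:
        raise RecordingIOError(
            f"{path.name}: sampling rate {fs:g} Hz is below the 1 kHz "
            "required for ripple-band analysis"
        )
    keep = [name for name in raw.ch_names if _is_eeg_label(name)]
    if not keep:
        raise RecordingIOError(f"{path.name}: no EEG channels after filtering")
    raw.pick(keep)
    samples = raw.get_data() * 1e6  # MNE returns volts
    annotations = []
    if annotation_path is not None:
        annotations = read_annotations_csv(annotation_path)
    return Recording(
        samples=samples, fs=fs, channel_labels=list(raw.ch_names),
        annotations=annotations,
    )


def read_annotations_csv(path) -> list[Annotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            channel = row.get("channel") or None
            out.append(
                Annotation(
                    label=row["label"],
                    channel=channel,
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                )
            )
    return out


def write_annotations_csv(annotations: list[Annotation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "channel", "start_s", "end_s"])
        for ann in annotations:
            writer.writerow(
                [ann.label, ann.channel or "", ann.start_s, ann.end_s]
            )
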