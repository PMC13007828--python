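"""End-to-end orchestration: simulate -> detect -> rates -> statistics.

A single YAML config drives the run; one global seed is fanned out to
every stochastic stage by hashing the stage name and subject id, so the
whole pipeline is reproducible and adding a stage never perturbs another
stage's random stream. Completed stages are skipped on re-run when their
outputs exist and the config hash is unchanged (resumable), and a run
manifest records digests of every produced file.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .detector import DetectionConfig, detect_subject, events_to_frame
from .io_edf import (
    read_recording,
    write_annotations_csv,
    write_edf,
)
from .montage import BipolarMontage
from .stats import DEFAULT_PLAN, report_markdown, run_study
from .synthetic import SignalSimSpec, events_to_frame as truth_to_frame, generate_recording

log = logging.getLogger("neohfa")


class ConfigError(ValueError):
    pass


_SIM_DEFAULTS = {
    "n_subjects": {"seizure": 12, "healthy": 8},
    "duration_s": 600.0,
    "n_channels": 24,
    "event_rate": {"seizure": 0.16, "healthy": 0.03},
}

_TOP_KEYS = {
    "out_dir", "seed", "log_level", "montage", "detection", "simulate", "stats",
}


def _suggest(key: str, known) -> str:
    def norm(s: str) -> str:
        return "_".join(sorted(s.lower().split("_")))

    best, best_score = None, 0.0
    for cand in known:
        score = max(
            difflib.SequenceMatcher(None, key, cand).ratio(),
            difflib.SequenceMatcher(None, norm(key), norm(cand)).ratio(),
        )
        if score > best_score:
            best, best_score = cand, score
    return f" (did you mean {best!r}?)" if best and best_score >= 0.6 else ""


def _build_detection_config(overrides: dict) -> DetectionConfig:
    known = {f.name for f in dataclasses.fields(DetectionConfig)}
    bad = set(overrides) - known
    if bad:
        key = sorted(bad)[0]
        raise ConfigError(f"unknown detection key {key!r}{_suggest(key, known)}")
    cleaned = {
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    }
    try:
        return DetectionConfig(**cleaned)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid detection config: {exc}") from exc


@dataclasses.dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    montage: BipolarMontage | None = None  # None = channels already bipolar
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)
    simulate: dict = dataclasses.field(default_factory=lambda: dict(_SIM_DEFAULTS))
    stats_plan: tuple = DEFAULT_PLAN
    config_hash: str = ""


def validate_config(path) -> PipelineConfig:
    """Load, default-fill and sanity-check a pipeline YAML config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config must be a YAML mapping")
    for key in doc:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown config key {key!r}{_suggest(key, _TOP_KEYS)}")
    detection = _build_detection_config(doc.get("detection") or {})
    if detection.min_snr < 0:
        raise ConfigError("min_snr must be >= 0")
    sim = dict(_SIM_DEFAULTS)
    sim.update(doc.get("simulate") or {})
    montage = None
    if doc.get("montage"):
        montage = BipolarMontage.from_yaml(doc["montage"])
    stats = doc.get("stats") or {}
    plan = tuple(stats.get("plan", DEFAULT_PLAN))
    cfg = PipelineConfig(
        out_dir=Path(doc.get("out_dir", "neohfa_run")),
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "INFO")),
        montage=montage,
        detection=detection,
        simulate=sim,
        stats_plan=plan,
    )
    cfg.config_hash = hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return cfg


def stage_seed(global_seed: int, stage: str, item: str = "") -> int:
    """Deterministic per-stage/per-item seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}:{item}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, message: str):
        self.stage = stage
        self.subject = subject
        super().__init__(
            f"stage {stage!r}"
            + (f", subject {subject!r}" if subject else "")
            + f": {message}"
        )


def _subject_plan(cfg: PipelineConfig) -> list[tuple[str, str]]:
    plan = []
    for group, count in cfg.simulate["n_subjects"].items():
        for i in range(int(count)):
            plan.append((f"{group}{i + 1:02d}", group))
    return plan


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute simulate -> detect -> stats; returns the run manifest."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    edf_dir = out / "edf"
    edf_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != cfg.config_hash:
            log.info("config changed; ignoring previous outputs")
            previous = {}

    manifest: dict = {
        "config_hash": cfg.config_hash,
        "version": __version__,
        "stages": {},
        "selection_reports": {},
    }
    subjects = _subject_plan(cfg)

    # ---- simulate -------------------------------------------------------
    sim_files: dict[str, str] = {}
    for subject, group in subjects:
        edf_path = edf_dir / f"{subject}.edf"
        ann_path = edf_dir / f"{subject}.annotations.csv"
        truth_path = edf_dir / f"{subject}.truth.tsv"
        prev = previous.get("stages", {}).get("simulate", {})
        if (
            edf_path.exists() and ann_path.exists() and truth_path.exists()
            and prev.get(edf_path.name) == _digest(edf_path)
        ):
            log.info("simulate: %s up to date", subject)
        else:
            try:
                spec = SignalSimSpec(
                    duration_s=float(cfg.simulate["duration_s"]),
                    n_channels=int(cfg.simulate["n_channels"]),
                    event_rate=float(cfg.simulate["event_rate"][group]),
                    seed=stage_seed(cfg.seed, "simulate", subject),
                )
                rec, truth = generate_recording(spec)
                write_edf(rec, edf_path)
                write_annotations_csv(rec.annotations, ann_path)
                truth_to_frame(truth).to_csv(truth_path, sep="\t", index=False)
            except Exception as exc:
                raise PipelineError("simulate", subject, str(exc)) from exc
        for p in (edf_path, ann_path, truth_path):
            sim_files[p.name] = _digest(p)
    manifest["stages"]["simulate"] = sim_files

    # ---- detect ---------------------------------------------------------
    rates_path = out / "rates.csv"
    det_files: dict[str, str] = {}
    rows = []
    for subject, group in subjects:
        events_path = out / f"{subject}.events.tsv"
        try:
            rec = read_recording(
                edf_dir / f"{subject}.edf",
                edf_dir / f"{subject}.annotations.csv",
            )
            events, record, report, logs = detect_subject(
                rec,
                montage=cfg.montage,
                config=cfg.detection,
                subject_id=subject,
                apply_montage=cfg.montage is not None,
            )
        except Exception as exc:
            raise PipelineError("detect", subject, str(exc)) from exc
        events_to_frame(events).to_csv(events_path, sep="\t", index=False)
        det_files[events_path.name] = _digest(events_path)
        manifest["selection_reports"][subject] = report.to_dict()
        rows.append({**record, "group": group})
    pd.DataFrame(rows).to_csv(rates_path, index=False)
    det_files[rates_path.name] = _digest(rates_path)
    manifest["stages"]["detect"] = det_files

    # ---- stats ----------------------------------------------------------
    cohort = pd.read_csv(rates_path)
    report = run_study(cohort, plan=cfg.stats_plan, seed=stage_seed(cfg.seed, "stats"))
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    (out / "report.md").write_text(report_markdown(report))
    manifest["stages"]["stats"] = {report_path.name: _digest(report_path)}

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
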