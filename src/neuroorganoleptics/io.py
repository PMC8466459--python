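"""File formats and the end-to-end pipeline orchestrator.

Recording CSV dialect: a ``#``-prefixed JSON header line carrying the
acquisition metadata (sampling rate, bit depth, channel order, subject,
session, timestamp), a column-header row (``nSeq`` sample counter plus one
integer column per channel), then the data rows. Timelines, questionnaires
and feature tables are plain CSV. Output is deterministic for fixed input.

``run_pipeline`` ties the stages together in the fixed study order:
signal-quality pre-validation -> template-outlier elimination -> per-window
HRV features -> acceptance/preference statistics. Every exclusion decision
is logged as a machine-parseable line, and summary counts (sessions lost,
recordings eliminated, windows analysed) are reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecg_hrv, sensory_stats, signal_quality
from .core import AcquisitionConfig, EventTimeline, RawRecording
from .sensor_transfer import ChannelCalibration, ecg_to_volts

__all__ = [
    "FormatError",
    "ValidationError",
    "read_recording",
    "write_recording",
    "read_timeline",
    "write_timeline",
    "read_questionnaire",
    "write_questionnaire",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("neuroorganoleptics")


class FormatError(ValueError):
    """The file does not follow the recording CSV dialect."""


class ValidationError(ValueError):
    """The file parses but violates a declared constraint (e.g. code range)."""


def write_recording(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording in the CSV dialect; byte-deterministic for fixed input."""
    path = Path(path)
    cfg = recording.config
    header = {
        "sampling_rate": cfg.sampling_rate,
        "resolution_bits": cfg.resolution_bits,
        "vcc": cfg.vcc,
        "channels": list(cfg.channel_map),
        "subject": recording.subject,
        "session": recording.session,
        "timestamp": recording.timestamp,
    }
    channels = [c for c in cfg.channel_map if c in recording.streams]
    n = recording.n_samples
    cols = {"nSeq": np.arange(n)}
    for c in channels:
        cols[c] = recording.streams[c]
    frame = pd.DataFrame(cols)
    with open(path, "w", newline="\n") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording CSV, validating codes against the declared bit depth.

    Malformed data rows and out-of-range codes are reported with their
    1-based line numbers.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing '#' JSON header line")
    try:
        header = json.loads(first.lstrip("#").strip())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: unparseable header: {e}") from e
    missing = {"sampling_rate", "resolution_bits", "channels"} - set(header)
    if missing:
        raise FormatError(f"{path}: header missing fields {sorted(missing)}")
    try:
        frame = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, ValueError) as e:
        raise FormatError(f"{path}: malformed data section: {e}") from e
    if frame.empty:
        raise FormatError(f"{path}: empty data section")
    channels = [str(c) for c in header["channels"]]
    absent = [c for c in channels if c not in frame.columns]
    if absent:
        raise FormatError(f"{path}: data columns missing channels {absent}")
    cfg = AcquisitionConfig(
        sampling_rate=float(header["sampling_rate"]),
        resolution_bits=int(header["resolution_bits"]),
        vcc=float(header.get("vcc", 3.3)),
        channel_map=tuple(channels),
    )
    streams = {}
    # Data rows start after the header line + column-header line.
    data_row_offset = 3
    for c in channels:
        col = frame[c]
        if not pd.api.types.is_numeric_dtype(col) or col.isna().any():
            bad = np.flatnonzero(pd.to_numeric(col, errors="coerce").isna())
            lines = (bad[:5] + data_row_offset).tolist()
            raise FormatError(f"{path}: non-numeric values in channel {c} at line(s) {lines}")
        vals = col.to_numpy()
        out = (vals < 0) | (vals > cfg.max_code)
        if np.any(out):
            lines = (np.flatnonzero(out)[:5] + data_row_offset).tolist()
            raise ValidationError(
                f"{path}: channel {c} codes outside [0, {cfg.max_code}] at line(s) {lines}"
            )
        streams[c] = vals.astype(np.int64)
    return RawRecording(
        config=cfg,
        streams=streams,
        subject=str(header.get("subject", "S00")),
        session=int(header.get("session", 1)),
        timestamp=str(header.get("timestamp", "1970-01-01T00:00:00")),
    )


def write_timeline(timeline: EventTimeline, path: str | Path) -> Path:
    path = Path(path)
    timeline.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path


def read_timeline(path: str | Path) -> EventTimeline:
    frame = pd.read_csv(path, keep_default_na=False)
    return EventTimeline.from_frame(frame)


def write_questionnaire(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, lineterminator="\n")
    return path


def read_questionnaire(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class PipelineConfig:
    """Where the dataset lives and how the stages are parameterised."""

    dataset_root: str | Path
    out_dir: str | Path
    products: tuple[str, ...] | None = None  # default: every product in the timelines
    dbscan_eps: float | None = None
    dbscan_min_samples: int = 5
    segment_s: float = signal_quality.DEFAULT_SEGMENT_S
    wilcoxon_alpha: float = sensory_stats.WILCOXON_ALPHA
    opposed_min_diff: int = sensory_stats.OPPOSED_MIN_DIFF


@dataclass
class PipelineResult:
    features: pd.DataFrame
    report: dict
    sessions_lost: int = 0
    recordings_eliminated: int = 0
    windows_analyzed: int = 0
    exclusions: list[str] = field(default_factory=list)


def _decision(result: PipelineResult, message: str) -> None:
    result.exclusions.append(message)
    log.info("DECISION %s", message)


def extract_session_features(
    recording: RawRecording,
    timeline: EventTimeline,
    dbscan_eps: float | None = None,
    dbscan_min_samples: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Run the ECG chain on one recording: per-product-window HRV features.

    Returns ``(feature rows, outlier_fraction)``; the caller applies the
    5% elimination rule.
    """
    fs = recording.config.sampling_rate
    cal = ChannelCalibration(n=recording.config.resolution_bits, vcc=recording.config.vcc)
    volts = ecg_to_volts(recording.streams["ECG"], cal)
    filtered = ecg_hrv.preprocess(volts, fs)
    peaks = ecg_hrv.detect_rpeaks(filtered, fs)
    templates = ecg_hrv.extract_templates(filtered, peaks, fs)
    labelled = ecg_hrv.template_outlier_fraction(
        templates, eps=dbscan_eps, min_samples=dbscan_min_samples
    )
    frac = labelled.outlier_fraction
    rr = ecg_hrv.rr_from_peaks(peaks, fs)
    rows = []
    for product in timeline.products:
        try:
            t0, t1 = ecg_hrv.contact_window(timeline, product, recording_end=recording.duration)
            feats = ecg_hrv.band_powers(rr.restrict(t0, t1))
        except (ecg_hrv.WindowTruncatedError, ValueError) as e:
            log.warning("window skipped subject=%s session=%s product=%s: %s",
                        recording.subject, recording.session, product, e)
            continue
        rows.append(
            {
                "subject": recording.subject,
                "session": recording.session,
                "product": product,
                "lf_power": feats.lf_power,
                "hf_power": feats.hf_power,
                "lf_norm": feats.lf_norm,
                "hf_norm": feats.hf_norm,
                "n_beats": feats.n_beats,
                "outlier_fraction": frac,
                "retained": ecg_hrv.accept_recording(frac) == "retained",
            }
        )
    return pd.DataFrame(rows), frac


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run validate -> eliminate -> hrv -> analyze over a dataset on disk.

    Expects ``dataset_root`` to hold ``recordings/*.csv``,
    ``timelines/*.csv`` (same stems) and ``questionnaire.csv``. Writes
    ``features.csv`` and ``report.json`` under ``out_dir``.
    """
    root = Path(config.dataset_root)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(features=pd.DataFrame(), report={})

    rec_paths = sorted((root / "recordings").glob("*.csv"))
    feature_frames = []
    for rec_path in rec_paths:
        recording = read_recording(rec_path)
        timeline = read_timeline(root / "timelines" / rec_path.name)
        stem = rec_path.stem

        # Stage 1: signal-quality pre-validation (ECG problems are fatal).
        report = signal_quality.assess_recording(
            recording.streams,
            fs=recording.config.sampling_rate,
            n=recording.config.resolution_bits,
            segment_s=config.segment_s,
        )
        if report.repeat_required:
            result.sessions_lost += 1
            bad = report.table[
                (report.table["channel"] == "ECG")
                & (report.table["flag"] != signal_quality.SegmentFlag.OK.value)
            ]
            _decision(
                result,
                f"exclude recording={stem} rule=ecg_quality "
                f"flags={sorted(bad['flag'].unique().tolist())} segments={len(bad)}",
            )
            continue

        # Stages 2+3: template-outlier elimination, then per-window features.
        rows, frac = extract_session_features(
            recording, timeline, config.dbscan_eps, config.dbscan_min_samples
        )
        if ecg_hrv.accept_recording(frac) == "eliminated":
            result.recordings_eliminated += 1
            _decision(
                result,
                f"eliminate recording={stem} rule=outlier_fraction>"
                f"{ecg_hrv.OUTLIER_FRACTION_MAX} value={frac:.4f}",
            )
            continue
        feature_frames.append(rows)

    features = (
        pd.concat(feature_frames, ignore_index=True) if feature_frames else pd.DataFrame(
            columns=["subject", "session", "product", "lf_power", "hf_power",
                     "lf_norm", "hf_norm", "n_beats", "outlier_fraction", "retained"]
        )
    )
    result.features = features
    result.windows_analyzed = len(features)
    features.to_csv(out / "features.csv", index=False, lineterminator="\n")

    # Stage 4: acceptance/preference statistics.
    report_obj: dict = {
        "sessions_lost": result.sessions_lost,
        "recordings_eliminated": result.recordings_eliminated,
        "windows_analyzed": result.windows_analyzed,
    }
    q_path = root / "questionnaire.csv"
    if q_path.exists() and len(features):
        table = read_questionnaire(q_path)
        pairs = sensory_stats.select_opposed_pairs(table, config.opposed_min_diff)
        pairs = sensory_stats.attach_feature_diffs(pairs, features)
        if len(pairs):
            report_obj["n_opposed_pairs"] = int(len(pairs))
            report_obj["sign_fraction_lf"] = sensory_stats.sign_fraction(pairs, "lf_power")
            report_obj["sign_fraction_hf"] = sensory_stats.sign_fraction(pairs, "hf_power")
        for feat in ("lf_power", "hf_power"):
            try:
                p, mask = sensory_stats.wilcoxon_matrix(
                    features, feat, alpha=config.wilcoxon_alpha
                )
                report_obj[f"wilcoxon_{feat}"] = json.loads(p.to_json())
            except ValueError:
                pass
        ga = table[table["question"] == sensory_stats.GLOBAL_ACCEPTANCE]
        nps = table[table["question"] == "nps_recommend"]
        if len(nps):
            cats = nps["response"].map(sensory_stats.nps_categorize).value_counts()
            report_obj["nps_distribution"] = {k: int(v) for k, v in cats.items()}
        kendall = {}
        for product in sorted(ga["product"].unique()):
            sub = ga[ga["product"] == product].pivot_table(
                index="subject", columns="session", values="response"
            )
            for s1, s2 in combinations_sorted(sub.columns):
                paired = sub[[s1, s2]].dropna()
                if len(paired) < 4:
                    continue
                try:
                    tau, pv, verdict = sensory_stats.kendall_repeatability(
                        paired[s1], paired[s2]
                    )
                except ValueError:
                    continue
                kendall[f"{product}:{s1}v{s2}"] = {"tau": tau, "p": pv, "verdict": verdict}
        if kendall:
            report_obj["kendall_repeatability"] = kendall

    result.report = report_obj
    (out / "report.json").write_text(json.dumps(report_obj, sort_keys=True, indent=1))
    log.info(
        "pipeline done: sessions_lost=%d recordings_eliminated=%d windows_analyzed=%d",
        result.sessions_lost, result.recordings_eliminated, result.windows_analyzed,
    )
    return result


def combinations_sorted(items):
    from itertools import combinations

    return combinations(sorted(items), 2)
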