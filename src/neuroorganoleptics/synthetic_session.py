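"""Synthetic acquisition sessions with known ground truth.

Real sessions of this protocol (multi-channel 10-bit/1 kHz streams, a
staged tasting timeline, and questionnaire tables) cannot be shipped, so
this module generates them. Every stage of the analysis pipeline can then
be tested against what the generator knows: exact beat times, injected
artifact intervals, configured LF/HF spectral powers, and configured
acceptance-score distributions.

Models
------
* RR series: spectral synthesis. A modulation signal is built as a sum of
  band-limited cosines with random phases — one group spanning the LF band
  (0.04-0.15 Hz), one the HF band (0.15-0.40 Hz) — whose total variances
  equal the configured band powers in ms^2. Beat times follow by walking
  the modulated instantaneous RR (an integral-pulse-frequency-modulation
  style sampling), so the resulting RR series carries the prescribed
  spectrum directly.
* ECG waveform: a stylised P-QRS-T template train (sums of Gaussian
  bumps) placed at the ground-truth beat times, converted to ADC codes by
  inverting the ECG transfer function. Simple, and the R-peak ground
  truth is exact by construction.
* Auxiliary channels: EDA as slow tonic drift plus event-locked phasic
  responses, respiration (PZT) as a quasi-sinusoid in the 0.2-0.4 Hz
  breathing range, PPG as a pulse train locked to the ECG beat times.
* Artifacts: the three episode classes seen in practice — flatline
  (electrode detachment; the channel falls to a constant, by default the
  low rail), saturation (a rail code), and motion spike bursts.
* Scores: integer draws around per-product means, clipped to the 9-point
  hedonic scale; an aligned 0-10 recommendation (NPS) response is derived
  from the same latent liking. Optionally, per-window LF/HF powers are
  drawn conditionally on the product's score (low acceptance => higher
  power), which gives end-to-end direction-recovery tests a known sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AcquisitionConfig, ArtifactRecord, Event, EventTimeline, GroundTruth
from .ecg_hrv import CONTACT_WINDOW_S, HF_BAND, LF_BAND
from .sensor_transfer import ChannelCalibration, microsiemens_to_eda_code, volts_to_ecg_code

__all__ = [
    "simulate_rr",
    "synthesize_ecg",
    "synthesize_auxiliary",
    "inject_artifact",
    "build_timeline",
    "simulate_scores",
    "draw_window_powers",
    "CohortConfig",
    "simulate_session",
    "simulate_cohort",
]


def _band_modulation(band: tuple[float, float], power: float, n_components: int, rng,
                     duration: float | None = None):
    """Frequencies, amplitudes and phases of one band-limited cosine group.

    Component frequencies are kept 5% of the bandwidth inside the band
    edges so finite-length leakage stays in-band, and — when the target
    duration is known — snapped to the Fourier grid ``k / duration`` so the
    components are orthogonal over the realisation and the realised band
    variance matches the configured power tightly. Amplitudes are
    deterministic (sum of a_k^2/2 = power); only the phases are random.
    """
    lo, hi = band
    bw = hi - lo
    f_lo, f_hi = lo + 0.05 * bw, hi - 0.05 * bw
    if duration is not None and duration * (f_hi - f_lo) >= 2:
        k_lo, k_hi = int(np.ceil(f_lo * duration)), int(np.floor(f_hi * duration))
        ks = np.unique(np.round(np.linspace(k_lo, k_hi, min(n_components, k_hi - k_lo + 1))))
        freqs = ks / duration
    else:
        freqs = np.linspace(f_lo, f_hi, n_components)
    n = len(freqs)
    amps = np.full(n, np.sqrt(2.0 * power / n)) if power > 0 else np.zeros(n)
    phases = rng.uniform(0.0, 2.0 * np.pi, n)
    return freqs, amps, phases


class _RRModulation:
    """Instantaneous RR deviation (ms) around the mean, as a function of time."""

    def __init__(self, lf_power: float, hf_power: float, rng,
                 lf_band=LF_BAND, hf_band=HF_BAND, n_lf: int = 24, n_hf: int = 40,
                 duration: float | None = None):
        f1, a1, p1 = _band_modulation(lf_band, lf_power, n_lf, rng, duration)
        f2, a2, p2 = _band_modulation(hf_band, hf_power, n_hf, rng, duration)
        self.freqs = np.concatenate([f1, f2])
        self.amps = np.concatenate([a1, a2])
        self.phases = np.concatenate([p1, p2])

    def __call__(self, t: float) -> float:
        return float(np.sum(self.amps * np.cos(2.0 * np.pi * self.freqs * t + self.phases)))


def simulate_rr(
    duration: float,
    mean_hr: float = 60.0,
    lf_power: float = 0.0,
    hf_power: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an RR series with prescribed LF and HF band powers.

    Parameters
    ----------
    duration : float
        Span to cover, seconds.
    mean_hr : float
        Mean heart rate in beats/min, within [30, 200].
    lf_power, hf_power : float
        Target band powers of the RR series, ms^2.
    seed : int or Generator
        Randomness source (phases only; amplitudes are deterministic).

    Returns
    -------
    (rr_ms, beat_times) : ndarray, ndarray
        RR intervals in ms and strictly increasing beat times in s
        (first beat at t = 0).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if not 30.0 <= mean_hr <= 200.0:
        raise ValueError(f"mean_hr must be in [30, 200] bpm, got {mean_hr}")
    if lf_power < 0 or hf_power < 0:
        raise ValueError("band powers must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mod = _RRModulation(lf_power, hf_power, rng, duration=duration)
    mean_rr = 60000.0 / mean_hr

    beats = [0.0]
    t = 0.0
    while True:
        rr = float(np.clip(mean_rr + mod(t), 300.0, 2000.0))
        t += rr / 1000.0
        if t > duration:
            break
        beats.append(t)
    beat_times = np.asarray(beats)
    rr_ms = np.diff(beat_times) * 1000.0
    return rr_ms, beat_times


# Stylised P-QRS-T template: (relative amplitude, centre offset s, Gaussian sigma s)
_PQRST = (
    (0.12, -0.17, 0.025),   # P
    (-0.10, -0.020, 0.010), # Q
    (1.00, 0.0, 0.012),     # R
    (-0.17, 0.025, 0.010),  # S
    (0.30, 0.26, 0.060),    # T
)


def synthesize_ecg(
    rr_series=None,
    config: AcquisitionConfig = AcquisitionConfig(),
    amplitude_mv: float = 1.0,
    *,
    beat_times=None,
    duration: float | None = None,
    noise_mv: float = 0.0,
    cal: ChannelCalibration | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, int]:
    """Synthesise an ECG ADC stream from an RR series or explicit beat times.

    The R peak of each stylised P-QRS-T template sits exactly at its
    ground-truth beat time; ``amplitude_mv`` is the R amplitude in mV.
    Returns ``(stream, n_saturated)`` where ``n_saturated`` counts samples
    clipped at the rails (an amplitude beyond the representable range of
    the transfer function shows up here).
    """
    if beat_times is None:
        if rr_series is None:
            raise ValueError("provide rr_series or beat_times")
        rr = np.asarray(rr_series, dtype=float)
        beat_times = (np.cumsum(rr) - rr[0]) / 1000.0
    beat_times = np.asarray(beat_times, dtype=float)
    if duration is None:
        duration = float(beat_times[-1] + 0.5) if beat_times.size else 1.0
    fs = config.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x_mv = np.zeros(n)
    # Each template only spans ~0.8 s; add it on a local slice.
    for bt in beat_times:
        lo = max(0, int((bt - 0.45) * fs))
        hi = min(n, int((bt + 0.75) * fs) + 1)
        if lo >= hi:
            continue
        tt = t[lo:hi] - bt
        for a, c, s in _PQRST:
            x_mv[lo:hi] += amplitude_mv * a * np.exp(-0.5 * ((tt - c) / s) ** 2)
    if noise_mv > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        x_mv = x_mv + rng.normal(0.0, noise_mv, n)
    if cal is None:
        cal = ChannelCalibration(n=config.resolution_bits, vcc=config.vcc)
    code_unclipped = volts_to_ecg_code(x_mv / 1000.0, cal, clip=False)
    n_saturated = int(np.sum((code_unclipped < 0) | (code_unclipped > cal.max_code)))
    return np.clip(code_unclipped, 0, cal.max_code).astype(np.int64), n_saturated


def synthesize_auxiliary(
    kind: str,
    duration: float,
    config: AcquisitionConfig = AcquisitionConfig(),
    seed: int | np.random.Generator = 0,
    *,
    beat_times=None,
    event_times=None,
    resp_freq_hz: float | None = None,
    tonic_base_us: float = 4.0,
    tonic_slope_us_per_s: float = 0.01,
    phasic_amp_us: float = 0.6,
    noise_frac: float = 0.0,
) -> np.ndarray:
    """Synthesise an auxiliary channel (EDA, PZT or PPG) as ADC codes.

    EDA: tonic drift (base + slope*t) with event-locked phasic bumps at
    ``event_times``; converted to codes through the inverse EDA transfer.
    PZT: quasi-sinusoidal breathing at ``resp_freq_hz`` (default drawn in
    0.2-0.4 Hz), centred at mid-scale.
    PPG: baseline plus one pulse per entry of ``beat_times``.
    """
    kind = kind.upper()
    if kind not in {"EDA", "PZT", "PPG"}:
        raise ValueError(f"unknown auxiliary channel kind: {kind!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = config.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    mid = config.full_scale // 2
    cal = ChannelCalibration(n=config.resolution_bits, vcc=config.vcc)

    if kind == "EDA":
        us = tonic_base_us + tonic_slope_us_per_s * t
        if event_times is not None:
            for t0 in np.asarray(event_times, dtype=float):
                tau = t - t0
                m = tau > 0
                # Skin-conductance-response shape: fast rise, slow recovery.
                us[m] += phasic_amp_us * (1.0 - np.exp(-tau[m] / 0.75)) * np.exp(-tau[m] / 2.0)
        if noise_frac > 0:
            us = us + rng.normal(0.0, noise_frac * cal.eda_full_scale, n)
        code = microsiemens_to_eda_code(us, cal)
    elif kind == "PZT":
        f = resp_freq_hz if resp_freq_hz is not None else float(rng.uniform(0.2, 0.4))
        phase = float(rng.uniform(0.0, 2.0 * np.pi)) if resp_freq_hz is None else 0.0
        amp = 0.25 * config.full_scale / 2
        x = mid + amp * np.sin(2.0 * np.pi * f * t + phase)
        if noise_frac > 0:
            x = x + rng.normal(0.0, noise_frac * config.full_scale, n)
        code = np.rint(x).astype(np.int64)
    else:  # PPG
        x = np.full(n, float(mid))
        amp = 0.2 * config.full_scale / 2
        if beat_times is not None:
            for bt in np.asarray(beat_times, dtype=float):
                c = bt + 0.25  # pulse-transit delay after the R peak
                lo = max(0, int((c - 0.3) * fs))
                hi = min(n, int((c + 0.3) * fs) + 1)
                if lo >= hi:
                    continue
                tt = t[lo:hi] - c
                x[lo:hi] += amp * np.exp(-0.5 * (tt / 0.06) ** 2)
        if noise_frac > 0:
            x = x + rng.normal(0.0, noise_frac * config.full_scale, n)
        code = np.rint(x).astype(np.int64)
    return np.clip(code, 0, cal.max_code)


def inject_artifact(
    stream,
    interval: tuple[float, float],
    kind: str,
    fs: float = 1000.0,
    n_bits: int = 10,
    *,
    value: int | None = None,
    seed: int | np.random.Generator = 0,
    channel: str = "ECG",
) -> tuple[np.ndarray, ArtifactRecord | None]:
    """Inject one artifact episode into a copy of the stream.

    Kinds: ``flatline`` (constant code, default the low rail — a detached
    electrode), ``saturation`` (high rail, or ``value`` to pick a rail),
    ``spike_burst`` (additive motion transients). Samples outside the
    interval are untouched. An empty interval is a no-op returning no
    artifact record.
    """
    if kind not in {"flatline", "saturation", "spike_burst"}:
        raise ValueError(f"unknown artifact kind: {kind!r}")
    x = np.asarray(stream).copy()
    t0, t1 = interval
    if t1 <= t0:
        import warnings

        warnings.warn(f"empty artifact interval {interval}; no-op", stacklevel=2)
        return x, None
    if t0 < 0 or t1 > len(x) / fs:
        raise ValueError(f"interval {interval} outside stream span [0, {len(x)/fs:.1f}]")
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    max_code = 2**n_bits - 1
    if kind == "flatline":
        x[i0:i1] = 0 if value is None else int(value)
    elif kind == "saturation":
        x[i0:i1] = max_code if value is None else int(value)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_spikes = max(1, int(round((t1 - t0) * 3.0)))  # ~3 transients/s
        centers = rng.uniform(i0, i1, n_spikes).astype(int)
        width = max(int(0.02 * fs), 1)
        for c in centers:
            lo, hi = max(i0, c - width), min(i1, c + width)
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.5) * max_code
            x[lo:hi] = np.clip(x[lo:hi] + amp, 0, max_code)
    return x, ArtifactRecord(start=t0, end=t1, kind=kind, channel=channel)


def build_timeline(
    products,
    seed: int | np.random.Generator = 0,
    *,
    baseline_s: float = 60.0,
    visual_s: float = 10.0,
    tasting_s: float = 60.0,
    question_s: float = 120.0,
    gap_s: float = 5.0,
) -> EventTimeline:
    """Build one session timeline: baseline, visual stimuli, tastings.

    The protocol stages are a relaxation baseline, randomised-order 10-s
    visual stimuli (one per product), then per product — again in random
    order — a 60-s tasting followed by a question phase long enough
    (default 120 s) that the full 2.5-min contact window always fits.
    """
    products = list(products)
    if not products:
        raise ValueError("need at least one product")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[Event] = [Event("baseline", None, 0.0, baseline_s)]
    t = baseline_s + gap_s
    for p in rng.permutation(products):
        events.append(Event("visual_stimulus", str(p), t, visual_s))
        t += visual_s + gap_s
    for p in rng.permutation(products):
        events.append(Event("tasting_onset", str(p), t, tasting_s))
        t += tasting_s
        events.append(Event("question_phase", str(p), t, question_s))
        t += question_s + gap_s
    events.append(Event("session_end", None, t, 0.0))
    return EventTimeline(events)


def simulate_scores(
    n_subjects: int,
    n_sessions: int,
    product_score_means: dict[str, float],
    score_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate questionnaire responses: 9-point global acceptance plus NPS.

    Hedonic scores are rounded, clipped draws around each product mean;
    the 0-10 recommendation response is derived from the same latent
    liking (rescaled to the NPS range with unit noise), so the two scales
    agree in direction.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    bad = {p: m for p, m in product_score_means.items() if not 1.0 <= m <= 9.0}
    if bad:
        raise ValueError(f"score means must lie on the 9-point scale [1, 9]: {bad}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        subject = f"S{si + 1:03d}"
        for sess in range(1, n_sessions + 1):
            for product, mean in product_score_means.items():
                latent = rng.normal(mean, score_sd)
                score = int(np.clip(np.rint(latent), 1, 9))
                nps = int(np.clip(np.rint((latent - 1.0) * 10.0 / 8.0 + rng.normal(0.0, 1.0)), 0, 10))
                rows.append((subject, sess, product, "global_acceptance", score))
                rows.append((subject, sess, product, "nps_recommend", nps))
    return pd.DataFrame(rows, columns=["subject", "session", "product", "question", "response"])


def draw_window_powers(
    score: float,
    base_lf: float,
    base_hf: float,
    coupling: float = 0.0,
    jitter_sd: float = 0.4,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Draw per-window LF/HF powers, optionally conditioned on the score.

    With ``coupling > 0`` a low acceptance score raises both band powers:
    the base power is multiplied by ``exp(coupling * (5 - score) / 4)``
    (neutral at the scale midpoint 5) before lognormal between-window
    jitter. ``coupling = 0`` (default) leaves powers independent of the
    score.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    mult = np.exp(coupling * (5.0 - score) / 4.0)
    lf = base_lf * mult * np.exp(rng.normal(0.0, jitter_sd))
    hf = base_hf * mult * np.exp(rng.normal(0.0, jitter_sd))
    return float(lf), float(hf)


def _piecewise_beat_times(
    segments: list[tuple[float, float, float, float]],
    mean_hr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Beat times over contiguous segments of (t0, t1, lf_power, hf_power)."""
    mean_rr = 60000.0 / mean_hr
    beats = [0.0]
    t = 0.0
    for t0, t1, lf, hf in segments:
        mod = _RRModulation(lf, hf, rng, duration=t1 - t0)
        while True:
            rr = float(np.clip(mean_rr + mod(t - t0), 300.0, 2000.0))
            if t + rr / 1000.0 > t1:
                break
            t += rr / 1000.0
            beats.append(t)
    return np.asarray(beats)


@dataclass
class CohortConfig:
    """Study-scale configuration for a synthetic cohort.

    Defaults mirror the study conditions: four products, three sessions,
    10-bit/1 kHz acquisition, 9-point acceptance scores around per-product
    means, and physiological base band powers typical of short-term
    recordings at rest.
    """

    n_subjects: int = 2
    n_sessions: int = 3
    products: tuple[str, ...] = ("bar", "cheese", "cookie", "milk")
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    score_means: dict[str, float] = field(
        default_factory=lambda: {"bar": 7.0, "cheese": 7.5, "cookie": 6.5, "milk": 5.0}
    )
    score_sd: float = 1.5
    mean_hr: float = 70.0
    base_lf_ms2: float = 600.0
    base_hf_ms2: float = 400.0
    coupling: float = 0.0
    jitter_sd: float = 0.4
    ecg_amplitude_mv: float = 1.0
    ecg_noise_mv: float = 0.01
    artifact_rate: float = 0.0  # probability a session gets one injected episode
    seed: int = 0


@dataclass
class SimulatedSession:
    subject: str
    session: int
    timeline: EventTimeline
    streams: dict[str, np.ndarray]
    ground_truth: GroundTruth
    scores: dict[str, int]


def simulate_session(
    cfg: CohortConfig,
    subject: str,
    session: int,
    scores: dict[str, int],
    rng: np.random.Generator,
) -> SimulatedSession:
    """Simulate one full session: timeline, four channels, ground truth.

    Within each product-contact window the RR band powers are drawn via
    :func:`draw_window_powers` from that product's acceptance score;
    outside the windows the cohort base powers apply.
    """
    timeline = build_timeline(cfg.products, rng)
    duration = timeline.end + 5.0
    windows = []
    lf_true: dict[str, float] = {}
    hf_true: dict[str, float] = {}
    for p in timeline.products:
        onset = timeline.tasting_onset(p).onset
        lf, hf = draw_window_powers(
            scores[p], cfg.base_lf_ms2, cfg.base_hf_ms2, cfg.coupling, cfg.jitter_sd, rng
        )
        lf_true[p], hf_true[p] = lf, hf
        windows.append((onset, onset + CONTACT_WINDOW_S, lf, hf))
    windows.sort()
    segments = []
    t = 0.0
    for t0, t1, lf, hf in windows:
        if t0 > t:
            segments.append((t, t0, cfg.base_lf_ms2, cfg.base_hf_ms2))
        segments.append((t0, t1, lf, hf))
        t = t1
    if t < duration:
        segments.append((t, duration, cfg.base_lf_ms2, cfg.base_hf_ms2))

    beat_times = _piecewise_beat_times(segments, cfg.mean_hr, rng)
    acq = cfg.acquisition
    ecg, n_sat = synthesize_ecg(
        beat_times=beat_times,
        config=acq,
        amplitude_mv=cfg.ecg_amplitude_mv,
        duration=duration,
        noise_mv=cfg.ecg_noise_mv,
        seed=rng,
    )
    phasic_events = [timeline.tasting_onset(p).onset for p in timeline.products]
    streams = {
        "ECG": ecg,
        "EDA": synthesize_auxiliary("EDA", duration, acq, rng, event_times=phasic_events),
        "PZT": synthesize_auxiliary("PZT", duration, acq, rng),
        "PPG": synthesize_auxiliary("PPG", duration, acq, rng, beat_times=beat_times),
    }
    gt = GroundTruth(
        beat_times=beat_times,
        lf_power_true=lf_true,
        hf_power_true=hf_true,
        score_means=dict(cfg.score_means),
        saturation_warnings=n_sat,
    )
    if cfg.artifact_rate > 0 and rng.uniform() < cfg.artifact_rate:
        kind = rng.choice(["flatline", "saturation", "spike_burst"])
        t0 = float(rng.uniform(0.0, duration - 15.0))
        streams["ECG"], rec = inject_artifact(
            streams["ECG"], (t0, t0 + 12.0), str(kind), acq.sampling_rate,
            acq.resolution_bits, seed=rng,
        )
        if rec is not None:
            gt.injected_artifacts.append(rec)
    return SimulatedSession(subject, session, timeline, streams, gt, scores)


def simulate_cohort(cfg: CohortConfig, out_dir: str | Path | None = None):
    """Simulate a cohort; optionally write it to disk.

    Returns ``(sessions, score_table)``. With ``out_dir`` given, writes one
    recording CSV + timeline CSV + ground-truth JSON sidecar per
    subject x session, and a single questionnaire CSV.
    """
    rng = np.random.default_rng(cfg.seed)
    table = simulate_scores(cfg.n_subjects, cfg.n_sessions, cfg.score_means, cfg.score_sd, rng)
    ga = table[table["question"] == "global_acceptance"]
    sessions = []
    for si in range(cfg.n_subjects):
        subject = f"S{si + 1:03d}"
        for sess in range(1, cfg.n_sessions + 1):
            rows = ga[(ga["subject"] == subject) & (ga["session"] == sess)]
            scores = dict(zip(rows["product"], rows["response"]))
            sessions.append(simulate_session(cfg, subject, sess, scores, rng))

    if out_dir is not None:
        from .io import write_questionnaire, write_recording, write_timeline
        from .core import RawRecording

        out = Path(out_dir)
        (out / "recordings").mkdir(parents=True, exist_ok=True)
        (out / "timelines").mkdir(parents=True, exist_ok=True)
        for s in sessions:
            stem = f"{s.subject}_ses{s.session}"
            rec = RawRecording(
                config=cfg.acquisition, streams=s.streams,
                subject=s.subject, session=s.session,
            )
            write_recording(rec, out / "recordings" / f"{stem}.csv")
            write_timeline(s.timeline, out / "timelines" / f"{stem}.csv")
            gt = s.ground_truth
            sidecar = {
                "beat_times": np.round(gt.beat_times, 6).tolist(),
                "injected_artifacts": [
                    {"start": a.start, "end": a.end, "kind": a.kind, "channel": a.channel}
                    for a in gt.injected_artifacts
                ],
                "lf_power_true": gt.lf_power_true,
                "hf_power_true": gt.hf_power_true,
                "saturation_warnings": gt.saturation_warnings,
            }
            (out / "recordings" / f"{stem}.groundtruth.json").write_text(
                json.dumps(sidecar, sort_keys=True)
            )
        write_questionnaire(table, out / "questionnaire.csv")
    return sessions, table
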