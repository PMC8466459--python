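"""ECG processing chain and frequency-domain heart-rate-variability features.

The chain mirrors standard short-term HRV practice:

1. ``preprocess`` — zero-phase Butterworth band-pass (order 3, 0.5-40 Hz)
   plus a 50 Hz notch for residual powerline interference, then
   z-normalisation of the waveform.
2. ``detect_rpeaks`` — a Hamilton-style detector: rectified first
   difference, 80-ms moving-average integration, adaptive signal/noise
   thresholding with a 200-ms refractory period, and peak refinement on
   the filtered waveform.
3. ``extract_templates`` / ``template_outlier_fraction`` — beat-centred
   waveform windows (-200/+400 ms) clustered with DBSCAN after
   per-template amplitude normalisation; density-noise templates form the
   outlier cluster. Recordings whose outlier fraction exceeds 5% are
   eliminated (``accept_recording``).
4. ``rr_from_peaks`` / ``band_powers`` — RR-interval series (implausible
   intervals outside 300-2000 ms dropped), cubic interpolation to a
   uniform 4 Hz tachogram, linear detrend, Welch averaged-periodogram
   spectral density, and integrated low-frequency (0.04-0.15 Hz) and
   high-frequency (0.15-0.40 Hz) band powers in ms^2.

Features are computed over product-contact windows: the 2.5 minutes from
tasting onset (1 min of tasting + 1.5 min of question answering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal
from sklearn.cluster import DBSCAN
from sklearn.metrics import pairwise_distances

from .core import EventTimeline

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "CONTACT_WINDOW_S",
    "OUTLIER_FRACTION_MAX",
    "RRSeries",
    "HeartbeatTemplateSet",
    "HRVFeatures",
    "WindowTruncatedError",
    "preprocess",
    "detect_rpeaks",
    "extract_templates",
    "template_outlier_fraction",
    "accept_recording",
    "rr_from_peaks",
    "band_powers",
    "contact_window",
]

#: Standard short-term HRV frequency bands, Hz.
LF_BAND: tuple[float, float] = (0.04, 0.15)
HF_BAND: tuple[float, float] = (0.15, 0.40)

#: Product-contact window length in seconds (1 min tasting + 1.5 min questions).
CONTACT_WINDOW_S: float = 150.0

#: Recordings with more than this fraction of outlier heartbeat templates
#: are eliminated.
OUTLIER_FRACTION_MAX: float = 0.05

#: Plausible RR interval range, ms; intervals outside are dropped.
RR_MIN_MS: float = 300.0
RR_MAX_MS: float = 2000.0

#: Template window around the R peak, seconds.
TEMPLATE_WINDOW_S: tuple[float, float] = (-0.2, 0.4)

#: Uniform resampling rate for the RR tachogram, Hz.
TACHOGRAM_FS: float = 4.0


class WindowTruncatedError(ValueError):
    """The recording ends before the contact window does."""


@dataclass
class RRSeries:
    """RR-interval series: interval end times (s) and interval lengths (ms)."""

    times: np.ndarray
    intervals: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.times.shape != self.intervals.shape:
            raise ValueError("times and intervals must have equal length")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) > 1 else 0.0

    def restrict(self, t0: float, t1: float) -> "RRSeries":
        """Intervals whose end time falls in [t0, t1)."""
        m = (self.times >= t0) & (self.times < t1)
        return RRSeries(self.times[m], self.intervals[m], self.n_dropped)


@dataclass
class HeartbeatTemplateSet:
    """Fixed-length beat-centred waveform windows with cluster labels."""

    templates: np.ndarray  # (n_beats, window_len)
    peak_indices: np.ndarray
    labels: np.ndarray | None = None  # DBSCAN labels; -1 = outlier

    @property
    def outlier_fraction(self) -> float:
        if self.labels is None:
            raise ValueError("templates have not been clustered yet")
        if len(self.labels) == 0:
            raise ValueError("outlier fraction undefined for an empty template set")
        return float(np.mean(self.labels == -1))


@dataclass(frozen=True)
class HRVFeatures:
    """Absolute and normalised LF/HF band powers for one analysis window."""

    lf_power: float  # ms^2
    hf_power: float  # ms^2
    n_beats: int = 0

    @property
    def lf_norm(self) -> float:
        tot = self.lf_power + self.hf_power
        return self.lf_power / tot if tot > 0 else float("nan")

    @property
    def hf_norm(self) -> float:
        tot = self.lf_power + self.hf_power
        return self.hf_power / tot if tot > 0 else float("nan")

    @property
    def lf_hf_ratio(self) -> float:
        return self.lf_power / self.hf_power if self.hf_power > 0 else float("inf")


def preprocess(
    ecg_volts,
    fs: float,
    band: tuple[float, float] = (0.5, 40.0),
    order: int = 3,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    normalize: bool = True,
) -> np.ndarray:
    """Band-pass + notch filter (zero-phase) and z-normalise an ECG waveform.

    Filters are applied forward-backward (``filtfilt``) so R-peak timing is
    not shifted. Requires ``fs`` comfortably above twice the band's upper
    edge. ``normalize=False`` returns the filtered waveform on its input
    scale (useful when inspecting the filters' magnitude response).
    """
    x = np.asarray(ecg_volts, dtype=float)
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for a {band[1]} Hz band edge")
    if len(x) < int(10 * fs):
        raise ValueError("need at least 10 s of signal")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    if notch_hz and notch_hz < fs / 2:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
        y = signal.filtfilt(b, a, y)
    if normalize:
        sd = y.std()
        if sd > 0:
            y = (y - y.mean()) / sd
    return y


def _detection_function(x: np.ndarray, fs: float) -> np.ndarray:
    d = np.abs(np.diff(x, prepend=x[0]))
    w = max(int(round(0.08 * fs)), 1)
    return np.convolve(d, np.ones(w) / w, mode="same")


def detect_rpeaks(
    filtered, fs: float, refractory_s: float = 0.2, edge_margin_s: float = 0.3
) -> np.ndarray:
    """Detect R peaks in a preprocessed ECG.

    Hamilton-style: local maxima of the integrated rectified derivative are
    screened by an adaptive threshold between running signal and noise
    levels; accepted detections are refined to the largest absolute
    waveform deflection within +-100 ms, with the refractory period
    enforced on the refined positions. Detections within
    ``edge_margin_s`` of either end are discarded — the zero-phase
    filters leave edge transients there and a beat straddling the
    boundary has no complete waveform.

    Returns strictly increasing sample indices (possibly empty).
    """
    x = np.asarray(filtered, dtype=float)
    if x.size == 0 or x.std() == 0:
        return np.empty(0, dtype=int)
    det = _detection_function(x, fs)
    dist = max(int(round(refractory_s * fs)), 1)
    cand, _ = signal.find_peaks(det, distance=dist)
    if cand.size == 0:
        return np.empty(0, dtype=int)

    # Adaptive two-level thresholding over candidate heights.
    init = det[: int(2 * fs)] if len(det) >= int(2 * fs) else det
    spk = float(init.max())
    npk = float(np.mean(det))
    accepted = []
    for i in cand:
        thr = npk + 0.3125 * (spk - npk)
        if det[i] >= thr:
            accepted.append(i)
            spk = 0.125 * det[i] + 0.875 * spk
        else:
            npk = 0.125 * det[i] + 0.875 * npk
    if not accepted:
        return np.empty(0, dtype=int)

    # Refine to the dominant deflection of the waveform near each detection.
    half = int(round(0.1 * fs))
    refined = []
    for i in accepted:
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = np.unique(refined)

    # Enforce refractory on refined positions, keeping the larger deflection.
    out: list[int] = []
    for i in refined:
        if out and i - out[-1] < dist:
            if np.abs(x[i]) > np.abs(x[out[-1]]):
                out[-1] = int(i)
        else:
            out.append(int(i))
    peaks = np.asarray(out, dtype=int)
    margin = int(round(edge_margin_s * fs))
    return peaks[(peaks >= margin) & (peaks < len(x) - margin)]


def extract_templates(
    filtered,
    peaks,
    fs: float,
    window: tuple[float, float] = TEMPLATE_WINDOW_S,
) -> HeartbeatTemplateSet:
    """Cut fixed-length beat-centred windows around each R peak.

    Beats whose window would run past either end of the signal are dropped.
    """
    x = np.asarray(filtered, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    before = int(round(-window[0] * fs))
    after = int(round(window[1] * fs))
    keep = peaks[(peaks - before >= 0) & (peaks + after <= len(x))]
    templates = np.stack([x[p - before : p + after] for p in keep]) if keep.size else np.empty(
        (0, before + after)
    )
    return HeartbeatTemplateSet(templates=templates, peak_indices=keep)


def template_outlier_fraction(
    template_set: HeartbeatTemplateSet,
    eps: float | None = None,
    min_samples: int = 5,
) -> HeartbeatTemplateSet:
    """Label heartbeat templates with DBSCAN; density noise = outlier cluster.

    Templates are amplitude-normalised (unit max-absolute) before Euclidean
    clustering so the grouping reflects morphology, not beat-to-beat gain.
    When ``eps`` is not given it defaults to twice the median pairwise
    distance between normalised templates (with a small positive floor):
    typical beats then sit well inside each other's neighbourhoods while
    morphologically distinct beats — whose distances are many times the
    median — fall outside.
    """
    T = template_set.templates
    if len(T) < min_samples:
        raise ValueError(
            f"need at least min_samples={min_samples} templates, got {len(T)}"
        )
    scale = np.max(np.abs(T), axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    Tn = T / scale
    if eps is None:
        d = pairwise_distances(Tn)
        med = float(np.median(d[np.triu_indices_from(d, k=1)]))
        eps = max(2.0 * med, 1e-6)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(Tn)
    return HeartbeatTemplateSet(
        templates=T, peak_indices=template_set.peak_indices, labels=labels
    )


def accept_recording(outlier_fraction: float) -> str:
    """``eliminated`` iff the outlier-template fraction exceeds 5%."""
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {outlier_fraction}")
    return "eliminated" if outlier_fraction > OUTLIER_FRACTION_MAX else "retained"


def rr_from_peaks(peaks, fs: float) -> RRSeries:
    """Build the RR series from R-peak sample indices.

    Intervals outside the physiologically plausible 300-2000 ms range are
    dropped; the drop count is kept on the series.
    """
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 3:
        raise ValueError(f"need at least 3 beats, got {len(peaks)}")
    t = peaks / fs
    rr = np.diff(t) * 1000.0
    times = t[1:]
    ok = (rr >= RR_MIN_MS) & (rr <= RR_MAX_MS)
    return RRSeries(times[ok], rr[ok], n_dropped=int(np.sum(~ok)))


def band_powers(
    rr: RRSeries,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    tachogram_fs: float = TACHOGRAM_FS,
    min_span_s: float = 120.0,
) -> HRVFeatures:
    """Integrated LF and HF band powers of an RR series, in ms^2.

    The irregular RR series is cubic-interpolated to a uniform tachogram,
    linearly detrended, and its spectral density estimated by Welch's
    averaged periodogram; band powers are the integrals of the density
    over each band.
    """
    if rr.span < min_span_s:
        raise ValueError(
            f"RR span {rr.span:.1f} s is below the {min_span_s:.0f} s minimum"
        )
    t0, t1 = rr.times[0], rr.times[-1]
    n = int(np.floor((t1 - t0) * tachogram_fs)) + 1
    tu = t0 + np.arange(n) / tachogram_fs
    kind = "cubic" if len(rr.times) >= 4 else "linear"
    f = interpolate.interp1d(rr.times, rr.intervals, kind=kind)
    x = signal.detrend(f(tu), type="linear")
    nperseg = min(len(x), 256)
    freqs, psd = signal.welch(x, fs=tachogram_fs, nperseg=nperseg, noverlap=nperseg // 2)

    def integrate(band: tuple[float, float]) -> float:
        m = (freqs >= band[0]) & (freqs < band[1])
        return float(np.trapezoid(psd[m], freqs[m])) if np.sum(m) > 1 else 0.0

    return HRVFeatures(
        lf_power=integrate(lf_band),
        hf_power=integrate(hf_band),
        n_beats=len(rr.intervals) + 1,
    )


def contact_window(
    timeline: EventTimeline,
    product: str,
    recording_end: float | None = None,
    window_s: float = CONTACT_WINDOW_S,
) -> tuple[float, float]:
    """Half-open product-contact window ``[onset, onset + 150 s)``.

    Raises :class:`WindowTruncatedError` when the recording is known to end
    before the window does; such windows are excluded from analysis.
    """
    onset = timeline.tasting_onset(product).onset
    end = onset + window_s
    if recording_end is not None and recording_end < end:
        raise WindowTruncatedError(
            f"recording ends at {recording_end:.1f} s, before window end {end:.1f} s"
        )
    return (onset, end)
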