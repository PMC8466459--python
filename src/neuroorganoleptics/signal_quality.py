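"""Signal-quality pre-validation for acquisition sessions.

Before any feature extraction, each recording is screened segment by
segment. For every segment the screen extracts two basic statistics — the
mean and standard deviation of the raw codes, expressed as fractions of
full scale — and converts them into membership probabilities over three
reference clusters centred at 20%, 50% and 90% of full scale. The cluster
centres correspond to where healthy channels sit: a well-attached ECG
electrode pair idles around mid-scale, EDA sits low, and a railed or
detached channel drifts toward the extremes.

Membership is modelled as a Gaussian likelihood of the segment mean at
each cluster centre with scale ``max(segment std, MIN_SCALE)``,
renormalised across the three clusters. This uses exactly the two
statistics the screen extracts; the floor keeps zero-variance segments
from producing degenerate likelihoods.

Decision rules:

* an ECG segment whose mid-cluster (50% FS) membership falls below 0.70
  is flagged ``noisy``;
* a segment with zero variance sitting at a rail code (0 or ``2**n - 1``)
  is flagged ``lost`` (complete signal loss, e.g. electrode detachment);
* only ECG problems are session-fatal: the verdict is ``repeat_required``
  iff any ECG segment is noisy or lost. Abnormal behaviour on the other
  channels is recorded but never triggers a repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "CLUSTER_CENTERS",
    "ECG_MID_CLUSTER_MIN",
    "SegmentFlag",
    "QualityReport",
    "cluster_membership",
    "flag_segment",
    "assess_channel",
    "assess_recording",
    "session_verdict",
]

#: Cluster centres as fractions of full scale.
CLUSTER_CENTERS: tuple[float, float, float] = (0.20, 0.50, 0.90)

#: ECG segments need at least this mid-cluster membership to pass.
ECG_MID_CLUSTER_MIN: float = 0.70

#: Floor on the Gaussian scale, in fractions of full scale.
MIN_SCALE: float = 0.02

#: Default segmentation, seconds, non-overlapping.
DEFAULT_SEGMENT_S: float = 10.0


class SegmentFlag(str, Enum):
    OK = "ok"
    NOISY = "noisy"
    LOST = "lost"


@dataclass
class QualityReport:
    """Per-segment quality table plus the session verdict.

    ``table`` columns: channel, segment (index), start_s, mean_fs, std_fs,
    p20, p50, p90, flag.
    """

    table: pd.DataFrame
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = session_verdict(self.table)

    @property
    def repeat_required(self) -> bool:
        return self.verdict == "repeat_required"


def cluster_membership(
    segment,
    n: int = 10,
    centers: tuple[float, ...] = CLUSTER_CENTERS,
    min_scale: float = MIN_SCALE,
) -> np.ndarray:
    """Membership probabilities of a raw-code segment over the FS clusters.

    Parameters
    ----------
    segment : array-like
        Raw ADC codes for one segment of one channel.
    n : int
        ADC resolution in bits; full scale is ``2**n``.

    Returns
    -------
    ndarray of shape (len(centers),), non-negative, summing to 1.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise ValueError("empty segment")
    fs = float(2**n)
    m = seg.mean() / fs
    s = max(seg.std() / fs, min_scale)
    c = np.asarray(centers, dtype=float)
    # Gaussian log-likelihood of the segment mean at each centre, shared scale.
    loglik = -0.5 * ((m - c) / s) ** 2
    loglik -= loglik.max()
    w = np.exp(loglik)
    return w / w.sum()


def _is_rail_flat(segment, n: int) -> bool:
    seg = np.asarray(segment, dtype=float)
    if seg.std() != 0.0:
        return False
    code = seg[0]
    return code == 0 or code == 2**n - 1


def flag_segment(
    membership,
    channel_role: str,
    *,
    rail_flat: bool = False,
    ecg_threshold: float = ECG_MID_CLUSTER_MIN,
) -> SegmentFlag:
    """Flag one segment from its cluster membership.

    ECG segments are noisy when their mid-cluster membership is strictly
    below ``ecg_threshold`` (membership exactly at the threshold passes).
    Segments of any role that are flat at a rail code are ``lost``.
    Non-ECG roles are never flagged noisy — their flags are informative
    only and the verdict ignores them.
    """
    role = channel_role.upper()
    if role not in {"ECG", "EDA", "PZT", "PPG"}:
        raise ValueError(f"unknown channel role: {channel_role!r}")
    if rail_flat:
        return SegmentFlag.LOST
    p = np.asarray(membership, dtype=float)
    if role == "ECG" and p[1] < ecg_threshold:
        return SegmentFlag.NOISY
    return SegmentFlag.OK


def assess_channel(
    stream,
    channel_role: str,
    fs: float,
    n: int = 10,
    segment_s: float = DEFAULT_SEGMENT_S,
) -> pd.DataFrame:
    """Segment one channel and flag every segment.

    Non-overlapping segments of ``segment_s`` seconds; a trailing partial
    segment of at least one second is kept.
    """
    stream = np.asarray(stream)
    seg_len = int(round(segment_s * fs))
    min_len = int(round(fs))  # at least 1 s of samples
    rows = []
    idx = 0
    for start in range(0, len(stream), seg_len):
        seg = stream[start : start + seg_len]
        if len(seg) < min_len:
            break
        p = cluster_membership(seg, n=n)
        flag = flag_segment(p, channel_role, rail_flat=_is_rail_flat(seg, n))
        fsn = float(2**n)
        rows.append(
            {
                "channel": channel_role.upper(),
                "segment": idx,
                "start_s": start / fs,
                "mean_fs": seg.mean() / fsn,
                "std_fs": seg.std() / fsn,
                "p20": p[0],
                "p50": p[1],
                "p90": p[2],
                "flag": flag.value,
            }
        )
        idx += 1
    return pd.DataFrame(rows)


def assess_recording(
    streams: dict[str, np.ndarray],
    fs: float,
    n: int = 10,
    segment_s: float = DEFAULT_SEGMENT_S,
) -> QualityReport:
    """Run the pre-validation screen over all channels of a recording."""
    tables = [
        assess_channel(stream, role, fs=fs, n=n, segment_s=segment_s)
        for role, stream in streams.items()
    ]
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["channel", "segment", "start_s", "mean_fs", "std_fs", "p20", "p50", "p90", "flag"]
    )
    return QualityReport(table)


def session_verdict(table: pd.DataFrame) -> str:
    """``repeat_required`` iff any ECG segment is noisy or lost, else ``accept``."""
    if len(table) == 0:
        return "accept"
    ecg = table[table["channel"] == "ECG"]
    bad = ecg["flag"].isin([SegmentFlag.NOISY.value, SegmentFlag.LOST.value])
    return "repeat_required" if bool(bad.any()) else "accept"
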