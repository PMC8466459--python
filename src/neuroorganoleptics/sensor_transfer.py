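"""ADC-code <-> physical-unit transfer functions for the acquisition channels.

The acquisition unit samples each channel with an n-bit ADC (codes in
``[0, 2**n - 1]``) referenced to the circuit operating voltage VCC. Each
sensor has a published transfer function mapping a code to physical units:

* ECG:  ``ECG(V)  = (ADC / 2**n - 1/2) * VCC / G``   (G = analog gain)
* PZT:  ``PZT(%)  = (ADC / 2**n - 1/2) * 100``       (chest-strap displacement)
* EDA:  ``EDA(uS) = (ADC / 2**n) * VCC / 0.132``     (skin conductance)

All three use ``2**n`` (not ``2**n - 1``) as the normaliser, exactly as
published, so the positive range ends one quantisation step below the
nominal ceiling (e.g. the EDA full-scale 25 uS is attained only at the
nominal code ``2**n``). The PPG channel has no published transfer function;
it is exposed as a unitless min-max normalisation.

Functions vectorise over numpy arrays and validate code range by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelCalibration",
    "InvalidCodeError",
    "ecg_to_volts",
    "volts_to_ecg_code",
    "eda_to_microsiemens",
    "microsiemens_to_eda_code",
    "pzt_to_percent",
    "ppg_normalize",
]


class InvalidCodeError(ValueError):
    """An ADC code lies outside ``[0, 2**n - 1]``."""


@dataclass(frozen=True)
class ChannelCalibration:
    """Static calibration constants shared by the channel transfer functions.

    Parameters
    ----------
    n : int
        ADC resolution in bits (10 for the acquisition unit used here).
    vcc : float
        Operating voltage of the circuit in volts.
    gain_ecg : float
        ECG analog gain G. The study hardware was customised to 570; the
        sensor datasheet default of 1100 yields the nominal +-1.5 mV range.
    eda_divisor : float
        Scaling constant of the EDA transfer function, in V/uS.
    """

    n: int = 10
    vcc: float = 3.3
    gain_ecg: float = 570.0
    eda_divisor: float = 0.132

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"resolution must be >= 1 bit, got {self.n}")
        if self.vcc <= 0:
            raise ValueError(f"vcc must be positive, got {self.vcc}")
        if self.gain_ecg <= 0:
            raise ValueError(f"gain_ecg must be positive, got {self.gain_ecg}")

    @property
    def full_scale(self) -> int:
        """Number of quantisation levels, ``2**n``."""
        return 2**self.n

    @property
    def max_code(self) -> int:
        """Largest representable code, ``2**n - 1``."""
        return 2**self.n - 1

    @property
    def eda_full_scale(self) -> float:
        """Nominal EDA ceiling in uS (25.0 for VCC = 3.3 V)."""
        return self.vcc / self.eda_divisor

    @property
    def ecg_range_volts(self) -> float:
        """Half-range of the ECG channel in volts, ``VCC / (2 G)``."""
        return self.vcc / (2.0 * self.gain_ecg)


def _check_codes(adc, cal: ChannelCalibration) -> np.ndarray:
    a = np.asarray(adc, dtype=float)
    bad = (a < 0) | (a > cal.max_code)
    if np.any(bad):
        offending = np.atleast_1d(a)[np.atleast_1d(bad)][:5]
        raise InvalidCodeError(
            f"ADC code(s) outside [0, {cal.max_code}]: {offending.tolist()}"
        )
    return a


def ecg_to_volts(adc, cal: ChannelCalibration = ChannelCalibration(), *, validate: bool = True):
    """Convert ECG ADC codes to volts.

    Mid-scale (``2**(n-1)``) maps to 0 V; the representable range is
    ``[-VCC/(2G), +VCC/(2G))``.
    """
    a = _check_codes(adc, cal) if validate else np.asarray(adc, dtype=float)
    out = (a / cal.full_scale - 0.5) * cal.vcc / cal.gain_ecg
    return out if out.ndim else float(out)


def volts_to_ecg_code(volts, cal: ChannelCalibration = ChannelCalibration(), *, clip: bool = True):
    """Inverse ECG transfer: volts to integer codes (rounded, clipped by default)."""
    v = np.asarray(volts, dtype=float)
    code = np.rint((v * cal.gain_ecg / cal.vcc + 0.5) * cal.full_scale)
    if clip:
        code = np.clip(code, 0, cal.max_code)
    code = code.astype(np.int64)
    return code if code.ndim else int(code)


def eda_to_microsiemens(adc, cal: ChannelCalibration = ChannelCalibration(), *, validate: bool = True):
    """Convert EDA ADC codes to microsiemens; linear through zero."""
    a = _check_codes(adc, cal) if validate else np.asarray(adc, dtype=float)
    out = (a / cal.full_scale) * cal.vcc / cal.eda_divisor
    return out if out.ndim else float(out)


def microsiemens_to_eda_code(us, cal: ChannelCalibration = ChannelCalibration(), *, clip: bool = True):
    """Inverse EDA transfer: microsiemens to integer codes."""
    u = np.asarray(us, dtype=float)
    code = np.rint(u * cal.eda_divisor / cal.vcc * cal.full_scale)
    if clip:
        code = np.clip(code, 0, cal.max_code)
    code = code.astype(np.int64)
    return code if code.ndim else int(code)


def pzt_to_percent(adc, cal: ChannelCalibration = ChannelCalibration(), *, validate: bool = True):
    """Convert respiration (PZT) ADC codes to percent displacement in [-50, +50)."""
    a = _check_codes(adc, cal) if validate else np.asarray(adc, dtype=float)
    out = (a / cal.full_scale - 0.5) * 100.0
    return out if out.ndim else float(out)


def ppg_normalize(adc_stream, cal: ChannelCalibration = ChannelCalibration()) -> np.ndarray:
    """Min-max normalise a PPG stream to [0, 1].

    The PPG sensor has no published transfer function, so the channel is
    exposed unitless. A constant stream maps to 0.5 by convention.
    """
    a = np.asarray(adc_stream, dtype=float)
    if a.size == 0:
        raise ValueError("cannot normalise an empty stream")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.full_like(a, 0.5)
    return (a - lo) / (hi - lo)
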