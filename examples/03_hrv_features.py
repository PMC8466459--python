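"""From raw ADC codes to LF/HF band powers over a contact window.

Runs the full ECG chain — transfer function, band-pass + notch filtering,
R-peak detection, template-outlier screening, RR series, Welch band
powers — and compares the estimates with the generator's configured
powers.
"""

from neuroorganoleptics.core import AcquisitionConfig
from neuroorganoleptics.ecg_hrv import (
    RRSeries,
    accept_recording,
    band_powers,
    detect_rpeaks,
    extract_templates,
    preprocess,
    rr_from_peaks,
    template_outlier_fraction,
)
from neuroorganoleptics.sensor_transfer import ChannelCalibration, ecg_to_volts
from neuroorganoleptics.synthetic_session import simulate_rr, synthesize_ecg

LF_TRUE, HF_TRUE = 800.0, 400.0
acq, cal = AcquisitionConfig(), ChannelCalibration()

rr_true, beats = simulate_rr(150, 70, LF_TRUE, HF_TRUE, seed=5)
stream, _ = synthesize_ecg(beat_times=beats + 0.5, config=acq, duration=151, noise_mv=0.01)

filtered = preprocess(ecg_to_volts(stream, cal), acq.sampling_rate)
peaks = detect_rpeaks(filtered, acq.sampling_rate)
labelled = template_outlier_fraction(extract_templates(filtered, peaks, acq.sampling_rate))
rr = rr_from_peaks(peaks, acq.sampling_rate)
feats = band_powers(rr)

print(f"beats: {len(beats)} true, {len(peaks)} detected")
print(f"outlier templates: {labelled.outlier_fraction:.1%} -> "
      f"{accept_recording(labelled.outlier_fraction)} (rule: eliminate above 5%)")
print(f"LF {feats.lf_power:6.1f} ms^2 (configured {LF_TRUE:.0f})")
print(f"HF {feats.hf_power:6.1f} ms^2 (configured {HF_TRUE:.0f})")
print(f"LF/HF {feats.lf_hf_ratio:.2f} (configured {LF_TRUE / HF_TRUE:.1f}), "
      f"normalised LF {feats.lf_norm:.2f}")
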