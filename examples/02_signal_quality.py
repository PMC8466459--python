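"""Pre-validate a recording and watch an injected artifact get caught.

A clean synthetic ECG passes the three-cluster screen; after a 12-s
electrode-detachment flatline is injected, the affected segments lose
their mid-cluster membership and the session verdict flips to
repeat_required (only ECG problems are session-fatal).
"""

import numpy as np

from neuroorganoleptics.core import AcquisitionConfig
from neuroorganoleptics.signal_quality import assess_recording
from neuroorganoleptics.synthetic_session import inject_artifact, simulate_rr, synthesize_ecg

acq = AcquisitionConfig()
rr, beats = simulate_rr(120, 70, 400, 300, seed=1)
ecg, _ = synthesize_ecg(beat_times=beats, config=acq, duration=120, noise_mv=0.01, seed=2)

clean = assess_recording({"ECG": ecg}, fs=acq.sampling_rate)
print("clean session verdict:", clean.verdict)

bad, record = inject_artifact(ecg, (40.0, 52.0), "flatline", acq.sampling_rate)
report = assess_recording({"ECG": bad}, fs=acq.sampling_rate)
print(f"after {record.kind} over [{record.start:.0f}, {record.end:.0f}] s:", report.verdict)
flagged = report.table[report.table["flag"] != "ok"]
print(flagged[["channel", "start_s", "mean_fs", "std_fs", "p50", "flag"]].to_string(index=False))
# p50 is the probability of belonging to the 50%-of-full-scale cluster;
# ECG segments need p50 >= 0.70 to count as usable.
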