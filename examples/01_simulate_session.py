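"""Simulate one tasting session and look at its ground truth.

Builds the staged protocol timeline (baseline, visual stimuli, tastings,
question phases), synthesises the four 10-bit/1 kHz channels, and prints
what the generator knows: beat count, per-product configured band powers.
"""

import numpy as np

from neuroorganoleptics.synthetic_session import CohortConfig, simulate_session

cfg = CohortConfig(coupling=0.8)
rng = np.random.default_rng(0)
session = simulate_session(cfg, "S001", 1, {"bar": 8, "cheese": 7, "cookie": 6, "milk": 2}, rng)

print("timeline:")
for e in session.timeline:
    label = f" {e.product}" if e.product else ""
    print(f"  {e.onset:7.1f} s  {e.kind}{label} ({e.duration:.0f} s)")

ecg = session.streams["ECG"]
print(f"\nECG stream: {len(ecg)} samples, codes {ecg.min()}..{ecg.max()}")
print(f"ground-truth beats: {len(session.ground_truth.beat_times)}")
print("configured per-window band powers (ms^2):")
for p in session.timeline.products:
    lf = session.ground_truth.lf_power_true[p]
    hf = session.ground_truth.hf_power_true[p]
    print(f"  {p:7s} score={session.scores[p]}  LF={lf:7.1f}  HF={hf:7.1f}")
# With coupling on, the low-scored product (milk) gets the largest powers:
# low acceptance is simulated as a stronger sympathetic-leaning response.
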