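# neuroorganoleptics

Sensory (organoleptic) testing of food and beverages augmented with
psychophysiological sensing: a tested, reusable pipeline from raw
multi-channel acquisition streams and self-report questionnaires to
heart-rate-variability features and the statistics that link physiology
to self-reported acceptance.

**Who it is for.** Consumer-behaviour and sensory-science researchers who
run tasting protocols with biosignal acquisition (ECG, electrodermal
activity, respiration, photoplethysmography from a 10-bit/1 kHz
Bluetooth unit) and want the analysis chain — sensor-unit conversion,
signal-quality screening, ECG processing, acceptance/preference
statistics — as an importable, reproducible library rather than ad hoc
scripts. Because such studies' raw data are typically private, the
package ships a synthetic-session generator with known ground truth, so
every stage is testable without any download.

## What it computes

ADC codes are converted to physical units through the hardware transfer
functions, e.g. ECG(V) = (ADC/2ⁿ − ½)·VCC/G with n = 10, VCC = 3.3 V,
G = 570, and EDA(µS) = (ADC/2ⁿ)·VCC/0.132 (0–25 µS range).

Each session is screened segment by segment: the mean and SD of the
codes (as fractions of full scale) give Gaussian membership
probabilities over three clusters centred at 20 %, 50 % and 90 % of full
scale; an ECG segment whose mid-cluster membership drops below 0.70 is
unusable, and only ECG problems force a session repeat.

The ECG chain applies a zero-phase Butterworth band-pass (order 3,
0.5–40 Hz) and 50 Hz notch, detects R peaks with a Hamilton-style
adaptive-threshold detector, screens heartbeat templates with DBSCAN
(recordings with > 5 % density-noise templates are eliminated), builds
the RR series, and integrates Welch spectral density over the standard
short-term bands to get the HRV features

  LF = ∫₀.₀₄⁰·¹⁵ S(f) df,  HF = ∫₀.₁₅⁰·⁴⁰ S(f) df  (ms²),

with normalised forms LF/(LF+HF), HF/(LF+HF), over each *product-contact
window* — the 2.5 min from tasting onset (1 min tasting + 1.5 min
question answering).

The statistics layer mirrors affective sensory practice: 9-point hedonic
summaries, NPS categorisation (promoter 9–10 / passive 7–8 / detractor
0–6), preference rank sums with Friedman and critical-difference tests,
Kendall tau-b repeatability across sessions, pairwise Wilcoxon
signed-rank matrices at α = 0.01, and the opposed-pair sign fraction:
over within-subject pairs of products whose acceptance scores differ by
≥ 5 points, the proportion with higher LF (or HF) for the low-acceptance
product.

## Worked example

Recover prescribed HRV band powers from a raw synthetic recording
(`examples/03_hrv_features.py`):

```sh
$ python examples/03_hrv_features.py
beats: 176 true, 176 detected
outlier templates: 0.0% -> retained (rule: eliminate above 5%)
LF  873.8 ms^2 (configured 800)
HF  495.8 ms^2 (configured 400)
LF/HF 1.76 (configured 2.0), normalised LF 0.64
```

The generator prescribed LF = 800 ms² and LF/HF = 2.0 for a 2.5-min
window; the full chain (transfer function → filters → R peaks → RR
series → Welch band powers) recovers every beat and estimates the ratio
within the expected short-window error. The other examples cover session
simulation, quality screening, the questionnaire statistics and the full
on-disk pipeline; `examples/05_full_pipeline.py` shows a session being
excluded by the quality screen with the logged decision line.

A thin CLI wraps the same functions:

```sh
norg simulate --out data/ --subjects 2 --coupling 0.8 --seed 1
norg validate data/recordings/S001_ses1.csv        # exit 3 = repeat required
norg hrv data/recordings/S001_ses1.csv data/timelines/S001_ses1.csv --out features.csv
norg analyze --dataset data/ --out results/
```

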