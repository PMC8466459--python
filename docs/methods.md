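# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, in the order data flows through the pipeline.

## Acquisition model and transfer functions

Recordings are multi-channel streams of integer ADC codes sampled by a
10-bit, 1 kHz acquisition unit operating at VCC = 3.3 V, with channel roles
ECG, EDA, PZT (respiration belt) and PPG. The channel transfer functions
are applied exactly as published for this hardware:

| channel | transfer | units | notes |
|---|---|---|---|
| ECG | (ADC/2^n − 1/2)·VCC/G | V | G = 570 (study hardware); 1100 is the datasheet default giving the nominal ±1.5 mV range |
| PZT | (ADC/2^n − 1/2)·100 | % displacement | mid-scale = 0 % |
| EDA | (ADC/2^n)·VCC/0.132 | µS | linear through zero; ceiling 25 µS at VCC = 3.3 V |
| PPG | min-max to [0, 1] | — | no published transfer; constant streams map to 0.5 |

All three published equations normalise by 2^n, not 2^n − 1, and the
package keeps that convention: integer codes live in [0, 2^n − 1], so the
positive range ends one quantisation step below the nominal ceiling (the
25 µS EDA ceiling is attained only at the nominal code 2^n, exposed as
`ChannelCalibration.eda_full_scale`). Conversion functions validate code
range by default; `validate=False` computes the analytic value for
out-of-range codes.

## Synthetic sessions

Real sessions of this protocol involve human participants and cannot be
shipped, so the simulator generates them with known ground truth. What it
emulates, and how:

**RR series.** Spectral synthesis: a modulation signal is the sum of two
groups of cosines, one spanning the LF band (0.04–0.15 Hz), one the HF
band (0.15–0.40 Hz), with deterministic amplitudes scaled so each group's
variance equals the configured band power in ms² and only the phases
random. Component frequencies stay 5 % of the bandwidth inside the band
edges (finite-length leakage stays in-band) and, when the target duration
is known, are snapped to the Fourier grid k/T so the components are
orthogonal over the realisation — the realised band variance then matches
the configured power tightly rather than fluctuating with phase
interference. Beat times follow by walking the modulated instantaneous RR
(integral-pulse-frequency-modulation style): t_{i+1} = t_i + RR(t_i).
Instantaneous RR is clipped to [300, 2000] ms, matching the plausibility
rule applied downstream.

**ECG waveform.** A stylised P-QRS-T template train: five Gaussian bumps
(P, Q, R, S, T) with fixed relative amplitudes and offsets, R centred
exactly at each ground-truth beat time, scaled by an R amplitude in mV
(default 1.0 mV) and converted to codes by inverting the ECG transfer
function. Samples clipped at the rails are counted as saturation
warnings. A dynamical-system ECG model was deliberately not used: the
template train is sufficient for testing R-peak detection and HRV
estimation, and its ground truth is exact by construction.

**Auxiliary channels.** EDA: tonic drift (base 4 µS, slope 0.01 µS/s)
plus event-locked skin-conductance-response bumps (fast rise ~0.75 s,
recovery ~2 s, amplitude 0.6 µS) at tasting onsets. PZT: quasi-sinusoid
at a breathing rate drawn in 0.2–0.4 Hz. PPG: one Gaussian pulse per
heartbeat delayed 250 ms after the R peak. These channels are acquired
and stored but not analysed downstream, mirroring the study's scope.

**Artifacts.** Three episode classes, the ones observed in practice:
`flatline` (electrode detachment — the channel falls to a constant,
defaulting to the low rail), `saturation` (rail code), and `spike_burst`
(~3 additive motion transients per second, ±30–50 % of full scale).
Samples outside the injected interval are untouched.

**Protocol timeline.** One session = 60 s relaxation baseline,
randomised-order 10 s visual stimuli (one per product), then per product
in random order a 60 s tasting followed by a 120 s question phase, with
5 s gaps. The question-phase default of 120 s guarantees the 2.5-min
contact window (60 s tasting + 90 s of answering) always fits; the real
protocol publishes only total session times, so the inter-event gaps are
declared defaults, not inferred ones.

**Scores.** Global acceptance is a rounded, clipped draw around each
product's mean on the 9-point hedonic scale (cohort defaults: four
products with means 7.0/7.5/6.5/5.0, SD 1.5 — a clearly liked, a
moderately liked and a polarising product). The 0–10 recommendation
(NPS) response is derived from the same latent liking rescaled to 0–10
with unit noise, so the two scales agree in direction. No distributional
form is published for such scores; the rounded-Gaussian choice is the
simplest that produces realistic heaping and ceiling effects.

**Score→physiology coupling.** Optionally (default off), per-window band
powers are drawn as base_power · exp(γ·(5 − score)/4) · lognormal jitter
(σ = 0.4). Positive γ encodes "low acceptance ⇒ higher LF/HF", the
direction suggested by the study's data; γ ≈ 0.5 gives a moderate effect
(a 9-vs-4 opposed pair differs by ×1.9 in expected power, partially
masked by jitter and estimation noise). With γ = 0 the features are
independent of the scores, which is the null used for type-I checks.

What the generator does **not** emulate: realistic ECG morphology
variation (axis, ectopy classes), respiratory sinus arrhythmia coupling
between the PZT and RR series, EDA/PPG artifacts, non-stationary heart
rate drift, and any dependence between subjects. Passing tests therefore
show that the pipeline recovers what this model encodes — band powers,
beat times, injected artifacts, score-feature coupling direction — not
that it is robust to every failure mode of real recordings.

## Signal-quality pre-validation

Each channel is cut into non-overlapping 10 s segments (a trailing
segment of at least 1 s is kept; the segment length is a declared
default, not a published one). For each segment the screen extracts the
mean m and standard deviation s of the codes as fractions of full scale
and converts them into membership probabilities over three clusters
centred at 20 %, 50 % and 90 % of full scale — where healthy channels
and railed/detached channels sit. "Probability of belonging" is given no
definition in the source protocol; here it is the Gaussian likelihood of
m at each centre with shared scale max(s, 0.02 FS), renormalised over the
three clusters. This uses exactly the two extracted statistics, is
symmetric (a mean equidistant from two centres splits membership
equally), and the 0.02 floor keeps zero-variance segments from producing
degenerate likelihoods.

Decision rules: an ECG segment with mid-cluster membership strictly below
0.70 is `noisy`; a zero-variance segment at a rail code is `lost`
(complete signal loss). The session verdict is `repeat_required` iff any
ECG segment is noisy or lost — abnormal behaviour on other channels is
recorded but never exclusionary. Thresholds for the non-ECG channels are
left configurable rather than invented.

## ECG chain and HRV features

1. **Filtering.** Butterworth band-pass, order 3, 0.5–40 Hz, plus a
   50 Hz IIR notch (Q = 30) for residual powerline interference, both
   applied forward-backward so R-peak timing is unshifted; then
   z-normalisation of the waveform. The minimum accepted sampling rate is
   2× the upper band edge.
2. **R-peak detection.** Hamilton-style: rectified first difference,
   80 ms moving-average integration, candidate peaks with a 200 ms
   refractory, adaptive signal/noise running levels (threshold at
   noise + 0.3125·(signal − noise), EWMA updates with weight 0.125),
   refinement to the largest absolute waveform deflection within
   ±100 ms, refractory re-enforced on refined positions. Detections
   within 0.3 s of the signal ends are discarded: zero-phase filtering
   leaves edge transients there and a boundary beat has no complete
   waveform.
3. **Template outliers.** Beat-centred windows of −200/+400 ms,
   amplitude-normalised (unit max-absolute) so the grouping reflects
   morphology rather than beat-to-beat gain, clustered with DBSCAN
   (Euclidean). Density noise is the outlier cluster. Default
   min_samples = 5; default eps = 2× the median pairwise distance, with a
   1e−6 floor so sets of identical templates (distance 0) still cluster.
   The factor 2 places typical beats well inside each other's
   neighbourhoods — within-class distances concentrate around the
   median, so an eps at the median itself strands a tail of normal beats
   as noise — while distinct morphologies sit many times the median
   away. Recordings with an outlier fraction strictly above 5 % are
   eliminated.
4. **RR series and band powers.** RR intervals in ms from successive
   peak times; intervals outside [300, 2000] ms are dropped and counted.
   The series is cubic-interpolated to a uniform 4 Hz tachogram (linear
   interpolation would low-pass the HF band, which sits near the
   beat-rate Nyquist), linearly detrended, and its spectral density
   estimated by Welch's averaged periodogram (Hann, 256-sample segments
   = 64 s, 50 % overlap). LF and HF are the integrals of the density
   over 0.04–0.15 Hz and 0.15–0.40 Hz — the standard short-term bands;
   the source names the features but not the edges. Normalised features
   are LF/(LF+HF) and HF/(LF+HF). A minimum RR span of 120 s is
   enforced; at the default resolution the lowest LF components are
   represented by only a few Welch bins, which is the main source of the
   remaining ratio-estimation error.
5. **Contact windows.** Per product, the half-open 150 s window starting
   at tasting onset (1 min tasting + 1.5 min question answering).
   Windows the recording does not fully cover raise a truncation error
   and are excluded.

## Acceptance and preference statistics

* **NPS**: promoter 9–10, passively satisfied 7–8, detractor 0–6 — an
  exact partition of the 0–10 scale.
* **Opposed pairs**: within subject × session, product pairs whose
  global-acceptance scores differ by ≥ 5 points, oriented high/low. The
  sign fraction of a feature is the proportion of pairs with a strictly
  positive low-minus-high difference; ties count as non-positive.
* **Wilcoxon matrix**: for each unordered product pair a paired
  signed-rank test over the subject × session observations present for
  both products (the design is within-subject; an unpaired rank-sum
  fallback is available). Identical paired samples are reported as
  p = 1. Cells with fewer than 5 observations are undefined.
  Significance uses a raw α = 0.01 with no multiplicity correction,
  matching the source analysis; Holm correction is available behind a
  flag.
* **Kendall repeatability**: tau-b with tie correction between paired
  per-subject scores of two sessions; exact two-sided p for small
  tie-free samples, normal approximation otherwise. The `correlated`
  verdict threshold is p ≤ 0.05.
* **Preference rankings**: per-item rank sums, the Friedman statistic
  (sign test for k = 2), and pairwise significance via the
  normal-approximation critical difference z₀.₉₇₅·√(n·k·(k+1)/6).
  Incomplete ranking rows are dropped and counted.

## Pipeline orchestration

`run_pipeline` fixes the stage order — quality validation, outlier
elimination, HRV features, statistics — and logs one machine-parseable
`DECISION` line per exclusion with the rule that fired and its value.
All randomness in the simulator flows from a single seed; reruns with
equal configs produce byte-identical CSV outputs (the chain contains no
hidden randomness — DBSCAN, filtering and Welch are deterministic).

## Problem sizes and verification

The test suite and the acceptance script run everything at desk scale:
R-peak sensitivity over five 62 s recordings (~355 beats), LF/HF ratio
recovery over twenty 2.5-min windows spanning ratios 0.5–4, artifact
detection over fifty 120 s sessions, type-I control over one hundred
replicates of a 4-product × 15-subject null cohort, and a full on-disk
pipeline run over a 4-subject coupled cohort. Statistical p-values are
verified against exhaustive enumeration oracles (all 2^n sign
assignments for the signed-rank test, all n! orderings for Kendall) at
n ≤ 8, and the generator's spectra against a direct-DFT periodogram
independent of the Welch path.

## Known limitations

* The quality screen's Gaussian-membership model is one reasonable
  reading of an underdefined procedure; the printed "−0.065 mV at 50 %
  of full scale" in the source does not follow from the ECG transfer
  function (mid-scale is 0 V) and is not reproduced.
* The LF/HF estimator is biased low for ratios at the extremes of the
  tested range on 2.5-min windows (few LF-band Welch bins); 5-min series
  roughly halve the error.
* The simulator's ectopic-free ECG means the 5 % elimination rule is
  exercised through injected morphology outliers, not physiological
  ectopy.
* Time-domain and nonlinear HRV, and any analysis of the EDA/PZT/PPG
  channels, are out of scope by design.
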