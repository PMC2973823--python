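# Methods

This note documents the models, parameter choices and numerical
conventions behind `rgcdecode`, and what the synthetic benchmark does and
does not establish.

## Synthetic stimulus and population

The stimulus generator reproduces the flash protocol: 66 ms full-field
flashes, colour red/green with probability ½ each, irradiance uniform on
0.07–0.7 µW/cm², inter-flash gaps i.i.d. uniform on 1.1–2.1 s (the jitter
avoids phase-locking the simulated retina). The default experiment uses
500 flashes (~13 min of recording) — enough for half/half
cross-validation of all decoders at desk scale.

Each cell is an inhomogeneous Poisson process

    r(t) = max(0, baseline − suppression(t)
               + Σ_flashes gain(colour, I) · k(t − onset − latency(colour, I)))

with `k(u) = (u/τ²) e^{−u/τ}` a unit-area causal alpha kernel (width τ
~12–25 ms), so `gain` is the expected number of evoked spikes per flash.
Spikes are generated by Poisson thinning on a 1 ms grid; all randomness
flows from a single `SeedSequence`, making recordings reproducible
bit-for-bit. Intensity couples affinely in log-irradiance (centred on the
geometric midpoint of the intensity range): higher intensity raises gain
and shortens latency, with a stronger latency slope for red — the
asymmetry that creates intensity-dependent colour confusability.

`suppression(t)` silences a fraction of an OFF cell's baseline between
flash onset and its response latency. This reflects standard OFF-cell
physiology (the light increment hyperpolarises the cell until the
offset-driven rebound) and is essential for the first-spike-latency code:
without it, ~50% of trials would have an uninformative baseline spike
before the response.

Cell classes (largest-remainder apportionment, so a 100-cell population
has exactly 5/35/5/55 cells):

| class | fraction | gain (green), spikes | latency (green), ms | red−green shift | suppression |
|---|---|---|---|---|---|
| tuned | 0.05 | 6–9 | 115–145 | +60–80 ms, red gain ×0.6–0.85 | 0.9 |
| weak | 0.35 | 0.4–1.2 | 80–110 | +10–30 ms | 0.5 (OFF half) |
| green_only | 0.05 | 0.8–2.0 | 80–110 | red gain = 0 | 0 |
| untuned | 0.55 | 1–3 (both colours) | 90–120 (both) | none | 0.5 (OFF half) |

Baselines are 6–10 Hz (2–6 Hz for green_only). Tuned-class latencies were
placed so that green first spikes fall below and red first spikes above a
~170 ms boundary, matching the observed first-spike separation in
well-tuned cells; only the ~70 ms shift itself, not the absolute
latencies, is externally constrained. The untuned majority responds to
flashes but identically for both colours: it carries onset information
while sitting at chance for colour, which is exactly the population
structure the "what from single cells, when from the population" division
of labour requires.

**What passing tests show — and don't.** The generator produces Poisson
spiking with the described latency/gain structure under full-field
stimulation. It has no receptive-field geometry, no eye movements, no
adaptation or inter-cell correlations, and its class boundaries are
sharper than a real continuum of cell tunings. Decoder results on it
demonstrate correctness and internal consistency of the readouts under
the stated response statistics, not performance on any particular retina.

## Response representation

Spike counts in 25 ms boxcar windows at 50% overlap (12.5 ms stride, kept
exact). Windows are half-open `[a, a+25)`: a spike on the right edge
belongs to the next window, and an interior spike is counted by exactly
two windows. The binary stimulus indicator marks a window 1 if it overlaps
the flash interval at all (partial overlap counts), so an interior 66 ms
flash marks 7–8 consecutive windows.

## Colour ("what") readout

LN fit: ridge-stabilised normal equations (λ = 1e−6 on the Gram matrix —
immaterial for well-posed fits, a documented fallback with warning for
singular designs). The threshold search is exact: candidates are midpoints
of consecutive sorted training estimates; among error-count ties the
centre-most optimal candidate is taken (the margin midpoint when classes
separate), which is why θ lands near 1.5 for balanced 1/2 coding. Ties at
ŝ = θ classify green. Decoders are fitted on the chronological first half
of trials and scored on the second.

First-spike readout: latencies within 375 ms of (estimated) onset, 10 ms
histogram bins, maximum likelihood over the per-colour conditionals.
Trials with no spike in the window are classified by a configurable
fallback (default red, the weaker-response class) rather than dropped, so
accuracy denominators equal trial counts. On tuned cells the first-spike
readout runs a few percentage points below the LN readout here — the
residual (10%) unsuppressed baseline still contaminates some first spikes;
the two readouts carry similar, not identical, information.

## Onset ("when") readout

The multi-cell LN estimator is anticausal: the decision at window t uses
counts from t to t+T (T = 250 ms default, 125 ms in the two-stage
readout), and the reported onset is the window-start time of the first
threshold crossing. The joint least squares over all cells' lags is solved
by chunked normal equations (the full lagged design matrix is never
materialised; ~100 cells × 20 lags fits in a 2001² Gram matrix). The
threshold is optimised at the event level: over ~200 quantile candidates
of the training-half estimator output, pick the θ minimising (missed
flashes + spurious detections) after matching, ties toward the largest θ.
One event per supra-threshold excursion (rising-edge lockout).

Matching is greedy nearest-neighbour within ±125 ms, each detection and
each flash used at most once, which guarantees |timing error| ≤ 125 ms for
matched pairs. FN is normalised by true events, FP by detections. RMS and
bias (mean red error − mean green error) are computed over matched pairs
only; an empty match set is flagged, not reported as zero error.

At the default scale (100 cells, 500 flashes) the detector reaches FN = FP
≈ 0–1%, RMS ≈ 20 ms and |bias| ≈ 1–3 ms on the held-out half. Naive
rate-code detectors (total or LS-weighted 250 ms counts) detect but with
clearly higher error; the per-cell weighting pays off exactly when the
population mixes a few informative with many uninformative cells.

## Two-stage causal readout

Stage one detects onsets with 125 ms filters; stage two classifies colour
with time zero at (estimated onset + 125 ms), so no spike is used twice
and the chain is causal. Missed flashes are excluded from the accuracy
ratio and reported separately. Colour weights are learnt either at exact
training onsets shifted by the filter length ("parallel") or at the
detector's own estimated onsets on the training half ("serial"). In these
clean simulations the two are statistically indistinguishable: serial
learning absorbs the detector's small systematic earliness and has ample
data, offsetting its extra alignment noise. The "exact onset" reference
arm uses the same causal shift with true onsets, so forcing perfect
detection makes the two arms identical by construction.

## ISI classifier

Every ISI is keyed by its second spike and assigned to a flash colour if
that spike falls within 216 ms (150 + 66) of a flash onset, else to black.
Bins are 25 ms over 0–1000 ms (out-of-range ISIs clamp to the edge bin
with a warning); tie-breaks are fixed black > green > red. ML ignores the
prior and therefore false-alarms on a black screen at rate
baseline × confusable-fraction — 6 Hz with half the ISIs confusable gives
one false alarm per 1000/(6 × 0.5) ≈ 333 ms; MAP with the empirical
rare-flash prior answers black almost everywhere. Robustness to the
assignment window holds once the window contains the evoked response
(red latencies reach ~200 ms here, so windows below ~220 ms truncate the
red response and shift rates materially).

## STA polarity

Gaussian full-field flicker at 33 ms frames (mean 0.35, σ 0.1 — declared
defaults; the probe's frame rate and contrast are otherwise
unconstrained). The STA is the mean stimulus trajectory in the 500 ms
before each spike; polarity is the sign of the largest deflection from the
*empirical* channel means, declared only beyond 3 standard errors with an
overlap-corrected effective sample size (spikes sharing a stimulus frame
are not independent samples). Simulated OFF cells classify OFF without
error; pure-noise trains occasionally exceed 3 SE at the peak (a max over
~30 bins), which is the known cost of the simple peak criterion.

## Geometry

Pinhole projection: image = target × eye-diameter / distance (0.60 mm for
4.5 cm at 30 cm through a 4 mm eye). Photoreceptor count divides the image
disc by the receptor footprint — square packing (d²) by default, giving
~7,854 for 6 µm receptors, versus ~10,000 for circular packing; square
packing is the inference consistent with the "about 7,000" figure.
Ganglion-cell counts: density × π r² with r either the image radius
(~1,272 at 4,500 mm⁻²) or grown by one receptive-field radius
(~2,262), bracketing the 1,000–2,000 estimate. All are exact closed forms,
cross-checked in tests against 1 µm pixel-counting integration.

## Problem sizes

Defaults were chosen as the smallest sizes at which the estimates are
stable: 500 flashes for decoder fits, 100 cells for population detection,
300 flashes / 60 cells for most unit tests, 50 random subgroups per point
in population-size sweeps. The full test suite runs in well under a
minute of compute plus a few minutes for the acceptance-scale runs.
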