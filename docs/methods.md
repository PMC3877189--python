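# Methods

This note documents the models and numerical choices behind each stage of
the pipeline, the defaults and why they were chosen, and what the
synthetic-data checks do and do not establish.

## Calibration and units

All intensities are on an SPL-like dB scale:
`10·log10(mean-square amplitude) + calibration_offset_db`. No absolute
calibration constant can be recovered from an arbitrary WAV file, so the
offset is a per-signal attribute, default 100 dB — a full-scale RMS signal
maps to 100 dB and the generator's reference snore (RMS 0.01) to 60 dB,
placing synthetic nights on the 20–80 dB range typical of calibrated
bedside recording chains. Linear frame energies are floored at −100 dB
(pre-offset) so silence never produces −∞.

## Enhancement

Spectral subtraction runs on 40 ms Hann frames at 50% overlap with
overlap-add reconstruction (input padded by one frame so every sample has
full window coverage; phase preserved). The per-bin amplitude gain is the
Wiener form `G = ξ/(1+ξ)` with the a-priori SNR ξ estimated by the
decision-directed rule (feedback weight 0.96) from a posterior SNR that is

* smoothed across frequency (9-bin moving average), because single-bin
  periodogram values of stationary noise are exponentially distributed and
  a raw per-bin rule lets a few random bins per frame leak through as
  "musical noise" spikes — which the histogram-based event detector then
  mistakes for events; and
* over-subtracted (noise power × 4), pushing ordinary background
  fluctuations below the gain floor.

The gain is clamped to [−25 dB, 0 dB]: the filter only attenuates, never
by more than 25 dB, bounding distortion on low-SNR events. The noise
template is initialised from the minimum-energy 40 ms frame of the first
10 s and tracked by exponential smoothing (weight 0.98 on the old
estimate, in the power domain — magnitude-domain averaging underestimates
noise power) on frames whose energy falls below the 20th percentile of the
trailing 10 s. Before any output is produced the template is warmed up
over that first window; the single-frame initial estimate has large
per-bin variance and converging it on-line would leave the first seconds
under-suppressed.

Contracts: every applied gain lies in [−25 dB, 0 dB] (exact, instrumented);
per processed frame the output spectrum is bounded by the input spectrum
(exact pre-overlap-add; re-analyzed bins can show a few percent
cross-frame leakage where adjacent frames carry different gains).

## Event detection and segmentation

Frame energies use 60 ms frames at 75% overlap (frame rate Fr = 66.67/s).
The night is split into 60 s sections (a final partial section joins the
previous one if shorter than 10 s). Per section, the dB energies are
histogrammed at 1 dB bins; the mode `e_max` sits at the background level
and the threshold `e_th` is the first bin above the mode whose count falls
to one tenth of the mode count (fallback `e_max + 6 dB` for degenerate
histograms). Thresholds are smoothed across sections with an order-5
running median (shrinking window at the edges).

Maximal runs of frames strictly above threshold are candidates. Each edge
is then refined outward: a least-squares line is fitted to the 10 energy
frames just outside the boundary and the boundary moves outward while the
fitted slope keeps its initial sign, with two guards — a 0.6 dB/frame
deadband on the sign test (75%-overlap energy frames are autocorrelated,
so on flat background a raw sign test random-walks several frames into
noise) and a 2 s travel limit. Refinement can only extend events, never
shrink them, and never crosses a neighbouring event.

Adjacent events separated by less than 200 ms are merge candidates: the
cosine similarity between the *mean-removed log*-magnitude spectra of the
earlier event's last 100 ms and the later event's first 100 ms must reach
0.7 (identical split snores score above ~0.78 even with frame-quantized
windows; unrelated event kinds stay below ~0.65 and background pairs below
~0.45). Mean removal matters — raw magnitude spectra of any two windows over
the same broadband background are nearly collinear, so a raw-spectrum
similarity cannot distinguish two halves of one split snore from two
unrelated noise blips.

Only events lasting 0.2–3.5 s (inclusive) are kept; longer-term snore
statistics show essentially all snore events inside this range, and the
test removes clicks and long disturbances cheaply.

Reported boundary times compensate the deterministic smear of the chain:
the onset is the first frame's start plus (frame − hop) = 45 ms (a frame
fires once the event enters the tail of its 60 ms window), and the offset
is the end of the last frame's hop cell minus a 60 ms release — the
suppression gains stay open for about one enhancement frame past an
event's end and leak background into the energy track. With these
conventions the synthetic-night boundary error is a few ms ± ~25 ms.

Event intensity is the dB of the mean linear frame energy over the event;
event SNR subtracts the background estimated from non-event frames within
5 s on each side.

## Feature pool (127 slots)

Categories and counts: periodicity Ta×10, duration Tb×4, energy Tc×11,
spectral parameterization Sa×68, bio-characteristic frequencies Sb×10,
spectral dynamics Sc×24. `feature_manifest()` documents every slot.
Slots that cannot be computed (unvoiced pitch, variance moments of a
single-frame event, flat autocorrelation) are flagged NaN and median-
imputed from the training data at classification time.

**Periodicity.** The dB energy context around the event (12 s on each
side, truncated at recording edges) is passed through a logistic transform
centred midway between its 10th and 90th percentiles with slope scale
(p90−p10)/8, floored at 1 dB. Snoring occupies a minority of the time, so
centring between the background and event levels (not at the median, which
sits inside the background mode) renders the signal nearly binary and
emphasizes rhythm over intensity. The autocorrelation of the mean-removed
transform is normalized to R(0)=1, smoothed with a 5-point moving average,
and the first peak with prominence ≥ 0.1 and height ≥ 0.05 in the 1–10 s
lag range gives the rhythm period τ_p. The chord `aτ+1` joins R(0) to
R(τ_p); `Area` is the mean squared deviation of R from that chord over
[0, τ_p], and the rhythm intensity is `R_I = R(τ_p)·Area`. Left and right
contexts are analysed separately (the event aligned at the context edge)
plus the combined two-sided context; together with `E_P` these fill the 10
Ta slots. `E_P` is the ratio of the summed *linear* frame energies of the
10 s before the event to the event's own energy — linear, because a ratio
of dB sums is dimensionally meaningless and linear sums make E_P read as
"number of similar prior events"; a truncated prior window at the
recording start is scaled up proportionally.

**Duration.** Total duration; 95% energy duration (between the 2.5% and
97.5% points of the cumulative sample-energy); their ratio; and the
energy-weighted standard deviation of time within the event (normalized).

**Energy.** Mean and peak intensity, SNR, and scale-free envelope shape:
normalized rise/fall time, energy centroid, weighted skewness/kurtosis,
crest factor, modulation depth, fill factor. All shape slots are invariant
to global gain.

**Spectral parameterization.** Per 40 ms frame at 50% overlap: LPC
coefficients (order 12, Levinson–Durbin), MFCCs c1–c13 (26 triangular mel
filters to 8 kHz, orthonormal DCT-II; c0 omitted so the set is gain
invariant), and 8 equal-width sub-band energy fractions. Aggregation to 68
slots: means of LPC/MFCC/sub-bands, standard deviations of MFCC/sub-bands,
four moments (mean/var/skew/kurtosis) of spectral centroid, bandwidth and
85% rolloff, and mean/std of spectral flatness.

**Bio-characteristic frequencies.** First three formants by the LPC root
method on pre-emphasized frames (roots with bandwidth < 500 Hz, median
over frames) plus the first formant bandwidth; pitch by the normalized
autocorrelation method on 80 ms frames searching 30–400 Hz (low floor to
cover low snore fundamentals; voiced when the peak exceeds 0.5), with
voiced fraction, pitch stability (std/mean), jitter, harmonicity, and a
voiced-present flag.

**Spectral dynamics.** Snore spectra are more stationary than most other
bedroom noises (once the background is subtracted), so these 24 slots
quantify change across frames: flux statistics of the unit-normalized
magnitude spectra, frame-to-frame spectral correlation statistics,
centroid/bandwidth/rolloff velocities, and per-sub-band trajectory
variances.

## Classification

Discrete AdaBoost over exhaustively-searched decision stumps: per round,
the (feature, threshold, polarity) minimizing the weighted error, with
cumulative-sum search over presorted features; ties break to the lower
feature index, then lower threshold. Learner weights
`α = ½·ln((1−ε)/ε)`; a round with no stump under 0.5 error stops training.
The decision score is the α-normalized vote in [−1, 1]. Default orders:
k = 300 for the final model, k = 100 inside forward feature selection,
which greedily adds the feature maximizing 10-fold cross-validated
accuracy (folds grouped by recording to prevent within-subject leakage)
and returns the subset at the criterion-curve maximum (default budget 34).
Training is deterministic given the input order; imputation medians, seed
and k are stored in the JSON model file (schema-versioned).

Note that boosted stumps cannot represent symmetric XOR structure (every
axis-aligned cut is at chance); the test suite checks parity with
scikit-learn's stump AdaBoost on that worst case rather than solvability.

The per-recording decision threshold S_TH assumes a bimodal score
histogram (snores toward +1, noises toward −1): 50 bins over [−1, 1],
order-5 moving-average smoothing, minimum search restricted to ±0.25
around zero, accepted only if both neighbouring bins exceed the minimum by
5% relative prominence — otherwise S_TH = 0 (also for recordings with
fewer than 30 events). Events are labeled snore iff S > S_TH (strict).

## Synthetic nights

The generator is the package's study-condition definition, not a
convenience fixture. A snore surrogate is a pulse train at the block's
pitch (default 90 Hz, ~1% period jitter — quasi-periodic but strongly
autocorrelated at one period lag, as voiced biological sound is) mixed
with turbulent noise at ~30% of the pulse RMS, filtered through 2–3
resonators (defaults 450/1200/2200 Hz, 150–250 Hz bandwidths), shaped by a
50 ms rise / 80 ms fall envelope, and scaled to the programmed intensity.
Non-snore events: clicks (< 100 ms broadband transients, removed by the
duration test), coughs (0.3–0.8 s bursts whose dominant resonance sweeps
from ~3 kHz to ~500 Hz — non-stationary spectrum, falling tilt), and
speech-like voiced streams with wandering formant pairs. Backgrounds are
pink (1/f power above a 20 Hz corner — recording chains high-pass the
infrasound region, and without the corner the sub-Hz bins dominate frame
energies unphysically) or white, default 35 dB. Snore blocks follow a
breathing-period schedule with Gaussian jitter (defaults: 4 s ± 0.3 s,
durations 0.6–1.4 s, intensities 55–65 dB spanning the 25–75 dB range
across configurations); non-overlap is enforced and infeasible schedules
raise. Everything is bitwise-deterministic under a fixed seed.

The design corpus used for acceptance (10 simulated subjects × 50 snores
+ 50 coughs/speech-like events, intensities 45–70 dB, per-subject period,
pitch and resonances) and the held-out night (100 snores / 100 noises at
≥ 15 dB SNR) are deliberately *easier* than clinical data: stationary
background, no bed-partner sounds, no posture changes, surrogate snores
from a single synthesis family. Passing the end-to-end checks (accuracy ≥
95% on the held-out night) demonstrates that the chain recovers planted
structure at realistic SNRs and event statistics — it does not certify
clinical-grade accuracy on real recordings, where event variety and
non-stationary noise dominate the difficulty.

## Problem sizes and determinism

The acceptance checks use 10-minute nights (10 for segmentation recovery,
2 noise-only), 180 events across breathing periods {2, 4, 6} s, a 6-point
jitter grid, and the 500/500-event corpus with a 200-event held-out night;
formula oracles run on ≥ 1000 randomized small instances each. All
randomness flows from explicit seeds (`numpy.random.default_rng`); the
pipeline itself contains no randomness, so identical inputs give
bitwise-identical events, scores, model files and reports.

## Known limitations

* Only relative calibration is possible; absolute SPL requires a
  calibrated chain.
* Breathing-phase attribution (inspiration vs expiration) needs
  respiratory effort signals and is out of scope.
* The per-recording threshold needs tens of events to locate a valley;
  sparse nights fall back to S_TH = 0.
* Full forward selection over 127 features at k = 100 is expensive
  (hours); the default end-to-end path trains on the full pool at k = 300,
  which the boosting margin tolerates well on the synthetic corpus.
* Real-data effects deliberately not emulated: room reverberation,
  bed-partner snoring, HVAC cycling, posture-dependent intensity drift.
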