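# Methods

This note documents the model behind `turtlehr`, the tunable parameters and
their defaults, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the protocol leaves room.

## The analysis model

The quantity of interest is the phase-conditioned heart rate of a
free-moving sea turtle wearing an ECG logger (250 Hz) and a longitudinal
accelerometer (16 or 50 Hz). Heart rate is treated as an event rate: for a
phase of duration *T* minutes containing *N* detected R waves, HR = *N*/*T*
beats min⁻¹. Per-status grand means are unweighted means over phase rates,
reported mean ± sample s.d. with the number of phases *n*.

The chain is strictly ordered and deterministic:

1. **Band-pass filter.** Zero-phase (forward–backward) Butterworth, default
   band 5–30 Hz, order 2 per pass (≈ 24 dB/octave effective). Zero phase
   matters because rates are computed from event counts in fixed windows;
   a phase-shifting filter would move events across phase boundaries. The
   band keeps the QRS energy of a slow reptilian heart (beat template
   energy peaks near 15 Hz at the default morphology) while rejecting
   baseline wander (≲ 0.1 Hz, attenuated > 95 %) and the upper part of EMG
   energy.
2. **R-wave detection.** Local maxima above a rolling adaptive threshold,
   accepted greedily in descending amplitude under a refractory constraint.
   The threshold in each 60-s block is `threshold_scale` (default 0.45)
   times the 0.999 quantile of |signal| in that block: the near-max
   quantile tracks the local R-peak amplitude even when it drifts, and the
   scale factor places the bar in the gap between the noise ceiling and the
   peaks. The refractory period (default 1 s) caps the detectable rate at
   60 beats min⁻¹, several-fold above any reported sea-turtle rate, so it
   suppresses filter ringing and double-counting without ever masking real
   beats. Events are reported at the local-maximum sample.
3. **Quality grading.** Non-overlapping 60-s windows aligned to the record
   start (trailing partial window discarded). A window is *detectable* when
   it contains ≥ 1 detected R wave whose amplitude exceeds `snr_floor`
   (default 5) times the window RMS and whose implied local rate (60 / gap
   to the nearest neighbouring detection) lies in `rr_bounds_bpm` (default
   1–60). The detectable fraction maps to the grade: < 0.30 *undetectable*,
   0.30–0.70 inclusive *unclear*, > 0.70 *clear*. The cut points follow the
   protocol's wording strictly — the boundary fractions 0.30 and 0.70 are
   both *unclear*. The SNR-plus-plausible-rate rule is this package's
   operationalization of a criterion that is human visual judgment in field
   practice; the floor of 5 sits between the peak-to-RMS ratio of pure
   band-limited noise (≈ 4 for a 60-s window) and that of a visible beat
   train over the default noise floor (≳ 7).
4. **Activity classification.** Sample s.d. of longitudinal acceleration
   over each complete minute, minute grid aligned to the deployment clock.
   SD < 0.5 m s⁻² ⇒ *resting*, otherwise *moving* — the boundary value
   itself is moving, reading the "lower than … otherwise" rule strictly.
   Maximal same-status runs of ≥ 2 min become phases; shorter runs are
   unclassified and excluded from both statuses rather than merged into a
   neighbour, and a long run is one phase, never stacked minimum-length
   phases.
5. **Handling exclusion.** Events strictly before the cutoff (default 12 h
   from the deployment clock origin) are dropped; an event exactly at the
   cutoff is retained. Phases are kept only if they start at or after the
   cutoff — a straddling phase is dropped whole, because truncation could
   manufacture a sub-minimum phase.
6. **Counting convention.** A phase counts events in the half-open interval
   [start, end): an event exactly on a boundary belongs to the later
   interval, so consecutive phases partition the timeline without double
   counting.

### Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `band_low_hz`, `band_high_hz` | 5, 30 | Hz | QRS energy above wander, below EMG peak |
| `filter_order` | 2 | — | 24 dB/octave after the double pass |
| `refractory_s` | 1.0 | s | caps rate at 60 bpm, far above turtle HR |
| `threshold_quantile` | 0.999 | — | near-max: tracks local peak amplitude |
| `threshold_scale` | 0.45 | — | drops the bar below peaks, above noise |
| `quality_window_s` | 60 | s | one window per analysis minute |
| `snr_floor` | 5 | — | separates beat peaks from noise maxima |
| `rr_bounds_bpm` | 1–60 | bpm | physiological plausibility band |
| `behavior_threshold_ms2` | 0.5 | m s⁻² | resting/moving cut on minute SD |
| `min_phase_minutes` | 2 | min | minimum run defining a phase |
| `handling_exclusion_h` | 12 | h | post-handling disturbance window |

Every default is config-exposed (`RunConfig`), and the resolved
configuration is embedded in every saved result, so nothing is applied
silently.

Grand means default to pooling all phases of a deployment (and of several
deployments, when combined) as equal observations; a `per_individual`
pooling mode first averages within each animal and then across animals,
because multi-animal summaries can reasonably be read either way.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
ground truth recorded for every run:

* **Behavior**: a two-state alternating-renewal process over whole minutes
  with geometric dwell times (defaults: resting mean 20 min, moving mean
  10 min, so two-thirds of time is resting). Geometric dwells are the
  minimal-assumption choice and naturally produce runs both shorter and
  longer than the 2-min phase rule, exercising the segmentation logic.
* **Cardiac events**: RR intervals drawn from a normal distribution around
  60/HR(status) seconds with coefficient of variation `rr_cv` (default
  0.1), truncated below at the beat-template width; the status of the
  minute containing an interval's start sets its rate (an unambiguous,
  testable transition rule). Defaults are the published per-state rates,
  8.6 resting and 12.2 moving beats min⁻¹. The beat-level CV is a scaffold
  value — field data report only phase-level means ± s.d., not beat-level
  variability.
* **Beat morphology**: each R wave is a Mexican-hat (biphasic) template of
  total width 0.12 s and peak amplitude 0.05 relative units, evaluated at
  exact sample-time offsets. Only the R deflection matters to the pipeline;
  no P/T waves are modelled. The small amplitude mirrors the ~10× attenuation
  of plastron-surface recordings.
* **Noise**: white sensor noise (SD 0.004), slow sinusoidal baseline wander
  (amplitude 0.02 at 0.1 Hz), and EMG bursts — band-limited 20–60 Hz noise
  (SD 0.01 within bursts) with Poisson onsets (3 min⁻¹, 2 s long) occurring
  *only inside moving minutes* and clipped at minute boundaries. These
  defaults represent a usable surface recording: beats clearly above the
  noise floor at rest, intermittent motion artifact while swimming.
* **Acceleration**: moving minutes carry a 0.4 Hz stroke sinusoid of
  amplitude 1.0 m s⁻² over sensor noise (SD 0.1); resting minutes are noise
  only. A full-minute sinusoid of amplitude A has SD A/√2, so moving-minute
  SDs sit near 0.71 m s⁻² and resting ones near 0.1 — on the correct sides
  of the 0.5 m s⁻² threshold by construction at the defaults.
* **Environmental channels**: constant-ish 1 Hz temperature (23.4 °C) and a
  shallow depth channel ride along untouched, as in real deployments.

All generators are deterministic under a fixed seed (independent child
streams per component, so changing one noise term never perturbs the event
train), and regeneration is byte-identical through the text I/O layer.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic PQRST morphology and
amplitude/electrode drift, temperature dependence of heart rate, dive
behavior and depth-correlated artifact, seawater-intrusion noise epochs,
inter-individual variability in signal quality, and any within-phase
autocorrelation structure beyond the renewal assumptions. Results on
synthetic deployments validate the *pipeline logic and its conventions*,
not field performance.

## Numerical choices and degenerate inputs

* Channel values are float64 end to end; files print full-precision `repr`
  so write→read is bit-for-bit identity. Loaders reject non-finite samples:
  the pipeline has no gap-handling rule, so missing data fail loudly.
* Minute SDs use the sample (ddof = 1) estimator; with 960–3000 samples per
  minute the distinction is cosmetic, but it matches the "sample s.d."
  reporting convention used for the grand means.
* An all-zero ECG yields an empty event train (not an error); an empty
  train yields detectable fraction 0 and grade *undetectable*; a record
  shorter than one quality window or than the filter warm-up raises a
  too-short error rather than returning a misleading grade.
* A record lying wholly inside the handling-exclusion window produces an
  empty (warned) summary; per-status s.d. is reported as NaN when fewer
  than two phases contribute.
* Percentages in placement tables round half-up to one decimal, matching
  hand-rounded published tables; each placement's denominator is the number
  of animals evaluated *at that placement*, which is how the published
  percentages reconcile.
* Ties in the detector's greedy acceptance are broken by candidate order
  (stable sort), i.e. the earlier of two equal peaks wins.

## Problem sizes

The test suite and the acceptance script validate the full chain on a 48-h
synthetic deployment (43.2 M ECG samples) for rate recovery, 10-min records
per rate point for detection F1, a 30-min fixed-seed deployment ladder for
noise monotonicity, and 10,000 random status sequences against a
brute-force segmentation oracle; unit tests use seconds-to-minutes scale
fixtures. These sizes make the stochastic checks tight (the 48-h record
yields ≈ 25,000 beats and ≈ 130 phases, putting the s.e. of recovered grand
means well under 1 %).

## Known limitations

* The detector assumes upright (positive) R deflections, as produced by the
  generator; inverted real-world leads would need a sign flip upstream.
* The quality grade is an automated proxy for a visual criterion; its SNR
  floor and rate bounds are calibrated against the synthetic noise model,
  not against human graders.
* Minute-grid alignment to the deployment clock is a convention; analyses
  using a different grid may disagree at phase boundaries.
* Heart rates are not temperature-corrected, and depth is carried but not
  analyzed.
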