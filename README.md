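# turtlehr

Non-invasive heart-rate analysis for sea-turtle biologging deployments.

Green sea turtles (*Chelonia mydas*) have dense keratinous scutes that make
carapace-surface electrocardiography hard: R waves recorded from electrodes
on the plastron are roughly one-tenth the amplitude of conventional
recordings, and muscle-contraction artifacts contaminate the signal whenever
the animal swims. `turtlehr` implements the analysis chain used to turn such
recordings — ECG at 250 Hz, longitudinal acceleration at 16 or 50 Hz,
temperature and depth at 1 Hz — into phase-conditioned heart-rate estimates:

1. **ECG processing** — zero-phase Butterworth band-pass filtering, adaptive
   R-wave detection with a refractory period suited to slow ectotherm hearts
   (5–20 beats min⁻¹), and a three-level signal-quality grade
   (*undetectable* < 30 % of windows detectable, *unclear* 30–70 %, *clear*
   > 70 %).
2. **Behavior classification** — per-minute standard deviation of
   longitudinal acceleration; minutes with SD < 0.5 m s⁻² are *resting*,
   otherwise *moving*; maximal same-status runs of ≥ 2 min become phases.
3. **Heart-rate statistics** — after excluding the first 12 h post-handling,
   each phase's heart rate is the R-wave count divided by the phase duration
   (beats min⁻¹), and per-status grand means are reported as mean ± s.d.
   over phases: HR_phase = N_R / T_phase, with the grand mean
   (1/n) Σ HR_phase per status.
4. **Placement evaluation** — aggregation of per-animal grades at the three
   plastron electrode placements (A: humeral, B: gular, C: intergular scute)
   into a count/percentage table, plus the unclear-at-A → clear-at-C
   improvement fraction.
5. **Synthetic deployments** — an alternating-renewal behavior process,
   a state-dependent cardiac event train rendered as low-amplitude beat
   templates, motion-conditional EMG noise, and stroke-like acceleration,
   all with recorded ground truth so the full chain is testable without
   real animals.

The package is organised statsmodels-style: `HeartRateModel` wraps one
deployment plus a `RunConfig`, and `fit()` returns a `HeartRateResults`
carrying the estimates, diagnostics and resolved configuration.

## Worked example

```python
import turtlehr as t

model = t.HeartRateModel.from_simulation(
    behavior=t.BehaviorModel(duration_min=360),   # 6-hour deployment
    seed=7,
    config=t.RunConfig(handling_exclusion_h=0),   # short record: keep it all
)
results = model.fit()
print(results.summary())
```

prints

```
turtlehr 0.1.0 — phase-conditioned heart-rate analysis
turtle 'SIM001', electrode placement C, ECG 250 Hz / accel 16 Hz, record 6.0 h

signal quality : clear (100.0% of 360 windows detectable)
R waves        : 3638 detected, 3638 after 0-h exclusion
phases         : 18 segmented, 18 analyzable

status      mean bpm      sd      n
resting          8.6     0.1     10
moving          12.3     0.1      8
```

The generator was configured with resting/moving rates of 8.6 and
12.2 beats min⁻¹; the pipeline's grand means (8.6 and 12.3 over 10 resting
and 8 moving phases) recover them, and the *clear* grade says R waves were
detectable in effectively every one-minute quality window. The same analysis
runs on real data via a deployment manifest:
`t.run_pipeline("deployment/manifest.yaml", t.RunConfig())`.

From a shell, the same flow is:

```sh
turtlehr simulate --out dep --seed 7 --duration-min 360
turtlehr process dep --exclude-hours 0 --out results_dir
turtlehr summarize evaluations.tsv --total 29
```

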