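# antiphony

Tools for quantifying **antiphonal calling** — precisely timed vocal
turn-taking — between paired individuals, built around the kind of
continuous per-bird recordings produced by backpack microphones on zebra
finch pairs.

Pair-bonded birds answer each other's short contact calls ("stack" calls)
within half a second. How symmetric that exchange is, how it develops as a
pair forms, and how it relates to affiliative behaviour (physical contact,
"clumping") are quantitative questions about two coupled point processes.
This package implements the full measurement chain:

- **Call detection and typing** (`antiphony.audio`): amplitude-envelope
  segmentation of continuous audio; ten spectro-temporal parameters per call
  (duration, mean/mode/first-peak frequency with their frame SDs,
  zero-crossing rate, amplitude peaks); Gaussian-mixture sorting into call
  types with an editable label file; removal of faint partner-leak
  detections; song counting from syllable totals.
- **Exchange statistics** (`antiphony.exchange`): the cross-correlogram of
  partner call onsets around each focal (female) call, ±2 s in 100 bins;
  answer/answered counts within 0.5 s; the **directionality index**

  ```
  D = (N_answers − N_answered) / (N_answers + N_answered)
  ```

  (0 = symmetric exchange, positive when the male answers more); Poisson
  confidence limits from the 2–4 s baseline flanks; antiphony detection and
  call-overlap rate.
- **Behaviour integration** (`antiphony.behavior`): affine video→audio clock
  alignment through matched anchor events, clumping time budgets, and call
  rates within each relative-position state.
- **Inference** (`antiphony.stats`): linear mixed models fitted by ML with
  10 000-draw posterior simulation under flat priors, 95% credible
  intervals, derived p for group contrasts, z-scoring, Lessells–Boag
  repeatability, and marginal/conditional r².
- **Synthetic ground truth** (`antiphony.simulate`, `antiphony.fixtures`):
  coupled Poisson calling with configurable answer probabilities and
  sub-second Gamma latencies, behaviour-state tracks, and simple rendered
  audio — every stage is testable against known truth.

## Worked example

Simulate one hour of a strongly asymmetric pair (the male answers 40% of
female calls, the female 10% of male calls) and measure the stack-call
exchange:

```python
from antiphony import (SimConfig, simulate_pair_calling, cross_correlogram,
                       detect_antiphony, summarize_exchange)

cfg = SimConfig(duration_s=3600, p_answer_f=0.1, p_answer_m=0.4, seed=7)
s = simulate_pair_calling(cfg)
f = s.female_events[s.female_events.call_type == "Stack"]
m = s.male_events[s.male_events.call_type == "Stack"]
summ = summarize_exchange(f.onset_s.to_numpy(), m.onset_s.to_numpy(),
                          f.duration_s.to_numpy(), m.duration_s.to_numpy())
det = detect_antiphony(cross_correlogram(f.onset_s.to_numpy(),
                                         m.onset_s.to_numpy()), alpha=0.01)
```

This prints:

```
female stacks: 562   male stacks: 694
answers: 186   answered: 89
directionality: +0.3527  (display +35.27)
male answer share: 0.268
overlap rate: 0.071
antiphonal: True   peak latency: 0.18 s
baseline lambda/bin: 4.41   upper limit: 11
```

The male answered 186 female stacks but was answered only 89 times, so the
index is strongly positive (+35.3 on the ×100 reporting scale). The
correlogram peak at 0.18 s — far above the Poisson upper limit of 11
counts/bin expected from the baseline rate — flags genuine antiphony, with
the low overlap rate (7%) typical of alternating exchange.

## Command line

```bash
antiphony simulate --preset new_pair_convergence --seed 1 --out data/
antiphony exchange --data data/ --out results/
antiphony stats    --data data/ --out results/
antiphony all      --config run.yaml      # stages + manifest from YAML
antiphony segment  recording.wav --out calls.csv --cluster-k 6
```

`simulate` presets encode the study's qualitative scenarios: newly
introduced pairs that start asymmetric and converge (`new_pair_convergence`),
established pairs symmetric throughout (`established_pair`), and an
uncoupled null (`uncoupled_null`).

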