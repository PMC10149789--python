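# aptemporal

Simulation and analysis toolkit for studying the relationship between
**absolute pitch** (AP) and **auditory temporal processing**.

Absolute pitch is the rare ability to name a musical tone without any
reference. One candidate explanation links it to unusually precise temporal
coding in the auditory system. This package implements, end to end, a study
design that probes that link in two experiments:

- **Experiment 1 — sine tones and gap detection.** Participants name 13 sine
  tones (F#3–F#4), 4 presentations each = 52 trials. Temporal acuity is
  measured with a gaps-in-noise task: 6-second white-noise segments containing
  0–3 silent gaps of 2–20 ms, 60 gaps per ear. Scores are the gap detection
  percentage (GDP) and the gap detection threshold (GDT): the shortest gap
  duration detected at least 4 of 6 times with performance maintained at all
  longer durations.
- **Experiment 2 — piano tones and backward masking.** Participants name 36
  piano tones (C3–B5), 2 presentations each = 72 trials, ordered so that
  consecutive tones are always more than an octave apart. Temporal resolution
  under masking is measured with a backward-masking task: a 25 ms tone
  followed by a 200 ms masker at inter-stimulus intervals of 0–400 ms, 48 tone
  trials plus 12 catch trials per ear, yielding a masking percentage (BMTP)
  and threshold (BMTT).

Pitch naming is scored by **chroma recognition rate** (CRR, % of trials with
the exact chroma named) and **mean absolute deviation** (MAD, the mean
circular chroma distance in semitones, 0–6). A participant is classified AP
when CRR exceeds a binomial chance cutoff (for 52 trials over 12 chromas at
99% confidence: 10 correct = 19.2%) *and* MAD < 1.00 semitones.

The package provides:

| Module | Contents |
| --- | --- |
| `aptemporal.protocols` | Constrained-randomized stimulus protocols (pitch tests, GIN tracks, BMT sessions) |
| `aptemporal.scoring` | CRR/MAD scoring, detection tallies, maintained-performance thresholds, ear averaging, censoring |
| `aptemporal.classification` | Binomial chance model and AP/Non-AP assignment rules |
| `aptemporal.observers` | Generative observer models (wrapped-Gaussian pitch naming, psychometric detection) and cohort simulation |
| `aptemporal.stats` | Student *t*, Hedges *g*, Pearson *r*, Benjamini–Hochberg, BCa bootstrap CIs and CI-inversion *p*-values, bisquare robust regression, Cohen's *f*² |
| `aptemporal.pipeline` | Full inference pipelines for both experiments |
| `aptemporal.cli` | `aptemporal` command-line interface |

## Worked example

Simulate a single observer on the 52-trial sine-tone test, score it, and
classify:

```python
from aptemporal import (
    PitchObserverParams, assign_group, build_pitch_id_protocol, chance_cutoff,
    score_pitch_id, simulate_pitch_observer,
)

protocol = build_pitch_id_protocol("exp1_sine52", seed=42)
observer = PitchObserverParams(sigma=0.4, guess_rate=0.05)
log = simulate_pitch_observer(observer, protocol, seed=7)
scores = score_pitch_id(log)
model = chance_cutoff(n_trials=52, n_alternatives=12, confidence=0.99)
label = assign_group(scores, training_crr=82.0, model=model)

print(f"CRR = {scores.crr:.2f}%   MAD = {scores.mad:.3f} semitones")
print(f"chance cutoff: {model.cutoff_count}/52 trials = {model.cutoff_percent:.1f}%")
print(f"assigned group: {label.value}")
```

Output:

```
CRR = 76.92%   MAD = 0.404 semitones
chance cutoff: 10/52 trials = 19.2%
assigned group: AP
```

Simulate a whole Experiment-1 cohort (9 AP + 10 Non-AP) and run the full
analysis from the command line:

```sh
aptemporal simulate --experiment 1 --seed 3 --out cohort.csv
aptemporal analyze --experiment 1 --in cohort.csv --out report.json --seed 5 --bootstrap-b 2000
```

Reading two headline results from `report.json`:

```python
import json
r = json.load(open("report.json"))
gt = r["group_tests"]["gdt"]
print(f"GDT group test: t({gt['df']}) = {gt['t']:.3f}, g = {gt['g']:.3f}, BH-adjusted p = {gt['p_bh']:.4f}")
c = r["correlations"]["gdt_crr"]
print(f"AP-group GDT~CRR: r = {c['r']:.3f}, 95% BCa CI [{c['ci_bca'][0]:.3f}, {c['ci_bca'][1]:.3f}]")
```

```
GDT group test: t(17) = 0.862, g = 0.378, BH-adjusted p = 0.3881
AP-group GDT~CRR: r = -0.686, 95% BCa CI [-0.983, 0.095]
```

Everything is deterministic under the seeds you pass: re-running either
command reproduces the artifacts byte for byte.

## Reproduction

Run the test suite (includes the acceptance criteria in
`tests/test_acceptance.py`):

```sh
python -m pytest -q tests/
```

Run the headline computation — both default cohorts through their complete
inference pipelines — and write all main quantities as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness in the script derives from `--seed`; identical seeds give
byte-identical output files.

## Documentation

See [`docs/methods.md`](docs/methods.md) for the statistical model, the
generative observer model and its default parameters, numerical choices, and
known limitations.
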