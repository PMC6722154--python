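# egopoint

Analysis and simulation toolkit for **mobile-device egocentric pointing
tests** of spatial orientation and memory.

Spatial disorientation is an early marker of pathological cognitive
decline, but bedside-compatible tests for it are scarce.  One practical
design has the patient stand at a fixed spot in a room and point a phone
at 15 named targets under four conditions of increasing difficulty:

| condition | task | spatial process |
|-----------|------|-----------------|
| EO | eyes open, point at visible targets | sensorimotor baseline |
| EC | eyes closed, same targets | spatial memory |
| RR | after a real 90° body rotation, eyes closed | spatial updating |
| MR | after an *imagined* 90° rotation | perspective taking |

The phone records each trial as a unit vector **v** = (e, n, u) in
East/North/Up coordinates.  `egopoint` provides everything around that
measurement: the session JSON data model, vector→angle conversion,
circular statistics (circular mean, resultant length R, circular SD
√(−2 ln R), Rayleigh test, von Mises and 2-component von Mises mixture
fits), psychometric reliability (McGraw–Wong ICCs ≡ Cronbach's α,
test–retest), baseline-referenced error scoring with rotation-frame
handling, repeated-measures condition tests with permutation inference,
questionnaire correlations, and a fully seeded synthetic-cohort generator
for validating the whole pipeline.

## Model in brief

Azimuth α = atan2(e, n) − facing heading (positive = right), elevation
ε = asin(u).  Each participant's pooled eyes-open trials give per-target
baseline directions (circular mean azimuth, mean elevation); every trial
is scored as a signed circular azimuth error, a signed elevation error
and a great-circle total error against the expected direction.  For MR
the expected azimuth is shifted ∓90° for the imagined rotation (an
unshifted baseline-scoring mode is available; in it, flips show up as the
characteristic bimodal ±90/180° error modes that the mixture model
detects).  Per-target circular SDs carry a √(n/(n−1)) small-sample
correction.  See `docs/methods.md` for the full account.

## Worked example

```python
from egopoint import SimConfig, simulate_cohort, PointingStudy

config = SimConfig(n_participants=6, seed=42)   # two-day protocol, 480 trials each
sessions, truth = simulate_cohort(config)
results = PointingStudy(sessions).fit(n_perm=999, seed=0)
print(results.summary())
```

prints

```
Egocentric pointing study results
=================================================
Participants: 6   Trials: 2880   MR transform: True

Condition summaries (vs. EO baseline)
-------------------------------------------------
cond   |az err|    az SD  |el err|    el SD     n
EC        12.54    16.63      4.57     5.76   540
EO         7.84    10.75      2.80     3.52  1260
MR        39.54    52.99      7.38     9.38   537
RR        15.73    22.07      5.89     7.40   540

rm-ANOVA condition effect: F(3, 15) = 163.47, p = 0.0000 (permutation p = 0.0010, 999 resamples)

Reliability
-------------------------------------------------
internal_azimuth        alpha   0.9290 CI [0.8034, 0.9884]
internal_elevation      alpha   0.9882 CI [0.9675, 0.9981]
test_retest_azimuth     ICC_C1  0.9940 CI [0.9908, 0.9961]
```

Reading the numbers: azimuth errors and SDs grow monotonically with task
difficulty (EO < EC < RR < MR — the generator's difficulty multipliers,
recovered by the analysis), elevation is roughly twice as precise as
azimuth in the baseline (3.5° vs 10.8° SD here; the EO azimuth SD pools
the eccentric contralateral targets whose variability is inflated), MR is
dominated by occasional 90/180° flip errors, and the eyes-open baseline
is highly reliable across targets and days.  `results.errors`,
`results.target_summaries` and `results.correlations` hold the underlying
tables; `results.save_report(outdir)` writes the CSV/JSON/figure bundle.

The same pipeline runs from the shell:

```sh
egopoint simulate --seed 7 --out cohort/
egopoint analyze 'cohort/P*_day*.json' --out report/ --mr-transform on
egopoint validate cohort/P001_day1.json
```

Session files follow the JSON dialect documented in
`src/egopoint/schemas/session.schema.json` (flat trial list, ENU unit
vectors, forward-tolerant of unknown keys such as GPS fields or
timestamps).

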