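# facsboot

Stratified, individual-level bootstrap analysis of frame-coded facial
behaviour, built around a guilt-induction study design: participants'
faces are coded frame-by-frame with the Facial Action Coding System
(FACS), and the question is whether particular Action Units (AUs) — single
facial muscle movements such as AU4 (Brow Lowerer), plus self-directed
behaviours like neck touching — occur more often in one set of video
frames than chance would allow.

Who this is for: researchers in affective science / behavioural ethology
who have event-coded AU data (onset/offset intervals per AU per video) and
want a reproducible, tested implementation of the frequency-contrast
pipeline, plus a synthetic-data generator to validate it end to end
without any raw video.

## The statistic

For each AU *a*, the **pooled frame frequency** of a group of individuals
is the proportion of visible video frames (pooled across the group, so
longer videos weigh more) on which *a* is active. The test scores the
observed test-group frequency against a null distribution built by
resampling **individuals** of the control group with replacement —
individuals, not frames, because AU activations persist in bouts and
frames are strongly autocorrelated. Each resample is stratified so that it
reproduces the test group's place-of-origin (PoO) composition, apportioned
by largest remainder. Over B resamples this yields, per AU:

- *expected frequency*: the mean of the B bootstrap frequencies,
- *z*: (observed − mean) / sd (sample sd),
- *p*: `min(#{boot ≥ obs}, #{boot ≤ obs}) / B`, ties counted as extreme —
  so p = 0.01 with positive z means exactly that in 990 of 1000 resamples
  the AU occurred less frequently than in the test data.

The same engine drives four condition contrasts (guilt vs control,
weak/strong guilt subsets vs control, strong vs weak) and the judgement
stage, where judges' time "pinpoints" become one-second frame windows
(centre frame `floor((t + 0.5)·fps)`, half-width `floor(0.5·fps)` frames)
and pinpointed frames are contrasted against the remaining frames of the
same videos. Parametric stages (PANAS manipulation checks, the
judged-guilt linear model with likelihood-ratio deletion tests and VIFs,
the self-report/judgement Pearson correlation) sit on top.

A synthetic generator produces whole studies with the structure the method
assumes: two-state Markov (bout) AU streams with per-individual
logit-scale expressivity offsets and condition-specific odds effects, very
different video durations per condition, judge pinpoints that concentrate
where guilt-marker AUs are active, and 0–100 slider ratings linear in AU4
/ neck-touch frame ratios.

## Worked example

```python
import facsboot as fb

ds = fb.generate_study(fb.GeneratorConfig(), seed=1)   # 66 guilt + 65 control
g, c = ds.by_condition("guilt"), ds.by_condition("control")
table = fb.contrast_conditions(
    ds.frames_for(g), ds.frames_for(c), g, c, ds.ontology,
    fb.BootstrapConfig(B=1000, alpha=0.01, seed=5),
)
print(table[table.significant][["au", "observed_freq", "expected_freq", "z", "p"]])
```

prints

```
           au  observed_freq  expected_freq          z      p
2         AU4       0.199859       0.094124  11.295784  0.000
4         AU7       0.337661       0.299397   2.682644  0.002
13       AU52       0.312884       0.225437   6.013260  0.000
20       AU62       0.229087       0.148353   6.782047  0.000
23  NeckTouch       0.021582       0.000000        inf  0.000
```

i.e. the AUs the generator elevates in the guilt condition (AU4, AU52,
AU62, NeckTouch) come out with positive z and empirical p below 0.01;
`observed_freq` is the guilt group's pooled frame frequency and
`expected_freq` the mean over 1000 stratified control resamples. The
NeckTouch row shows the signed-infinity z sentinel: every control resample
had frequency 0 (the bootstrap sd is zero), while the guilt group touched
the neck on 2% of frames — the empirical p still comes from the tail
counts. (AU20's small planted effect is not always detected at this n, and
AU7 here is a false positive — see docs/methods.md on the method's
attained level.)

The same run from a shell:

```sh
facsboot simulate --seed 1 --out study/
facsboot select --events study/events.csv --participants study/participants.csv --out aus.csv
facsboot contrast --events study/events.csv --participants study/participants.csv \
    --aus aus.csv --b 1000 --seed 5 --out table1.csv
facsboot run --synthetic --seed 1 --out full_run/   # all stages at once
```

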