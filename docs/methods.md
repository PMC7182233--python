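# Methods

## Data model

Facial behaviour is represented at two levels. **Events** are coded
activation intervals: one row per AU per continuous activation, with
0-based frame indices and half-open `[onset, offset)` intervals, so
duration = offset − onset and abutting events concatenate without overlap.
Intensity (low/high) is stored but collapsed to presence for every
analysis. **Frame matrices** expand events into a frames × AUs 0/1 table
with a per-frame visibility mask; frames on which the whole face cannot be
seen are recorded as `NotVisible` pseudo-events and *removed* from every
frequency computation (dropping, not zero-filling, keeps denominators
honest). The frame rate is fixed per study (default 25 fps); mixed-rate
datasets are not supported.

The shipped ontology has 24 AU/AD codes (numbered facial AUs, head/eye
position descriptors, and two self-directed channels, FaceTouch and
NeckTouch). A 15-code alias list is also shipped for the judgement stage;
the two counts come from mutually inconsistent statements in the source
material and the 15-code membership is a best-effort reading (numbered
facial AUs + AU54 + the self-directed channels) — analyses default to the
24-code set.

## AU inclusion filter

An AU enters the analysis only if, in *each* condition, the number of
participants producing it at least once reaches the smallest k with exact
binomial tail P(X ≥ k | n, p0) ≤ α (defaults p0 = 0.5, one-sided α = 0.05,
n = that condition's participant count; sentinel n + 1 when unattainable).
Shame-linked codes (AU54, AU64) and the self-directed behaviours are
force-included on theory grounds. The historical criterion of "39
producers per condition" cannot be re-derived unambiguously (its n, chance
probability and sidedness are unstated), so `SelectionConfig.min_count`
accepts an explicit override and the binomial computation is the default.

## The bootstrap contrast

Unit of resampling: the **individual**, because frames within an
individual are heavily autocorrelated (bouts) and expressivity differs
between individuals; resampling frames would understate the null variance
by an order of magnitude. Each of B replicates draws m individuals from
the control group with replacement (m defaults to the control group size),
stratified by place of origin so that each replicate reproduces the test
group's stratum composition. Stratum draw counts use largest-remainder
apportionment with alphabetical tie-break; within a stratum, draws index
uniformly into the sorted id list, which makes results independent of
input iteration order. A drawn individual contributes its frames as many
times as it is drawn.

Per AU: observed = test-group pooled frequency; expected = mean of the B
bootstrap frequencies; z = (observed − mean)/sd with sample sd (ddof = 1);
p = `min(#{boot ≥ obs}, #{boot ≤ obs}) / B` with ties counted as extreme
(conservative at the boundary). If the bootstrap sd is exactly zero and
the observed value differs from the constant, z is reported as signed
infinity and p still comes from the tail counts. `p = 0` is stored as 0.0
and printed as `< 1/B` in human-readable reports. The
`two_sided_double` option doubles the minimum tail (the textbook two-sided
empirical p); the default is the one-direction rule, the convention under
which "p = 0.01 with positive z" means exactly 990 of 1000 resamples below
the observed value.

### Attained level

This design — build a null distribution from the control group only, then
score an *independent* test group against it — is intrinsically
anti-conservative, and the package documents rather than hides this:

1. The discrepancy observed − bootstrap-mean has variance
   ≈ σ²/n_test + σ²/n_control, while the bootstrap spread is ≈ σ²/n_control.
   With equal group sizes the empirical z is inflated by √2, giving
   ≈ 2·Φ(−2.326/√2) ≈ 10% rejections at a nominal α = 0.01 under the
   one-direction-p rule (which itself rejects in either direction,
   contributing a factor ~2 relative to a doubled p).
2. For very rare AUs (baseline frame probability ~10⁻³, e.g. NeckTouch)
   most control individuals carry zero active frames, the bootstrap
   distribution degenerates at 0, and any positive observed frequency
   lands in the extreme upper tail — visible as huge or infinite z values.

`facsboot.simulation.null_rejection_fraction` measures the attained level
by full simulation (both groups drawn from one identical generative
model); at the default settings it comes out near 0.10–0.15 rather than
0.01, driven by (1) everywhere and by (2) for low-baseline AUs. The
self-comparison case (test group ≡ control group) *is* calibrated, because
the observed statistic is then the centre of its own bootstrap
distribution. Consumers who need a level-α decision rule should treat the
per-AU flags as descriptive ranking evidence, or compare against a
two-group resampling scheme; the implementation keeps the original rule
because reproducing that rule is the point of the package.

## Pinpoint windows

Judges report whole seconds. A pinpoint at t seconds is centred on the
frame containing t + 0.5 s, i.e. `floor((t + 0.5)·fps)`, with a symmetric
error margin of `floor(0.5·fps)` frames (12 at 25 fps — floor of 12.5),
giving a 25-frame (one-second) window away from video edges. Windows are
clipped at boundaries rather than dropped (dropping would bias against
early/late pinpoints); pinpoints whose entire window falls past the video
end are dropped with a warning. Windows from all judges are unioned per
video; *unique instances* count distinct (video, second) pairs, the finest
resolution the judges can report. Frames carrying none of the retained
AUs are removed from both the pinpointed and the remainder partition (a
blank face cannot have been judged on facial grounds); zero-AU frames are
kept in the condition contrasts, where no such removal is defined. The
remainder set is everything not guilt-pinpointed; windows reported for
*other* emotions are not excluded from it. The pinpoint contrast then runs
the same bootstrap engine with videos as the resampled individuals,
separately for control-condition and guilt-condition videos.

## Parametric stages

- PANAS manipulation checks: two-sided paired t-tests per item/scale and
  condition (negative t = increase, the within-subject reporting
  convention), plus Welch two-sample tests of post-induction scores
  between conditions. An exactly constant nonzero shift reports signed
  infinite t with p = 0.0 (machine floor), never NaN.
- AU vs self-report: the association between an AU's per-participant frame
  proportion and a post-induction item score is an unstated model in the
  source; implemented as simple OLS of proportion on score, slope on the
  proportion-per-scale-unit scale.
- Judged guilt: described originally as a "linear mixed model" with *no*
  random effects — the response is one mean rating per video — so it is
  fitted as Gaussian OLS. Full model: four AU frame ratios (AU4, AU10,
  AU20, NeckTouch) + how many of the four appear + condition + PoO +
  self-reported guilt change; null model: the last three only. Full-vs-null
  and per-predictor single-term deletions are likelihood-ratio chi-square
  tests (matching drop1 semantics; F-tests would differ slightly at small
  n). Collinearity is summarised by variance inflation factors; continuous
  predictors are z-standardized (sample sd), which rescales coefficients
  but leaves every test invariant (asserted in the suite).

## Synthetic generator

What it emulates: the statistical structure the analysis is sensitive to.
Per participant i and AU a, the stationary frame probability is
`p_ia = logistic(logit(base_a) + u_i + 1[guilt]·log(effect_a))` with
u_i ~ N(0, σ_ind); frames follow a stationary two-state Markov chain with
off→on rate `p/(L(1−p))` and on→off rate `1/L` (stationary probability p,
mean on-run L frames), generated exactly as alternating geometric
sojourns. Configurations with off→on rate > 1 (p > L/(L+1)) are rejected;
individual-level tail values are clamped into the valid region. The lag-1
autocorrelation is `1 − 1/(L(1−p))`: strongly positive at L = 10, and at
L = 1 slightly *negative* (−p/(1−p)), vanishing for small p — the chain
collapses to i.i.d. sampling only in that limit.

Defaults are the study conditions: 66 guilt / 65 control participants;
truncated-normal durations (guilt mean 73.66 s, sd 46.56 s, min 10 s;
control 7.90 s, sd 4.27 s, min 2 s) at 25 fps; baseline probabilities from
the control-condition expected-frequency column of the reference contrast
table (NeckTouch, printed as 0.00 there, is set to 0.001, consistent with
the observed 0.02 being ~20× its expectation); guilt-condition odds
multipliers on AU4 (2.7), AU20 (1.5), AU52 (1.45), AU62 (1.5) and
NeckTouch (20); individual logit sd 0.3; bout length 10 frames; PoO strata
European:EastAsian = 2:1, labels only (an optional `poo_effect` logit
shift exists for stress tests). PANAS items use printed before/after
means/sds where available (e.g. guilt item 1.35 → 2.70 in the guilt
condition), with unprinted cells filled consistently with the reported
between-condition differences; before/after draws are correlated (ρ = 0.4)
and rounded into the 1–5 (items) or 10–50 (scale sums) range.

Judges: Poisson(7) pinpoints per guilt video (Poisson(3) per control
video — chosen to match 36 instances over 12 control videos) at integer
seconds, with per-second sampling weight `1 + scale·(#guilt-marker AUs
active in that second)` (scale default 1); 10% of guilt pinpoints receive
a co-label with another emotion. Slider ratings are normal around a video
mean linear in the AU4 and NeckTouch frame ratios (guilt-video means
≈ 35, control ≈ 20, matching the reported judgement level difference).

Randomness: one study seed, split into independent per-participant streams
via `SeedSequence(seed, spawn_key=(group, index))`, so enlarging one group
never perturbs previously generated participants; judge tables use
separate per-video streams.

What it does *not* emulate: anatomy-driven AU co-occurrence constraints,
any cap on simultaneously active AUs, judge reliability/response-time
dynamics, or visibility loss (generated frames are fully visible; the
visibility machinery is exercised with hand-built fixtures). Passing tests
therefore validate the pipeline's arithmetic and operating
characteristics under bout-structured, heterogeneous binary streams — not
the realism of any particular facial display.

## Numerical choices and problem sizes

- Empirical-p ties count as extreme; a constant bootstrap column is
  detected by exact max = min comparison (so mean-subtraction rounding
  cannot fake a tiny sd) and triggers the signed-infinity z sentinel.
- Largest-remainder quotas guard against float shortfall of exact quotas
  before distributing remainder seats; ties break alphabetically.
- The operating-characteristic experiments use 300 null datasets × B = 300
  (attained level; 60 + 60 individuals, 15 AUs, short-video durations for
  both groups so they are identically distributed) and 100 study-scale
  runs × B = 300 (power / null flag rates); these sizes give binomial
  Monte-Carlo standard errors of ~0.0015 on the attained level and ~0.03
  on per-AU flag rates.
- Pipeline runs derive every stage's RNG stream from the single recorded
  seed; two runs with identical config + seed produce byte-identical
  output trees (asserted in the suite).

## Known limitations

- The attained level of the contrast is well above nominal by design of
  the original procedure (see "Attained level"); the package reproduces,
  measures and documents this rather than correcting it.
- The producer-count criterion's historical value (39) is not recoverable;
  results depend on the override chosen.
- The judged-guilt model treats per-video mean ratings as independent
  observations; judge-level variance is not modelled.
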