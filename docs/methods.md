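# Methods

## The measurement problem

A C3-zone microzone is defined by the receptive field its climbing-fibre
input carries; the working hypothesis is that units sharing a receptive-field
class also share a task-related activity pattern.  Two quantitative pieces
are needed: per-unit modulation latencies relative to paw lift, and a
statistic linking the clustering of activity patterns to the class labels.
`microreach` implements both, together with a generator that reproduces the
study conditions closely enough for every stage to be exercised and for the
latency estimator to be validated by parameter recovery.

## Synthetic sessions

Trials are laid out at a fixed 10 s inter-trial interval.  Reaction time
(door open → paw lift) and reach duration (paw lift → tube entry) are drawn
from truncated normals (> 0): duration 320 ± 131 ms as reported; reaction
time 300 ± 80 ms, chosen so that a small fraction of trials falls under the
150 ms exclusion cut (the study excluded 12.5% of reaches overall; the
generator does not target that rate, only realistic tails).  The paw-down
hold is 500 ± 100 ms, which only matters for bumps anchored to that event.

Each unit fires as an inhomogeneous Poisson process, simulated by thinning a
homogeneous process at the rate ceiling.  The rate is

λ(t) = baseline + Σ bumps  A·exp(−(t − c)² / 2σ²),  σ = response_width/2,

with the primary bump anchored to paw lift and optional secondary bumps to
other events; λ is clipped at 0 so suppression never produces a negative
rate.  No refractory period is modelled — at 20–40 Hz baseline the Poisson
approximation is adequate for count statistics, though inter-spike-interval
structure is unrealistic.

The injected "onset" of a unit is the 2-SD leading edge of its primary bump
(c − 2σ).  Class presets use the reported values: baselines 32.4 / 22.6 /
37.6 / 31.6 / 33.9 / 36.7 Hz and onset statistics −110 ± 63, 0 ± 165,
−152 ± 83, 41 ± 159, −8 ± 180, 180 ± 164 ms for classes 1, 2, 6, 8, 9, 10.
Distal classes (1, 2, 6) carry a secondary 20 Hz bump at tube entry, giving
the multi-peak profiles typical of distal fields; proximal classes are
single-peaked.  Two parameters are not reported anywhere and were fixed
once: response amplitude 50 Hz (inside the observed spread of peak-minus-
baseline rates, and large enough that the ±2 SD crossing sits close to the
2-SD leading edge rather than far up the bump flank) and response width
100 ms (σ = 50 ms, a transient burst comparable to the ~320 ms reach).

Per-unit true onsets are drawn once per unit and held fixed across trials,
because the reported latency spread is between units, not between trials.
By default the draws are stratified: the n units of a class sit at the
midpoint quantiles of N(onset_mean, onset_sd), randomly assigned to units.
With 4–10 units per class, i.i.d. draws would make the class sample mean
wander by ±80 ms (SD 165/√4) — the generator's own sampling noise would then
exceed the ±40 ms recovery tolerance and recovery would be untestable.
Stratification reproduces the reported between-unit statistics at the
printed counts; `SessionConfig(stratified_onsets=False)` restores i.i.d.
draws.

What the generator does **not** emulate: kinematic trajectories, complex-
spike/simple-spike waveform structure, firing-rate drift and satiation
effects across a session, refractoriness and bursting, or correlated noise
between simultaneously recorded units.  Passing recovery tests therefore
demonstrates that the estimator is unbiased under Poisson variability at
realistic rates and trial counts — not that it is robust to every feature of
real recordings.

## Latency pipeline

Defaults: ±1000 ms window (the clustering vectors span 2 s around paw lift;
endpoints are a package choice with the baseline required inside), 10 ms
bins, Gaussian kernel of SD 10 ms truncated at ±3 SD with edge
renormalisation, baseline −1000..−500 ms, threshold ±2 SD.  Baseline mean
and SD are computed on the smoothed trace, so threshold and trace share
units; z over the baseline bins then has mean 0 and SD 1 identically.  Units
silent at rest (zero baseline SD) are flagged and excluded from z-based
analyses rather than divided by.

Onset is the left edge of the first significant bin at or after the baseline
end (−500 ms).  The literal single-bin crossing rule is available
(`min_run_bins=1`) but is not the default: per-bin |z| ≥ 2 occurs by chance
in ≈ 4.6% of bins, and over a 150-bin search window first-crossing latencies
are dominated by false positives (simulated bias of −400 ms for a class with
true onset +180 ms).  The default requires the crossing to be sustained for
7 consecutive bins (70 ms), which drops the false-alarm rate to a few
percent per profile while adding < 10 ms average onset bias at the default
amplitude; the per-class recovery tests bound the net effect within ±40 ms
(bin width + kernel support).  Peak latency is the bin of maximal |z| from
the onset onward (so onset ≤ peak by construction); a rate-extremum variant
sits behind `peak_on_rate`.

Trial exclusion uses the population SD (ddof = 0) of reach durations over
the trials passing the reaction-time rule, two-sided (|deviation| >
2.5 SD).  The fast/slow comparison takes the lower and upper duration
quartiles (⌊n/4⌋ trials from each end of a stable sort, so ties break by
trial order) and requires ≥ 60 kept trials, the study's criterion for that
sub-analysis.

Population PETHs per class are bin-wise means of member z-profiles,
re-standardised against their own baseline so the ±2 SD threshold keeps its
meaning at the population level (a mean of k unit-variance traces has
baseline SD ≈ 1/√k; without re-standardisation the threshold would be
k-dependent).  The mean-of-z convention is scale-invariant across units,
which is why it was preferred over summed counts.

## Cluster–class correspondence

The activity matrix stacks the z-profiles (rows are already standardised, so
PCA uses column mean-centering only, no rescaling).  Three components are
retained; if they explain < 80% of the variance a warning is emitted rather
than an error — synthetic sessions carry relatively more independent Poisson
noise per unit than averaged recordings, and typically land at 65–75%.
k-means (Euclidean, Lloyd) runs 50 seeded restarts and keeps the best
within-cluster sum of squares; k equals the number of classes with at least
4 usable units.  The confusion matrix orders clusters against classes by the
Hungarian assignment maximising the diagonal — an explicit convention, and
an upper bound on any other ordering.

The ARI is computed from the contingency table by the pair-counting formula
(cross-checked in the tests against brute-force pair enumeration and
scikit-learn).  Its significance statistic shuffles class labels across
units (class sizes preserved) and reports the percentile of the observed ARI
as 100 × #{null < observed}/n_perm, strict inequality.  Because the ARI on a
finite table is discrete, ties with the observed value have positive
probability and the strict-less percentile is conservatively biased low by
half the tie mass (measured ≈ 5 points at n = 38 under the null); the
calibration test checks uniformity of the tie-corrected (mid-rank)
percentile and bounds the deviation of the strict one.

A note on identifiability: with the reported between-unit onset SDs (up to
180 ms) the class onset distributions overlap heavily, and a 38-unit session
generated with those spreads carries essentially no recoverable cluster–
class signal (ARI ≈ 0).  Correspondence testing therefore uses
`class_determined_profiles()` — the same presets with zero between-unit
onset spread, so profiles are fully determined by class up to Poisson noise.
On such sessions the observed ARI (≈ 0.8) exceeds the entire 1000-shuffle
null (percentile 100%).

## Receptive-field atlas

The figurine drawings are discretised to 15 named regions with unit area
weights (configurable); class templates follow the textual class
descriptions, including class 7 (lateral forearm + upper arm), for which no
unit was recorded.  Classification is the area-weighted Jaccard similarity
between full extents, ties broken toward the lower class id; overlap between
two fields is 100·|A∩B|/|A∪B| on full extents (strong ∪ weak), with a
strong-core-only variant behind a flag.  Because the real overlap values
derive from free-form drawings, the reported 64.4 ± 35.6 (concordant) vs
2.2 ± 3.8 (discordant) split is treated as a qualitative anchor: jittered
same-class template pairs score high, cross-class pairs near zero.

Map jitter removes each non-core template region with probability j and adds
each adjacent outside region with probability j/2; the core is never
removed, so maps stay non-empty and j = 0 returns the template exactly.

## Group statistics and orchestration

`group_compare` wraps the named designs (one-way ANOVA, Mann–Whitney,
paired/unpaired t, Pearson) and records a Shapiro–Wilk normality check next
to parametric tests without auto-switching.  α = 0.05 throughout and no
multiple-testing correction is applied; comparisons are reported as separate
named contrasts and should be interpreted as such.  `run_all` chains
filtering → profiles → modulation table → population PETHs → clustering
(skipped with a logged reason when fewer than two classes reach 4 units) →
the comparisons (baseline/onset/peak by class, pooled distal {1,2,6} vs
proximal {8,9,10} latencies, paired peak-vs-baseline by direction, fast/slow,
CS/SS overlap when maps are present), and writes a manifest holding every
seed and a config hash; outputs are byte-identical across re-runs.

## Problem sizes and determinism

The default validation session is 38 units × 40 trials (~400 s of simulated
time per unit, ~15–40 k spikes each), which the full suite processes in
seconds; the permutation statistic uses 1000 shuffles and calibration runs
200 replicates at 200 shuffles.  All randomness flows from one master seed
through named `SeedSequence` children (per class, per unit, per purpose), so
any subset of units is reproducible independently of the rest.

## Known limitations

- The latency estimator's sustained-run requirement trades a small late bias
  for false-positive control; very brief (< 70 ms) true modulations would be
  missed at the defaults.
- The atlas reduces drawn fields to 15 equal-area regions; overlap
  percentages are comparable within this package but not numerically to
  planimetry on drawings.
- ARI-percentile ties (discrete null) make the strict-less statistic
  conservative by up to a few points near the middle of the null; decisions
  at the 95% bar are unaffected in practice because signal sessions sit at
  or near the 100th percentile.
- The ANCOVA-style class × rate × duration analysis is not implemented; the
  covariate coding is under-determined and the package restricts itself to
  the named univariate designs.
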