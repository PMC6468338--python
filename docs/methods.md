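# Methods

## Model

`crcpse` implements the classical two-sample (Lincoln–Petersen) closed
population estimator. A first sample marks `M` individuals; a second,
independent sample of size `C` contains `R` marked individuals; then
`N̂ = M·C/R` with `Var(N̂) = M·C·(M−R)·(C−R)/R³` and a normal 95% interval
`N̂ ± 1.96·√Var`. The estimator is valid under four assumptions:
independent samples, a closed population between rounds, correct matching
of recaptures, and equal catchability of all individuals.

In the unique-object variant, the mark is a distinctive gift rather than a
personal identifier, so matching is indirect. Two recapture definitions
are carried through the whole package: *def2* counts only individuals who
physically present the object; *def1* additionally counts those who,
having lost it, identify the correct object on a photo sheet of 10–15
decoys. A wrong photo pick is a misidentification and counts under
neither definition; it is tallied separately.

### Reporting conventions

Person counts — the point estimate and both CI bounds — are rounded **up**
to the next whole number (`ceil`); a fraction of a person implies at least
one more. The CI lower bound is truncated at zero *before* rounding, so a
negative bound reports as 0. Prevalence is computed from the rounded
estimate as `N̂/denominator × 100` and printed half-up to 2 decimals (at
that precision, rounded and unrounded numerators give identical output on
every bundled row). The point estimate is kept as an exact integer ratio
internally; nothing is rounded before the final report.

These conventions reproduce all 36 published point estimates and
prevalences for the bundled Ugandan data. The published CI bounds are less
disciplined: 28 of 36 bounds match the ceiling rule exactly, and the
remaining 8 are off by exactly one in the source with no single rounding
rule explaining them (one published row even mixes rules between its own
lower and upper bound). The tests therefore assert CI reproduction on the
28 self-consistent bounds and document the exclusions here rather than
adopting two rules.

`R = 0` raises a structured "no recaptures" error; a multi-town run
reports the town as non-estimable and continues. Chapman's nearly
unbiased variant `(M+1)(C+1)/(R+1) − 1` is available as an explicitly
optional function and is never used implicitly.

### Planning

The target number of objects to distribute in a town assumes the key
population is 0.5% of adult women (FSW) or 1.5% of adult men (MSM);
`target_sample_size` is that share of the denominator, rounded up.

## Bundled data

Eighteen town × population rows (11 FSW, 7 MSM) from a June–August 2017
exercise in Uganda, with adult-population denominators. Three transcription
inconsistencies exist in the source and are kept verbatim, surfaced by
`consistency_checks` as report-only notes:

* Busia FSW: per-distributor recaptures sum to 23, matching neither
  recapture definition (22/19);
* Mukono FSW: distributor sum 114 vs definitions 116/113;
* Kabarole MSM: objects offered − refusals = 84 but capture 1 = 83.

One further source conflict: the Kabarole FSW def2 estimate appears as
both 397 and 398 in different places of the source; 398 = ceil(102·183/47)
is the arithmetically consistent value and is what this package computes.

## Diagnostics

* **Distributor shares** — each capture-2 distributor's recaptures as a
  share of the capture-2 total, printed to 2 decimals (half-up), compared
  unrounded. The **imbalance flag** fires when the largest pairwise share
  difference exceeds 0.10 — i.e. one team found >10 percentage points more
  recaptures than another, suggesting unequal effort or non-random
  sampling. The threshold is on absolute share difference, matching the
  units the shares are reported in; it is applied to unrounded shares and
  is symmetric in distributor labels.
* **Prevalence plausibility** — the implied prevalence is classified
  against published reference bands, endpoints inclusive: MSM 3–5% of
  adult men (global range), FSW 0.1–12.0% of adult women (African
  subnational range). Bands are reporting aids only; they never modify an
  estimate.

## Simulator

`simulate_round_trip` generates the field process per individual: draw a
capture propensity; Bernoulli capture 1; if captured, Bernoulli refusal
(refusers stay unmarked and recapturable, which preserves the
M = offered − refusals identity); marked individuals retain the object
with `retention_prob` (the 5–7 day gap); Bernoulli emigration; unmarked
immigrants enter; Bernoulli capture 2 over those present; recaptured
object-losers identify the correct photo with `photo_id_accuracy`, else
register a wrong pick. Capture-2 events are allotted to distributors by a
configurable allocation. The emitted events feed straight into
`summarize`, so recovery studies exercise the full pipeline.

Parameter defaults describe the ideal study: `true_n=1000`,
`p1=p2=0.3` (capture probabilities giving expected samples of ~300, the
order of the field counts), full retention, no refusals, closed
population, 12 decoys (mid-range of the 10–15 photo sheet), two capture-2
distributors with equal allocation.

Design choices where the process description left room:

* **Heterogeneity** — with `heterogeneity = d > 0`, each individual draws
  one propensity from a Beta with mean `p1` and variance `d·p1·(1−p1)`
  (`a = p1(1/d − 1)`, `b = (1−p1)(1/d − 1)`) and uses it in *both* rounds.
  This is the smallest parameterization that expresses unequal
  catchability together with the positive round-to-round dependence that
  biases the estimator downward; `p2` is ignored in that regime. `d = 0`
  is the homogeneous independent case.
* **False claims** — never-marked individuals claiming an object default
  to probability 0 (no rate is known for the field procedure); when
  enabled they guess the photo with probability `1/decoy_count`. Wrong
  picks by genuine object-losers are uniform over the decoys.
* **Moments** — replicates where the estimator is undefined (no
  recaptures, or an empty capture round) are counted and excluded from
  bias/RMSE/coverage; the exclusion count is part of the result.

`recovery_study` reports mean/median estimate, relative bias, RMSE, and
empirical 95%-CI coverage against the known truth, reproducibly from one
seed (replicates use spawned child seeds).

### What the simulator does and does not emulate

It reproduces the sampling mechanics (two rounds, refusal, object loss,
photo identification among decoys, migration, distributor allocation) but
not the social structure of real field data: no venues or spatial
clustering, no social-network recruitment, no distributor fabrication,
and age/GPS fields are carried but never modeled. Passing recovery tests
therefore validate the estimator's arithmetic and its documented
sensitivities to assumption violations — they do not certify unbiasedness
in any particular real town, where the violations are unobserved.

## Verification

The test suite checks, among others:

* all 36 published point estimates and prevalences, the 28 self-consistent
  CI bounds, all 36 published distributor shares, and the exact set of
  imbalance-flagged towns, recomputed from the bundled counts;
* exactness (`N̂·R = M·C`) and monotonicity properties of the point
  estimate, and agreement within ±1 with an independent brute-force
  hypergeometric maximum-likelihood search on every `(M, C, R)` with
  `M, C ≤ 30`;
* Monte-Carlo recovery at 500 replicates, `N = 1000`, `p = 0.3`:
  |relative bias| < 2% and CI coverage in [0.90, 0.98] under the ideal
  configuration; ×2 inflation of the presented-only estimate at 50%
  retention; unbiasedness restored under def1 with perfect photo
  identification; underestimation under shared-propensity heterogeneity.
  Unit tests use 200–300 replicates for speed; the 500-replicate studies
  run in the acceptance tests (a few seconds each).

## Known limitations

Two sources only (no log-linear multi-list models), normal-approximation
intervals (coverage degrades at very small R — the Tororo-style rows),
no weighting or finite-population correction (the field analysis used
none), and the CI rounding caveat above.
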