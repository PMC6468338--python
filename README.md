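# crcpse — two-source capture-recapture population size estimation

`crcpse` estimates the size of hidden populations — here female sex
workers (FSW) and men who have sex with men (MSM), the key populations of
HIV surveillance — from a two-round *unique-object* capture-recapture
exercise, and ships a simulator of that field procedure so the estimator
can be stress-tested when its assumptions fail.

In the field procedure, peer distributors offer a distinctive object (a
hand mirror, a keychain) to population members at known hotspots; the
object is the "mark". About a week later a second team asks everyone it
reaches whether they received one. A person counts as *recaptured* either
when they physically present the object or also when they identify it
correctly on a photo sheet of 10–15 decoys — two recapture definitions
(def2 and def1 respectively) that bracket the effect of object loss.

## The estimator

With `M` individuals marked in capture 1, `C` seen in capture 2, and `R`
seen in both, the Lincoln–Petersen estimate of the closed population size
is

```
N̂ = M·C / R          Var(N̂) = M·C·(M−R)·(C−R) / R³
95% CI = N̂ ± 1.96·√Var(N̂)   (lower bound truncated at 0)
```

All person counts are rounded **up** to the next whole number, and
prevalence is `N̂ / adult population × 100`. The estimator assumes
independent samples, a closed population, correct matching of recaptures,
and equal catchability; the simulator has a dial for breaking each one
(heterogeneous capture propensity, migration, object loss and photo
misidentification, refusals).

## Worked example

The package bundles the per-town counts from a 2017 two-source exercise in
11 Ugandan towns (11 FSW, 7 MSM town rows):

```python
>>> from crcpse import load_uganda_summaries, estimate_town
>>> mbale = [s for s in load_uganda_summaries() if s.town == "Mbale" and s.population == "FSW"][0]
>>> (mbale.n_capture1, mbale.n_capture2, mbale.recaptures_def2)
(111, 156, 25)
>>> e = estimate_town(mbale, "def2")
>>> (e.n_hat, e.ci_lower, e.ci_upper, e.prevalence_pct)
(693, 474, 912, 0.43)
```

111 women were marked, 156 reached in round 2, 25 presented the object, so
the estimated FSW population of Mbale is 111·156/25 → **693** women
(95% CI 474–912), i.e. 0.43% of Mbale's 161,720 adult women.

Running `python examples/estimate_town_sizes.py` prints the full table,
beginning:

```
town      pop   def     N_hat        95% CI  prev %
Mbale     FSW   def1      559       410-709    0.35
Mbale     FSW   def2      693       474-912    0.43
Jinja     FSW   def1      802      534-1069    0.56
```

The def1/def2 gap in a town measures object loss: in Tororo only 3 of 16
recaptured women still carried the object, and the presented-only estimate
balloons from 539 to 2872. `examples/simulate_object_loss.py` reproduces
that mechanism on synthetic data with known truth — at 50% object
retention the presented-only estimate doubles (×2.04 at 300 replicates)
while the photo-sheet definition stays unbiased —
and `examples/diagnose_field_quality.py` runs the data-quality report
(per-distributor recapture shares, the >10-percentage-point imbalance
flag, refusal rates, arithmetic consistency, prevalence plausibility
bands).

A thin CLI wraps the same pipeline:

```
crcpse estimate --summary counts.csv --definition both --out results/
crcpse diagnose --summary counts.csv --out results/
crcpse simulate --config sim.cfg --reps 500 --seed 1 --out results/
```

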