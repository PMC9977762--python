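# flocknet

Social network analysis for large captive bird flocks, built around the kind
of data a photographic association study of flamingos produces: repeated
group-composition samples with partial individual identifiability,
behavioural event logs tied to personality traits, and agonistic event logs
with win/loss/draw outcomes and social-support records.

The package answers three questions about a flock:

1. **Do birds associate non-randomly?** Group sightings are turned into a
   half-weight association index (HWI) matrix and observed lagged association
   rates are compared against a permutation null that re-assorts identities
   day by day.
2. **Does personality structure the network?** Per-bird tallies of
   aggressive, exploratory and submissive behaviour are condensed into a
   single personality score (PC1 of the trait correlation matrix), binned
   into ordinal categories, and tested as a dyadic dissimilarity predictor of
   the HWI matrix by MRQAP with double semi-partialing — alongside sex,
   origin and age controls.
3. **Does personality predict social role and social support?** Node degree,
   betweenness, average association strength, fight totals/outcomes and
   social-support frequency are regressed on personality score and age with
   node-label permutation inference.

## The statistics in brief

For a dyad (A, B) sampled across photographic sessions, with `x` samples
together, `y_AB` samples both identified but apart, and `y_A`, `y_B` samples
where only one was identified:

```
HWI = x / (x + y_AB + (y_A + y_B) / 2)         in [0, 1]
```

The lagged association rate `g(τ)` is the probability that a dyad associated
on day `d` (sharing a subgroup in ≥1 sample, after the chain rule and the
unidentified-bird exclusions) associates again on day `d + τ`, given both are
identified then; the null rate is the same statistic after daily identities
are shuffled uniformly within each day's identified set, preserving subgroup
sizes. Observed and null rates are compared with a paired t-test across lags.

MRQAP regresses the vectorised HWI matrix on dyadic predictor matrices
(|category-rank difference| for personality, |age difference|, sex/origin
mismatch). Each predictor's p-value comes from node permutations of its
residual matrix (Dekker double semi-partialing), so homophily appears as a
*negative* partial correlation of the dissimilarity predictor. Node-level
regressions are ordinary least squares with p-values from shuffling the
response across birds; all permutation p-values use (1 + #extreme)/(1 + n)
and are reproducible given a seed.

A fully parameterised synthetic-data generator (`flocknet.simulate`) emulates
the study design — two daily-sampled flocks of 115–147 birds, 4 samples/day
on 4 consecutive days a week, ring concealment, personality/sex/origin/age
homophily, persistent companion bonds, and personality-linked fight and
support rates — so the entire pipeline is testable end to end with known
ground truth.

## Worked example

Simulate a small flock (30 birds, 20 observation days) and run the whole
pipeline:

```
$ flocknet simulate --out demo/data --profile small --seed 7
synthetic dataset written to demo/data

$ cat demo/config.yaml
sightings: demo/data/sightings.csv
roster: demo/data/roster.csv
behaviour: demo/data/behaviour.csv
fights: demo/data/fights.csv
supports: demo/data/supports.csv
outdir: demo/out
n_perm_mrqap: 1000
n_perm_node: 1000
n_perm_null: 100
seed: 7

$ flocknet run-all --config demo/config.yaml
done: 30 birds, lag vs null t(30) = 2.204, p = 0.0353
```

The lag rate (mean 0.381) sits above the null rate (mean 0.374) across the
30 supported lags and the paired test rejects at α = 0.05: the simulated
birds associate non-randomly, as expected from the generator's default
homophily and companion-bond settings. The personality extraction prints

```
$ flocknet personality --behaviour demo/data/behaviour.csv \
      --roster demo/data/roster.csv --out demo/out
PC1 eigenvalue 1.633 (54.43% of variance)
```

meaning one component captures ~54% of the variance of the three positively
correlated trait tallies. `demo/out/mrqap.csv` holds the dyadic regression:

```
predictor    partial_correlation  p_value
personality              -0.1764   0.0040
age                      -0.1998   0.0010
sex                      -0.0525   0.3916
origin                   -0.1322   0.0070
```

The negative, significant personality partial correlation says that dyads
with more similar personality categories have higher association indices —
the homophily the generator planted. Node metrics, the Bray–Curtis
behavioural similarity matrix, agonistic summaries, node-label permutation
regressions and a GraphML export of the weighted network land in `demo/out/`
alongside a manifest of seeds and parameters; re-running the same config
reproduces every file byte for byte.

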