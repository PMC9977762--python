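# Methods

This note documents the models, estimators, numerical choices and known
limitations of flocknet, module by module.

## Association data model

The sampling unit is the photographic session: a partition of the sighted
birds into subgroups plus, per subgroup, a count of birds whose leg rings
could not be read. Two collection conventions are supported:

* **Pre-grouped sightings** (`day,slot,subgroup,bird_id,n_unidentified`),
  where the observer has already resolved subgroup membership.
* **Proximity edges** (`day,slot,bird_a,bird_b`), pairs judged within one
  neck length. The *chain rule* converts these to subgroups as the connected
  components of the proximity graph: birds farther apart than the threshold
  still associate when linked through intermediates. A `ProximityRecord`
  carries the full set of sighted ids in addition to the edges — edges alone
  cannot represent a bird sighted alone, which must become a singleton
  subgroup.

Unidentified birds are carried as per-subgroup counts rather than
placeholder ids so the exclusion rules are deterministic: a pair containing
an unidentified bird is discounted entirely (the identified partner
contributes nothing that session); in subgroups larger than two the
unidentified members are dropped and the identified associations kept;
wholly unidentified subgroups are removed.

Day indices are integer offsets from the study start. Calendar parsing, if
any, belongs at the reader boundary; every analysis needs only ordered days.

## Half-weight association index

Counts are accumulated per session (not per day) for each dyad: `x` sessions
together, `y_AB` both identified but apart, `y_A`/`y_B` only one identified.
The association index is the half-weight form

    HWI = x / (x + y_AB + (y_A + y_B)/2),

the standard estimator when universal identification within a sample is
impossible; with full identifiability it reduces to `x / (x + y_AB)`.
Birds added mid-study (the roster's `first_day_present`) accrue counts only
from their arrival, so denominators are dyad-specific. Dyads never jointly
observable score 0 — with a logged warning — rather than NaN, keeping the
matrix dense for MRQAP. A bird photographed alone counts as "identified but
not associated" by default; `count_singletons=False` treats lone birds as
unsampled instead (the choice is a sensitivity switch because field
protocols differ on it, and the data alone cannot decide).

Matrix files store the full symmetric matrix (not a triangle) so corruption
is detectable via the symmetry check on read; floats are written at `repr`
precision, making write→read an exact round trip.

## Network metrics

Degree, betweenness, clustering and path length are computed on a binarized
graph (edge iff HWI > threshold; default threshold 0, appropriate for the
dense networks of large captive flocks and exposed as an option for
sensitivity analysis). Average association strength is the row mean of the
weighted HWI matrix over the other N−1 birds.

* **Betweenness** is unweighted shortest-path betweenness with fractional
  credit among tied geodesics (Freeman/Brandes), unnormalised. A verbal
  "number of shortest paths through the node" definition does not resolve
  ties; fractional credit is the field convention.
* **Clustering** is the mean local (Watts–Strogatz) coefficient over nodes
  of degree ≥ 2 (lower-degree nodes have no defined local clustering and are
  excluded with a log message). Because the applied literature often
  conflates this with the global triangle ratio, the transitivity variant is
  computed and reported alongside.
* **Average path length** is the mean geodesic over connected ordered pairs;
  disconnected pairs are excluded with a warning rather than mapped to
  infinity.
* An edgeless network yields NaN metrics with `defined=False`; nothing is
  fabricated.

## Temporal analysis

Sessions are pooled into days: a dyad is "associated on day d" if it shares
a subgroup in at least one of that day's samples. The lagged association
rate at lag τ aggregates over all day pairs (d, d+τ):

    g(τ) = Σ #{dyads associated on d and on d+τ} /
           Σ #{dyads associated on d with both identified on d+τ}.

The null holds each day's identified set and subgroup sizes fixed and
shuffles identities uniformly within the day; the null rate at τ is the mean
of the recomputed rate over Monte-Carlo replicates (default 100 shuffles —
the null mean stabilises quickly because every day pair contributes).
Shuffling can move association onto birds unidentified at the later day, so
a lag may lose support in a given replicate; the null is the mean over
replicates that retain support.

Observed and null rates are compared with a two-sided paired t-test, paired
by lag (τ = 1 … max observed span). Pairing by lag matches a rate-vs-lag
reading of the comparison and gives df = (number of supported lags − 1);
with one observation day per calendar day over k days this is k − 1.
Lags supported by fewer than 10 dyad-days are dropped (logged) to avoid 0/0
noise. If observed and null agree exactly at every lag the test returns
t = 0, p = 1; a constant nonzero difference is flagged as zero-variance with
p undefined. Type-I calibration of the whole construction is verified by
simulation in the test suite (rejection ≈ 5% under the exchangeable
generator).

## Personality

Each bird's aggressive / exploratory / submissive event counts form its
trait tally. Behavioural similarity between birds is Bray–Curtis,
`1 − Σ|x−y| / Σ(x+y)` over the three traits; a pair of all-zero tallies has
no defined similarity and is NaN with a warning.

The single personality score is the first principal component of the
**correlation** matrix of the three tallies (tallies are z-scored first).
The correlation matrix is used rather than the covariance because the traits
are counts on different base rates; the component is sign-oriented so the
loading sum is positive, making larger scores mean more frequent aggressive,
exploratory *and* submissive behaviour. The eigenvalue, its share of the
total variance (eigenvalue/3 × 100), raw unit-norm loadings and
trait–component correlations (loading × √eigenvalue) are all reported, since
extraction tables in the literature do not always say which convention they
print. Tallies are not rate-normalised by observation time by default (a
fixed observation protocol makes raw tallies comparable); normalisation by
`observation_hours` is available upstream of the PCA if protocols differ.

Scores are binned into ordinal categories A < B < C < D. The field protocol
states rounded, slightly gapped bounds (A below −0.9, B from −0.89 to 0, C
from 0.1 to 1.0, D above 1.1); the default reading closes the gaps into
contiguous half-open bins at −0.9, 0 and 1.0, treating the printed bounds as
rounded bin edges. A `strict` mode enforces the printed bounds verbatim and
raises on scores falling inside a gap, so the discrepancy can never pass
silently.

## MRQAP and node-label permutation regression

Both engines separate estimation from inference: coefficients are exactly
OLS; permutations only build the reference distribution. All Monte-Carlo
p-values use the add-one rule (1 + #extreme)/(1 + n_perm), so p = 0 is
impossible; exact enumeration over all n! node permutations is available for
small problems and then reports the exact tail fraction.

**MRQAP.** The response is the vectorised upper triangle of the HWI matrix;
predictors are dyadic matrices built from node attributes with
*dissimilarity* coding — |category-rank difference| for personality (A=1 …
D=4; raw-score |difference| is an option), |age difference| in years, and
0/1 mismatch for sex and origin (unknown sex is its own level, so
male-vs-unknown is a mismatch). Homophily therefore appears as a negative
partial correlation. Significance uses Dekker's double semi-partialing:
predictor k's residual matrix (k regressed on the other predictors over
dyads) is permuted by a common row/column node permutation, re-residualised
on the other predictors, and its correlation with the residualised response
recomputed; the two-sided p compares |statistic| tails. DSP is the modern
default for multi-predictor QAP and robust to predictor collinearity;
simple response-matrix permutation is retained as `method="y"` for
cross-checking. A collinear design (condition number > 1e8) is rejected
with the offending predictor pair named. A stability mode re-runs the test
at 1000/5000/10000 permutations to expose p drift. Permutation counts below
99 are refused outside exact mode.

**Node regressions.** Social-role metrics (degree, betweenness, average
association strength) and agonistic responses (fight totals, wins, losses,
support given) are regressed on personality score and age. The response is
shuffled across birds; per-predictor upper, lower and two-sided tail
p-values are reported (ties included in both tails, so p_upper + p_lower ≥
1) together with a model p from the permutation distribution of F. The
upper-tail p is reported alongside the two-sided one because
published tables of this design print one-tailed upper p-values (p > 0.999
for negative coefficients is that test's signature). A constant response
yields zero coefficients and undefined p, flagged.

## Agonistic summaries

Each fight's identified participants accrue one `total_fights` plus exactly
one of won/lost/drawn, so the partition identity holds for every bird after
any event stream. Draws are counted in totals but kept as their own column
(downstream models use totals, wins and losses). A social-support record
counts only if the supporter did not instigate the fight, supporter and
supported share a side, both are identified, and the supported (focal) bird
was not displaced afterwards; invalid records are rejected with a warning.
Sides and outcomes come from the observer's log — no geometric or
behavioural adjudication is attempted. "Social support frequency" as
modelled is support *given*; support received is kept for completeness, and
the two totals balance over the flock by construction.

## Synthetic data generator

`SimConfig` defaults describe a single study-scale flock: 140 birds (45%
male, 45% female, 10% unsexed; half wild-caught; ages uniform on 2–45
years), 69 observation days on a 4-consecutive-days-a-week calendar, 4
photographic samples a day, a 9% cohort of birds arriving ~60% of the way
through the study, a mean subgroup size of 10, and a 15% per-sighting ring
concealment probability. Group composition per sample uses sequential
seating: birds are placed in random order and join an existing subgroup
with weight `size × exp(mean affinity to members)` or open a new one with a
concentration weight solved (by bisection on the expected-cluster-count
identity) to hit the target mean subgroup size. Affinity is

    −w_personality·|z_i − z_j| − w_sex·mismatch − w_origin·mismatch
    − w_age·|age_i − age_j| + pair_fidelity·bond(i, j),

with `z` a latent standard-normal personality scalar and `bond` a fixed
random matching over ~60% of the flock representing persistent preferred
companions. With all weights zero the process is a plain Chinese-restaurant
partition — exchangeable over identities, which is what makes the null
calibration studies exact in distribution.

Behavioural events are Poisson with log-rate linear in z (default base
means 20/10/15 for aggressive/exploratory/submissive and slope 0.2, chosen
so the three tallies are positively correlated and PC1 carries roughly half
to two-thirds of the variance, the regime reported for real flocks). Fights
draw an instigator with probability ∝ exp(fight_rate_slope·z), a uniform
opponent, a logistic win probability in (z_i − z_j) with a 10% draw rate,
and a potential supporter recruited from the focal bird's high-affinity
neighbours who joins with probability logistic in their own z; 20% of
support acts end with the focal bird displaced (so the counting rule is
exercised), and 5% of fight participants lose their identity to emulate
observation failures.

Two derived profiles fix the conditions used by the test suite:
`SimConfig.small()` (30 birds, 20 days, mean subgroup 5) for fast runs;
`.null()` zeroes every homophily weight and effect slope; `.strong()` sets
unambiguous effects (personality weight 2.0, fidelity 3.0, behaviour slopes
0.5, fight base 15 with slope 1.0, support probability logistic(3z)) for
direction and power checks.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: breeding-season dynamics and temporal drift
in preferences (affinities are constant over the study), enclosure geometry
and spatial constraints on grouping, observer biases beyond uniform ring
concealment, behavioural plasticity (z is fixed per bird), and any
species-level differences beyond parameter values. Synthetic networks at
study scale are also denser than real flock networks (nearly every dyad is
eventually seen together, so clustering and path length sit near 1.0 at
threshold 0); real flocks show more zero dyads than uniform-baseline seating
produces.

## Problem sizes and numerical choices

Calibration studies in the test suite use 500 replicates of the null small
profile with 199 permutations per test and 100 null shuffles; power studies
use 100 replicates of the strong profile. Exact-enumeration checks use 4
nodes (24 permutations) for MRQAP and 6 birds (720 permutations) for node
regression. Oracle-equivalence checks run 200 random sighting sets of up to
8 birds and 20 sessions against brute-force recounts at 1e−10. The
acceptance script analyses one default-profile flock (140 birds, 276
sessions) with 1000 permutations. Tie comparisons in permutation tails use
an absolute tolerance of 1e−12; collinearity is declared at condition number
1e8. All randomness flows from explicit seeds through numpy Generators
(independent child streams per pipeline stage via `SeedSequence.spawn`), and
every seeded stage is bit-reproducible.

## Known limitations

* The HWI assumes identification failures are independent of identity; the
  generator obeys this, real ring concealment may not (habitual one-legged
  standers).
* The paired t-test across lags treats per-lag rates as exchangeable paired
  observations although they share underlying days; simulation shows the
  test is nonetheless well calibrated under the generator's null, but that
  is an empirical, not analytic, guarantee.
* DSP p-values are asymptotically, not exactly, conditionally valid for
  n_perm-based Monte-Carlo use; exact enumeration is available only for toy
  sizes.
* Flock-level comparisons between two analysed flocks are deliberately out
  of scope: each flock is an independent run and the report contains no
  cross-flock inferential statistics.
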