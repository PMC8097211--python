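# Methods

This note documents the models implemented in `driftnet`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real field data.

## Event model and ingestion

A *visit event* is a deduplicated detection of one tagged wasp at one nest.
Antennae map many-to-one onto nests (2–4 antennae per nest front), so reads
from sibling antennae are merged before deduplication. Within a tag, a read
opens a new event when (a) it occurs at a different nest from the previous
retained event, or (b) it is at least `window` seconds (default 60) after
the previous retained event's first read. Measuring the gap to the
*retained event's start* rather than to the preceding raw read makes the
rule idempotent and avoids bin-boundary artifacts of fixed 60-s binning; a
nest change always splits, since a wasp physically moved. Events are
assigned to monitoring periods by timestamp against an explicit calendar of
half-open intervals `[start, end)` — a boundary read belongs to the earlier
period — and events outside every period are counted and excluded, never
silently dropped; the same holds for unparseable lines and reads from
unmapped antennae.

A wasp's home is the nest on which it was tagged. Drift classification is
purely positional (visited nest ≠ home nest); wasps whose tags are missing
from the roster are flagged and excluded from classification. Per-nest
*return fidelity* is the fraction of a nest's own wasps' events that are
natal.

The detection-rate helper formalizes the standard binomial argument: with a
fraction `c` of the nest front inside the detection zone and `k`
independent passes (entry and exit give `k = 2`), the probability of at
least one detection is `1 − (1 − c)^k`.

## Diffusive null and social differentiation

The null model for within-aggregation drift heterogeneity holds each
nest's drifter out-strength `R_i` fixed and redistributes it over the other
nests with a Gaussian kernel of the inter-nest distance,
`K(x) = exp(−x²/2σ²)`:

    E_ij = R_i K(X_ij) / Σ_{k≠i} K(X_ik).

Rows of `E` sum to `R_i` exactly, and as σ grows `E` converges entrywise to
the flat null `R_i/(N−1)`. The social-differentiation statistic is the
coefficient of variation of edge weights about this expectation,
`S = sqrt(v)/μ` with `v = Σ_{i≠j}(O_ij − E_ij)²/N(N−1)` and
`μ = Σ_i R_i/N`. Two mode flags exist because the statistic admits two
readings: `kernel="as-printed"` uses `exp(−x/2σ²)` (exponential decay
rather than Gaussian), and `sqrt_v=False` reports `v/μ`. The defaults are
the Gaussian kernel and the square root, consistent with a Gaussian
distance model and with `S` being a coefficient of variation (sd over
mean). Note the units of `μ` (per nest) differ from those of `v` (per
dyad); `S` is used only comparatively, against its own Monte-Carlo null, so
the constant factor is immaterial.

Null replicates draw row `i` of a null `O` as Multinomial(`R_i`, kernel
probabilities) and are scored against the *same* fixed `E`; the p-value is
the plus-one rule `(b+1)/(m+1)` with `m = 9999` replicates by default, so p
is never zero and the smallest reportable value is `1/(m+1)`. Because σ is
unknown, the test sweeps a grid (default: 20 log-spaced values from 0.1×
the smallest to 10× the largest inter-nest distance) and reports the σ
*maximizing* the p-value, ties broken toward larger σ — the most
conservative choice available, since rejecting under the best-supported
null is the strongest statement. Grid values small enough to underflow the
kernel for some row are skipped and recorded as NaN in the per-σ table.
Aggregation-level p-values combine via Fisher's method,
`T = Σ −2 ln p ~ χ²(2k)`; p-values known only as upper bounds are floored
at that bound first.

Calibration: when data are generated from the diffusive null at the tested
σ, the test's type-I error is nominal (checked at 500 simulated
aggregations, N = 10); against a preferred-partner alternative (each nest
sends all drifters to one partner) the observed S exceeds the null's 99th
percentile essentially always at R_i = 20.

## Edge persistence

Presence of a directed dyad in a period is `O_ij > 0`. The recurrence table
counts dyads present in ≥1, ≥2, ≥3 and all periods. The null redraws, per
period and replicate, each donor's recipients uniformly without replacement
while preserving exactly (a) that donor's binarized out-degree and (b) the
period's totals of within- versus between-aggregation edges. The
implementation deals a shuffled multiset of within/between "tokens" to
donors and repairs capacity violations by swapping tokens between donors;
both constraints hold exactly in every replicate (asserted in tests),
though the distribution over the constrained space is approximately rather
than provably uniform. The `≥1` threshold is tested in the *fewer
transient dyads* direction (fewer distinct dyads than the null implies
recurrence); higher thresholds in the *more recurring* direction. The
within/between split is preserved in total, not per ordered aggregation
pair. The persistent-versus-transient weight comparison takes the nonzero
per-period event counts of dyads at or above an incidence threshold
(default 2 — the split point is not canonical, so it is a parameter) and
uses a rank-sum statistic with a label-shuffling permutation p.

## Assortment by building

The mixing matrix `e` holds the fraction of binarized directed edges per
ordered building pair; `r = (Tr e − Σ a_g b_g)/(1 − Σ a_g b_g)` with `a`,
`b` the row/column sums. The directed form is the default (the drift
network is directed); an undirected option symmetrizes. When every edge
falls in a single class-to-class diagonal cell the formula degenerates to
0/0; with more than one label class present this is the perfectly
assortative limit and `r = 1` is returned, while a single-class network is
flagged undefined. The standard deviation of `r` comes from a
delete-one-edge jackknife, `sd² = Σ_edges (r_(−e) − r)²`.

For campaigns whose buildings were not all monitored simultaneously,
between-building drifting is only observable in the directions and pairs
that overlapped; the constrained trace null fixes each nest's out-degree,
re-points its edges to distinct destinations drawn uniformly from an
allowed-destination mask (supplied as data: permitted source-group →
destination-group pairs), and compares the observed within-building edge
fraction Tr(e) to the null distribution (plus-one rule, trace ≥ observed).
On a 4-nest toy the sampled null matches exhaustive enumeration of all
feasible destination assignments to total-variation distance < 0.05.

## Blocked logistic MRQAP (double semi-partialing)

The response is binary drift occurrence `y = (O_ij > 0)` on ordered
within-block dyads — binarized because drift counts are sparse and skewed.
Blocks are aggregation×campaign strata that could physically exchange
wasps; dyads never cross blocks, and blocks with fewer than three nests are
excluded (no nontrivial permutation exists). Covariates follow the
donor/recipient parameterization: distance, donor size, recipient size,
donor worker:brood, recipient worker:brood, where worker:brood is adult
females over medium+large larvae (the stages receiving most forage). A
nest with zero medium+large larvae has an undefined ratio and its dyads are
excluded by default. A signed-difference worker:brood covariate can be
fitted instead by adding the column to the design and naming it in
`covariates`.

Estimation is maximum likelihood by Newton/IRLS; complete separation is
detected (coefficients exceeding ±30 log-odds or a degenerate Hessian) and
flagged with capped estimates rather than silent divergence. The
permutation scheme is double semi-partialing: the focal covariate is
residualized by OLS on the other covariates at the dyad level (linear
residualization, per the method's construction, even though the outcome
model is logistic); each permutation draws an independent node relabelling
within every block, applies it simultaneously to donor and recipient
indices of the residual matrix (`P ε Pᵀ`), refits the logistic model with
the permuted residual in the focal column, and records the coefficient.
Because the residual spans the same column space as the raw covariate, the
identity relabelling reproduces the observed coefficient exactly (up to
IRLS round-off; a small tie tolerance absorbs this). The report gives both
one-sided tail probabilities, `Pr(<=b)` and `Pr(>=b)`, each with the
plus-one rule; they overlap on ties, so their sum is at least 1. The
intercept has no natural QAP null and is reported without tail
probabilities unless `test_intercept=True`, which permutes the response
itself. The permutation count defaults to 2000 and the fraction of
non-converged permutation refits is tracked; above 5% the result is
flagged unstable.

The null ensemble used for calibration deserves a note: a colony simulated
with zero covariate effects still shows a *true* association between donor
size and drift occurrence, because more wasps mechanically produce more
drift events. The hypothesis the blocked QAP-DSP tests is exchangeability
of the covariate with respect to the network under within-block node
relabelling; the calibration ensemble therefore reassigns the census
covariates at random within buildings after simulating the network. Under
that ensemble all five covariates reject at the nominal 5% rate (200
simulated colonies); against a strong negative distance effect
(β = −0.5/m at kernel scale 4 m, two blocks of 10 nests) power exceeds
90%.

## Auxiliary statistics

The distance–relatedness Spearman correlation is tested by permuting nest
identities within each aggregation — rows and columns of the relatedness
matrix move together while positions (distances) stay fixed — so the
dyadic dependence structure is preserved under the null; dyads are
unordered within-block pairs, the p-value two-sided with the plus-one
rule. The distance-class comparison of relatedness (threshold 1 m,
configurable) uses a midrank rank-sum statistic with label-shuffling
permutations and reports the null mean alongside. Within- versus
between-aggregation distances are compared with a Welch (unequal-variance)
t-test; the variance assumption is not canonical, and Welch is the safer
default given 2–4 within-building distance samples per campaign versus a
handful of between-building gaps.

## Synthetic colony generator

The generator's defaults emulate the published field setting: buildings
425 m apart; nests scattered within a building with an isotropic Gaussian
of sd 3.44 m, giving a mean within-aggregation pairwise distance of
`sd·√π ≈ 6.1 m`; group sizes negative-binomial around 19.6 adults
(dispersion k = 2.4, matching the census spread); medium+large brood
negative-binomial around 15 (k = 3 — field brood counts are overdispersed,
and this also decorrelates nest size from worker:brood ratio); four
monitoring periods of five days; events emitted homogeneously over the
08:00–18:00 foraging window (within-day dynamics are unspecified in the
field protocol, so the simplest assumption is used); and a natal-return
probability calibrated so that ~8.5% of events are drifts.

Each event is a drift with a per-nest probability given by a logistic link
in the *donor-level* covariates (donor size, donor worker:brood), with the
intercept solved numerically so the colony-wide mean drift rate equals the
configured target exactly. Drift destinations follow
`P(j | i) ∝ exp(−X_ij²/2σ_gen²) · logistic(η_ij) · γ_ij`, where η carries
the covariate effects and γ is a log-normal per-dyad preference that
carries over to the next period with probability `persistence` (default
0.8). Donor-level effects cannot enter the destination choice — the choice
renormalizes within each donor's row, cancelling them — which is why they
drive the drift/return decision instead; recipient-level, dyad-level and
distance effects live in the destination choice. This placement makes
sign recovery through the downstream dyadic model well-posed: the model
fits the same logistic family the generator samples from.

Each emitted event becomes 1–3 raw antenna reads within the dedup window at
one of the nest's 2–4 antennae, so generated logs exercise the full ingest
path; detection is perfect by default (`detection_prob = 1`), making exact
round-trip recovery of the true drifter set a testable invariant, with
optional thinning to mimic the ~96% field detection rate. Same seed, same
outputs, bit for bit.

With default donor effect sizes (0.02 per adult, 0.15 per unit
worker:brood) the synthetic campaign's median per-nest return fidelity
falls in the mid-90s percent range, in line with the field summary; drift
is then mildly concentrated in large, worker-biased nests.

What the generator does *not* emulate: individual-level heterogeneity in
drift propensity within a nest (field data show a minority of individuals
doing most drifting; here all of a nest's wasps share one propensity, so
the fraction of individual drifters runs higher than in the field),
tag loss and collisions, detection-probability variation between nests,
within-day activity rhythms, brood development and census dynamics
(censuses enter as one analysis-window average per nest), and any
behavioural feedback between manipulation and drifting — the
worker/brood-removal manipulation changes covariates only. Passing tests
therefore certify the statistical machinery under the stated generative
assumptions, not the field realism of those assumptions.

## Numerical choices and problem sizes

Permutation defaults follow the analysis conventions: 9999 replicates for
the heterogeneity null, 10000 for persistence, 4999 for the trace null and
the auxiliary tests, 2000 for the MRQAP; all use the plus-one rule and an
explicit seed, and identical seeds give identical p-values. Calibration
and power studies in the test suite and acceptance script run at reduced
sizes chosen to keep Monte-Carlo error interpretable: 199–499 replicates
per test, 200–500 simulated colonies for type-I rates, 20–30 runs for
power and sign recovery, with acceptance bands of three Monte-Carlo
standard deviations. The sign-recovery study uses three buildings of 14
nests, three 5-day periods at 4 events/wasp/day, and effect sizes
(−0.3/m distance, ±0.12 per adult, ±0.8 per worker:brood unit) — strong
enough to be identifiable from ~40 nests' worth of dyads, which is the
realistic information bound for nest-level covariates.

## Known limitations

* The persistence null's token-repair sampler meets both conservation
  constraints exactly but its distribution over the constrained space is
  not proven uniform.
* The MRQAP residualization is linear; a fully model-based (deviance
  residual) variant is not implemented.
* `S` has no analytic null distribution; inference is Monte-Carlo only.
* The trace-null and persistence-null infeasibility errors identify the
  offending donor but do not attempt constraint relaxation.
* Aggregation-wide (between-block) effects are untestable by construction
  in the blocked MRQAP — the stratification that makes within-block
  inference valid removes between-block contrasts.
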