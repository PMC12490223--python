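# Methods

`neobasket` reimplements, as a tested library, the statistical machinery of a
two-cohort neoadjuvant immunotherapy trial in mismatch-repair-deficient
(dMMR/MSI) colorectal cancer: one basket of clinical T4 colon cancers, one of
rectal cancers, each scored by pathological complete response (pCR) against
its own historical control. The package has three layers: the endpoint
analysis applied to individual patient data (exact binomial intervals,
Kaplan-Meier and reverse-Kaplan-Meier estimation, quartile summaries), the
Bayesian hierarchical two-stage design (posterior computation, threshold
calibration, operating characteristics, posterior-predictive probability of
success), and a synthetic-data generator that emulates the patient table so
every stage is testable without external data.

## The patient table and its encoding

The packaged fixture transcribes the trial's individual-patient table:
22 patients (14 colon, 8 rectum) with regimen, RAS/RAF status, surgery,
cycles, time to surgery (TTS), pathological stage (ypTN), tumor regression
grade (TRG, 0-3; grade 0 is pCR, equivalently ypT0N0) and follow-up. All
durations are months from the start of study treatment. Three encoding
decisions were forced by inconsistencies in the printed table and are
recorded in the fixture header:

* One rectal patient's surgery cell reads "no" while the row carries a time
  to surgery, ypT0N0 and TRG 0, and the rectal per-protocol set of six
  operated patients only reconciles if the patient was operated; the fixture
  encodes surgery = yes.
* R0 resection status is not reported per patient; every operated patient is
  encoded R0 (consistent with the 100% per-protocol R0 rate).
* Exactly one event-free-survival event exists (clinical complete response
  at month 6, regional-node progression three months later: event at
  month 9); every other patient is event-free.

Analysis sets follow the trial's definitions: full analysis set (FAS) = all
enrolled, per-protocol set (PPS) = operated and protocol-compliant, safety
set = at least one dose (all). Non-operated watch-and-wait patients count in
FAS pCR denominators and never in numerators, so the FAS and PPS pCR
numerators coincide by construction.

**Published-cutoff reconstruction for survival rows.** The survival analysis
in the publication was run at a data cutoff whose stated median follow-up
(35.6 months) exceeds every per-patient follow-up value in the printed
table, which is evidently an earlier snapshot; per-patient follow-up at the
later cutoff was never published. Read literally, the snapshot puts one
event-free rectal patient (8.8 months of follow-up) outside the risk set at
the month-9 progression event, giving a one-year event-free survival of
6/7 = 86% instead of the published 88% = 7/8. The survival rows therefore
use a documented reconstruction: censoring times of event-free patients are
floored at 12 months (`censor_floor=12.0` in `efs_input`), encoding the fact
— implied by the published estimate and the stated cutoff — that all
event-free patients were at risk at one year. Event times are never
adjusted, and the raw snapshot encoding remains the default of the
endpoint builder. The same tension explains why the time-to-surgery medians
recomputed from the table (colon 2.7 months) sit below the published text
values (3.5 months): the recomputed numbers are reported side by side with
the printed ones, not forced to agree.

## Exact binomial intervals

Every published rate carries a two-sided 95% Clopper-Pearson interval. The
bounds invert the equal-tailed binomial tests, computed through the
beta-quantile identity (exact to floating point; the percent formatting
needs no more than 1e-10): lower = Beta^{-1}(alpha/2; x, n-x+1), upper =
Beta^{-1}(1-alpha/2; x+1, n-x), with closed boundaries at x = 0 and x = n.
Report percentages use half-up rounding to one decimal (so 13/16 = 81.25%
prints as 81.3). A deterministic enumeration oracle certifies conservatism:
coverage(n, p) = sum over x of Binom(x; n, p) * 1[p inside interval(x)] is at
least the nominal level over the whole tested (n, p) grid, with no Monte
Carlo. Wilson and Jeffreys intervals exist solely to audit discordant
printed cells; note the Wilson score equation at x = n has roots p = 1 and
p = n/(n+z^2), so its upper bound there is exactly 1.

Four published interval cells are not consistent with the exact method the
publication states (6/8 printed 35.6-95.5 vs exact 34.9-96.8; 11/14 printed
48.8-94.3 vs exact 49.2-95.3; the 6/6 lower bound printed 51.7 vs exact
54.1 = 100 x 0.025^(1/6); 5/6 printed 36.5-99.1 vs exact 35.9-99.6). The
generated table report flags these cells and shows both values; it never
overwrites or reverse-engineers them. Objective-response numerators are not
derivable from the patient table (per-patient radiology was not published),
so ORR rows require explicitly supplied counts.

## Survival estimation

Kaplan-Meier fitting is delegated to lifelines; on top of its event table
the package computes the Greenwood variance and a linear-scale Wald interval
clipped to [0, 1]. The linear scale is deliberate: the published cells have
the shape "88% (64%-100%)", and a log-log interval can never produce an
upper bound of exactly 100%. Because the published rounding rule is unknown,
the audit compares survival percentages with a tolerance of one percentage
point (the recomputed lower bound is 64.6%, printing as 65% under half-up
rounding against the published 64%).

Median follow-up uses the reverse Kaplan-Meier method: censoring becomes the
event, and the median/quartiles are read off the curve at S = 0.5, 0.75,
0.25. Quantiles use first crossing (first drop time with S <= q), refined at
exact ties: when the curve lands exactly on q, the midpoint of the adjacent
drop times is returned. With zero events this convention reproduces type-2
sample quantiles (inverse ECDF with averaging) exactly, which is the
reduction the property tests assert. Time-to-surgery is summarized by the
median with Tukey-style hinges in the half-excluding convention (the halves
omit the middle value when the count is odd); this convention uniquely
reproduces the published rectal IQR of 4.4-7.3 months.

## The hierarchical basket model

Cohort j contributes x_j ~ Binomial(n_j, p_j). Because the cohorts carry
different historical controls (3% colon, 10% rectum), exchangeability on the
raw logit scale would encode an implausible prior; the model instead places
it on the null-offset logit scale, the standard basket-design device:

    delta_j = logit(p_j) - logit(p0_j)
    delta_j | mu, tau ~ Normal(mu, tau^2)
    mu ~ Normal(0, 10^2)
    tau ~ Half-Normal(1)

delta_j > 0 means cohort j beats its own control, and the per-cohort
decision quantity is the exceedance P(delta_j > 0 | data). tau -> 0 forces
complete pooling (one shared delta); large tau recovers independent
analyses under a diffuse prior on delta, whose conjugate limit is the
Haldane-prior posterior Beta(x, n-x) on p (a flat prior on delta transforms
to the Beta(0,0) kernel on p — not the uniform Beta(1,1)). The original
supplementary model specification is not public; this parameterization and
the priors are the package's own reconstruction, and the sensitivity of each
reported quantity to that reconstruction is discussed below.

### Posterior computation

Two engines cross-check each other.

*Quadrature* (the default, deterministic). The posterior over (mu, log tau)
is integrated on a product grid: uniform nodes in log tau over
(tau_scale x 1e-3, tau_scale x 3.5), and a composite mu axis — coarse nodes
across the prior support merged with fine nodes across each cohort's
likelihood region — with trapezoid weights, so the narrow likelihood ridge
at small tau stays resolved however wide the prior is. At each node the
cohort-level integral over delta is split at delta = 0 (the exceedance
numerator) and evaluated in the conditional-prior CDF variable
u = Phi((delta - mu)/tau) by fixed-order Gauss-Legendre: node placement
follows conditional-prior mass, which handles tau -> 0 spikes, while the
segments outside the likelihood's fine region — where the binomial is
asymptotically constant — are Gaussian tail integrals in closed form, which
handles tau much wider than the likelihood. Doubling every grid size moves
the trial-data exceedance by less than 1e-3 (in practice ~1e-10), and the
diffuse-limit check agrees with the conjugate oracle to ~3e-4.

*Random-walk Metropolis* on (delta_1, delta_2, mu, log tau): four chains of
40,000 iterations, half burn-in, joint Gaussian proposals whose scalar step
size adapts to ~25% acceptance and whose covariance is refreshed twice from
the burn-in history; adaptation stops at burn-in end. Effective sample sizes
use Geyer's initial monotone sequence estimator; a warning is raised below
400. Quadrature and MCMC exceedances agree within 0.02 across a 3 x 3 grid
of data configurations (typically within 0.005).

### Two-stage design, calibration, probability of success

The published design enrols 11 colon / 8 rectum patients in stage 1 and
continues to 28 / 16 if more than 2 of 11 colon *and* more than 3 of 8
rectum patients achieve pCR. The continuation rule is implemented literally
as that joint AND (`continuation: joint`); a per-cohort variant
(`per_cohort`) is provided as a sensitivity switch. Final per-cohort success
is exceedance above a threshold gamma_j on the completed data.

*Calibration* simulates the design under the all-null scenario (3%, 10%) and
takes the smallest gamma on {0.50, 0.51, ..., 0.99} whose per-cohort success
rate is at most alpha = 5%, scoring one common batch of simulated trials
against every grid value. Simulation uses per-patient uniforms, so success
is monotone in the true rates under common random numbers. Under the
literal joint rule the null trial almost never continues (probability about
1.7e-5 = P(X>=3 | 11, 0.03) x P(X>=4 | 8, 0.10)), so the null success rate
is ~0 at every gamma and calibration returns 0.50 for both cohorts: the
printed stage-1 bars, not the posterior threshold, carry essentially all of
the type-I control. The calibrated type-I error verified on a fresh seed is
~0 per cohort, comfortably below 5%.

*Power cannot be reproduced as published.* Under the design alternative
(15%, 35%), the literal joint rule continues with probability
P(X>=3 | 11, 0.15) x P(X>=4 | 8, 0.35) ~ 0.20 — the colon factor alone is
0.221 — so no final criterion can reach the published 80% power from this
reconstruction; the governing supplementary model is unavailable. The
package reports the honest operating characteristics of the literal rule
(joint success ~6% under the alternative) and certifies its machinery by
exactly checkable properties instead: enumeration coverage of the exact
interval, quadrature-vs-MCMC agreement, the conjugate diffuse limit,
monotonicity of success in the true rates, and exact-interval parameter
recovery on synthetic cohorts.

*Probability of success* is posterior-predictive: given the observed stage-1
data (8/14 colon, 6/8 rectum — the actual enrolment, which overran the
planned 11 colon), response rates are sampled from the hierarchical
posterior (MCMC draws), stage-2 outcomes are drawn for the remaining planned
enrolment (14 colon, 8 rectum), and the calibrated final criterion is scored
per replicate; trial success means both cohorts succeed (per-cohort values
are also emitted, since the publication does not define the joint rule).
With both observed rates a multiple of their controls the result is
indistinguishable from 1 at 10,000 replicates, consistent with the published
"more than 99%". This conclusion is robust to the prior reconstruction:
every reasonable prior puts the exceedances far beyond any gamma on the
grid. The 80% power figure is the one quantity that is *not* robust to the
reconstruction, and it is left unreproduced rather than tuned.

Randomness policy: every stochastic routine takes an explicit seed; a single
seed expands through `numpy.random.SeedSequence` into independent
per-component streams, and every stochastic result object carries its seed,
replicate count and Monte-Carlo standard error.

## Synthetic data generator

The generator emulates the structure of the patient table, not any
particular patient: per-cohort Bernoulli pCR at the design rates (defaults
0.15 colon / 0.35 rectum at the observed enrolment of 14 / 8), a
triplet-vs-monotherapy regimen mix (probability 0.5), pre-operative cycles
uniform on 3-12, log-normal times to surgery with medians matched to the
fixture (2.7 / 6.0 months), follow-up uniform on 8-34 months, and
exponential event-free-survival events at 0.003 per month (about the
fixture's observed rate of one event in ~380 person-months), censored at
follow-up.

The rate parameter is defined as the FAS pCR rate: a generated responder is
always operated with TRG 0, so the derived count x/n is exactly binomial in
the parameter and the Clopper-Pearson recovery harness inherits the exact
coverage guarantee (the recovery test requires >= 93% empirical coverage
over 200 replicates, leaving room for replicate noise on a >= 95% truth).
Watch-and-wait behaviour is drawn among non-responders (18% by default),
mirroring how such patients enter the FAS denominator without pathology.
Residual-disease TRG for operated non-responders is uniform on {1, 2, 3}
(the publication offers only a single observed split, 8/2/1/1 in the colon
FAS, as evidence). Radiological response is never generated — it is out of
scope throughout the package. What passing recovery tests show is that the
analysis pipeline is correct for data with this binomial-plus-censoring
structure; they say nothing about, e.g., correlated response and surgery
decisions, accrual over calendar time, or measurement error in TRG grading,
none of which the generator models.

## Numerical and degenerate-input conventions

Ties between events and censorings at the same time are handled
events-first. A Kaplan-Meier quantile the curve never reaches is returned as
an absent value, not an error. `survival_at(t=0)` returns the degenerate
interval [1, 1]; upper confidence bounds are clipped at 1 and lower at 0.
Interval methods reject x > n, n = 0 and confidence levels outside (0, 1).
The loader collects *all* validation problems (row, patient id, field)
before failing, so a malformed table reports every issue at once. Posterior
mass that underflows to zero (degenerate prior scales) raises rather than
returning silent zeros.

## Problem sizes

Default replicate counts are 10,000 for calibration, operating
characteristics and probability of success (Monte-Carlo standard error below
0.5 percentage points for probabilities near 5%), with the seed-stability
check run at 50,000. Posterior evaluations inside the simulators are
memoized by data configuration, which reduces tens of thousands of
simulated trials to at most a few hundred deterministic quadrature calls.

## Known limitations

* The hierarchical prior, the gamma grid and the joint-success definition
  are reconstructions of an unavailable supplementary specification; all
  headline checks except the power figure are insensitive to this.
* The published-cutoff survival reconstruction encodes only what the
  published estimate implies (all event-free patients at risk at 12 months);
  per-patient follow-up at the true cutoff is unknown, so estimates beyond
  the last snapshot time inherit the snapshot's censoring pattern.
* The data model permits exactly two cohorts wherever the design layer is
  involved; nothing is tested beyond two.
* Radiological endpoints (RECIST reading, per-patient best response) and
  safety tabulations are out of scope.
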