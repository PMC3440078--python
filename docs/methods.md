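# Methods

This note documents the model, the algorithmic choices behind it, and what
the synthetic-data experiments do and do not demonstrate.

## Observation model and additive predictor

Counts $Y_{st}$ (district $s = 1..S$, day $t = 1..T$) are conditionally
Poisson with mean $\mu_{st}$ and

$$\log \mu_{st} = \alpha + \delta\,\mathrm{DOW}_t + \beta\,\mathrm{DSI}_t
+ \gamma \mathrm{PM}_t + f(\mathrm{TP}_t) + f(T_t) + u_s + \eta_s
+ \log \mathrm{pop}_s.$$

Assumptions worth making explicit:

- a single monitoring station supplies PM₁₀ and temperature, so all
  environmental covariates vary by day only;
- PM₁₀ enters linearly at lag 0, in µg/m³ (effects are reported per
  10 µg/m³ at summary time, not rescaled inside the model);
- the population offset is time-constant over the study period — a known
  simplification for an 11-year window;
- counts are conditionally independent across district-days given the
  predictor.

### Exposure windows

Dust-storm episodes are inclusive date intervals.  Pre-ADS days are the 7
calendar days before an episode's first day; post-ADS days the 7 calendar
days after its last day.  "Days" are calendar days including weekends: the
window is defined by length, not by working days.  When the post-window of
one episode intersects the pre-window of the next (episodes < 15 days
apart), the intersection is relabelled EVENT; chains of close episodes are
handled pairwise left-to-right.  Precedence is EVENT > POST > PRE > OTHER,
so a day inside an episode is never anything but EVENT.  Windows reaching
beyond the study calendar are truncated with a logged warning — the
boundary behaviour (e.g. an episode on the first study day) is this
package's choice, since nothing forces any particular treatment.

### Smooth terms

$f(\mathrm{TP})$ and $f(T)$ are P-splines: cubic B-spline bases on
equidistant knots spanning the covariate range, penalized by the
second-difference (RW2) matrix $K = D_2^\top D_2$.  $K$ has rank $m-2$ and
annihilates constant and linear coefficient vectors, so as the smoothing
variance shrinks the fit collapses onto a straight line; this supplies the
"natural" linear boundary behaviour without explicit natural-spline
constraints.  Defaults: $m = 10$ basis functions for temperature, $m = 20$
for calendar time (roughly two per study year).  No knot counts are
dictated by the problem; both are constructor parameters.  Each smooth is
centred (its fitted mean over study days is absorbed into the intercept)
to keep $\alpha$ identifiable — the basis rows sum to one, so the centring
is an exact coefficient shift that leaves the RW2 prior invariant.

### Spatial effects

$u_s \sim N(0, \sigma^2_u)$ i.i.d.; $\eta$ carries the intrinsic CAR
(Gaussian Markov random field) prior with density
$\propto \exp(-\eta^\top Q \eta / 2\sigma^2_s)$, $Q$ the adjacency-graph
Laplacian.  The full conditional of $\eta_s$ is normal with mean the
neighbour average and variance $\sigma^2_s/N_s$.  The intrinsic prior is
improper; a sum-to-zero constraint on $\eta$ is re-applied after every
sweep, with the removed mean absorbed into $\alpha$.  Isolated districts
are rejected at input validation ($N_s = 0$ leaves the conditional
variance undefined).

### Overdispersion

The model offers $\mathrm{Var}(Y_{st}) = \phi_s \mu_{st}$ through
observation-level multiplicative gamma effects with fixed shape $\nu$
(Poisson-gamma mixing, conjugate latent updates), giving
$\mathrm{Var} = \mu(1 + \mu/\nu)$.  The default is the plain Poisson
likelihood (`dispersion_nu=None`); per-district Pearson dispersion
estimates $\hat\phi_s$ are always computed at the posterior-mean fit so
that unmodelled overdispersion is visible either way.

## Posterior computation

Metropolis-within-Gibbs over blocks, per sweep: fixed effects (intercept,
6 DOW, 3 DSI, PM₁₀), temperature-spline coefficients, time-spline
coefficients, $\eta$, $u$, then all variances.  Fixed effects carry a
diffuse $N(0, 10^6)$ prior so every proposal precision is proper.

**Block proposals.** Each Gaussian block uses an IWLS proposal: the Poisson
log-likelihood is expanded to second order, giving working weights
$\mu$ and precision $X^\top W X + P_0$.  The IWLS step is iterated to
convergence — i.e. to the mode of the block's full conditional — and the
proposal is the Gaussian with that mean and the working precision there.
Because the mode is a deterministic function of the conditioning state,
forward and reverse proposal distributions coincide and the Hastings
correction reduces to density ratios under a single Gaussian; the
accept/reject step keeps the exact posterior stationary.  A single
(non-iterated) IWLS step anchored at the current value was tried first and
rejected: at realistic counts (hundreds to thousands per district-day) the
conditional is so concentrated that a proposal launched far from the mode
is essentially never accepted — the calendar-time spline block froze at 0%
acceptance.  With mode-centred proposals, acceptance rates sit near 1,
which reflects the quality of the Gaussian approximation at these counts,
not a tuning defect; tests treat any rate in (0.1, 1] as healthy.

**Initialization.** Before sampling, four IWLS backfitting sweeps put every
block at its conditional mode and set variances to conditional posterior
means.  This matters for the same reason as above: an exact MH step from a
grossly implausible state (all coefficients zero) rejects almost surely,
and a block stuck at zero drags its variance to zero through the conjugate
update — a self-reinforcing trap observed with the unstructured spatial
block before initialization was added.

**Block order and the spatial decomposition.** $u$ and $\eta$ enter the
likelihood only through their sum, so the likelihood cannot apportion
variance between them; the split is prior-driven and mixes very slowly.
Whichever district block updates first absorbs the spatial signal during
initialization and keeps it.  The structured block $\eta$ is therefore
updated (and initialized) before $u$: on synthetic data generated with a
structured share of 98.4%, this ordering recovers $\rho \approx 99\%$,
whereas the reverse ordering mis-attributes the signal and returns
$\rho \approx 7\%$.  The reported decomposition should be read with this
weak identifiability in mind — as in any intrinsic-CAR-plus-exchangeable
(Besag-York-Mollié type) model with a handful of areas.

**Variances.** Conjugate draws from
$\mathrm{IG}(a + r/2,\; b + \tfrac12\theta^\top K\theta)$ with
$a = b = 0.001$ and $r$ the structure-matrix rank ($m-2$ for RW2 penalties,
$S$ for the identity, $S-1$ for the Laplacian).

**Schedule.** Default 22,000 iterations, 2,000 burn-in, thinning 20 →
1,000 retained draws.  One chain; the log posterior is recorded at every
retained draw and must be finite, and draws are bit-reproducible given the
seed (single PCG64 stream; default seed 20120315).

**Numerical guards.** Linear predictors beyond ±80 mark a proposal
non-finite (rejected with a warning); Cholesky failure of a proposal
precision likewise rejects; mode-finding caps at 50 Newton steps with a
relative tolerance of 1e-9.  A non-finite log posterior at a retained draw
aborts the run with a diagnostic dump rather than storing garbage.

## Posterior summaries

Percent changes are $100(e^b - 1)$ with the point estimate computed from
the posterior mean of the coefficient, then transformed (the usual
reporting convention for log-linear models); interval bounds transform the
2.5th/97.5th posterior quantiles.  Significance means the 95% interval
excludes zero on the coefficient scale.  District relative rates
$RR_s = e^{\eta_s}$ are classified LOW/HIGH when at least 80% of posterior
mass falls strictly below/above 1, else NEUTRAL; draws exactly equal to 1
count toward neither tail.  The variance share is
$\rho = 100\,\sigma^2_s/(\sigma^2_u + \sigma^2_s)$, computed at the
posterior means of the variance components.  Rounding to two decimals
happens only at report time.

## Synthetic-data generator

The generator inverts the model with known truth.  Defaults emulate the
study conditions:

- 12 districts with approximate Taipei populations (110k–315k) and the
  bundled adjacency graph; counts in the hundreds to low thousands per
  district-day (baseline rate 0.005 visits/person/day);
- 4–5 dust-storm episodes per calendar year, 1–6 days long, concentrated
  in winter and spring, non-overlapping;
- temperature as an annual sinusoid (mean 23 °C, amplitude 7 °C, coldest
  late January, Gaussian noise sd 1.5 °C); PM₁₀ lognormal (median
  45 µg/m³, log-sd 0.35), multiplied by 2.6 on episode days so event-day
  means clear 100 µg/m³;
- day-of-week log-effects of 0.40–0.55 versus Sunday (clinics largely
  closed Sundays);
- exposure-window effects of −2.97% (event), +3.38% (post), +0.45% (other)
  and +1.18% per 10 µg/m³ of PM₁₀ — the magnitudes reported for all
  children combined, used as generator settings, not as reproduction
  claims;
- a smooth nonlinear temperature response (positive cold, negative warm)
  and a slow multi-year trend, both centred;
- spatial effects drawn from the priors with $\sigma^2_u = 0.0019$,
  $\sigma^2_s = 0.1184$.

Default size is 12 districts × 730 days; the full 4,017-day calendar is a
flag away.  The two-year default keeps a complete simulate → fit →
summarize round trip to a few minutes on one CPU, which is also the
problem size used by the test suite and the acceptance script.

What the generator does **not** emulate: insurance-claim microdata and
ICD coding, holidays and epidemic outbreaks, day-to-day autocorrelation in
PM₁₀ beyond episode elevation, multi-station exposure gradients,
population change over the decade, and reporting artefacts.  Passing
recovery tests therefore show that the estimator inverts its own model
correctly at realistic dimensions and magnitudes — they do not show that
the model is correctly specified for real claims data.

## Known limitations

- The $u/\eta$ split (hence $\rho$) is weakly identified; see above.
- The intrinsic CAR is improper and the sum-to-zero constraint is a
  modelling choice; relative rates are interpretable only against the
  city-wide mean.
- Fixed $\nu$ overdispersion is a coarse stand-in for freely varying
  per-district $\phi_s$; $\hat\phi_s$ diagnostics flag misfit but the
  likelihood does not adapt to it.
- One chain by default; trace export and `arviz` conversion are provided
  for convergence checking, but no automated multi-chain diagnostics.
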