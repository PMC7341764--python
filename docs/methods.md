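# Methods

`heightmort` estimates and decomposes height-stratified tree mortality
during a drought, for the situation where a pooled mortality-versus-height
trend may be an artifact of height-related changes in taxonomic
composition rather than of intrinsic tall-tree vulnerability. This note
records the models, the defaults and why they were chosen, what the
synthetic data do and do not emulate, and the package's known limitations.

## The decomposition

For height class *i* and taxonomic groups *t* = 1..x (x ≥ 2), with
*n<sub>i,t</sub>* trees alive at the start of the accounting window and
*d<sub>i,t</sub>* of them dead by its end, pooled fractional mortality is

    M_i = (Σ_t d_{i,t}) / (Σ_t n_{i,t}) = Σ_t m_{i,t} · p_{i,t},

with *m<sub>i,t</sub>* = d/n the group mortality and *p<sub>i,t</sub>* =
n<sub>i,t</sub>/Σn the group's share of the class (Σ<sub>t</sub> p = 1).
Because M<sub>i</sub> is a convex combination, a pooled trend across
height classes can oppose every group's own trend when the p's shift with
height — Simpson's paradox. Two direct standardizations isolate the
mechanism:

* **constant composition** — recompute M<sub>i</sub> with a single
  reference proportion vector (the population as a whole, from
  start-of-window populations) in every class, keeping each class's
  actual m's;
* **constant group mortality** — keep actual compositions but pin one
  focal group's mortality at its pooled (all-heights) value.

All decomposition inputs are real-valued; back-calculated populations
(below) are non-integer by construction. Monotonicity classification uses
strict comparisons with a 1e-9 float tolerance.

## Height classes from diameter

Trees are recorded in 5-cm DBH classes (breast height 1.37 m). Height
classes (5–15 m, 15–30 m, >30 m) come from species-specific
height–diameter curves; the default is a Chapman–Richards form
`H = 1.37 + A(1 − e^{−k·d})^c`, with a linear toy form for closed-form
checks. Class thresholds invert the curve at 5/15/30 m (bracketing to
0.01 cm) and round to the nearest 5-cm class, ties up. A class above a
species' asymptote is marked unreachable. Conventions the data do not
dictate, chosen once and tested: the DBH class label is the bin's lower
edge, and a label at or above a threshold belongs to the taller class.
Trees below the 5-m class are excluded from all mortality analyses.
Near-threshold stems can be misbinned by quantization — mismatches are
confined to within 2.5 cm of the continuous threshold (the rounding
half-width), but the share of stems in those bands depends on the stand's
DBH distribution, so no fixed misassignment rate is guaranteed.

## Dating death from snag condition

Each standing dead tree carries an ordinal retention class (1 = freshest
foliage/fine-twig condition). From a calibration set of snags with known
death years, the package fits a gamma distribution of time-since-death
for every (calibration group × retention class) cell. Time-since-death
uses a mid-year convention: a death in calendar year *y* observed at
survey year *s* is *t* = *s* − *y* + 0.5. Rare species borrow a similar
taxon's calibration (firs and other uncommon conifers → *Abies
concolor*; *Pinus jeffreyi* → the combined *P. ponderosa* +
*P. lambertiana* sample; angiosperms → *Quercus kelloggii*). Cells with
fewer than 3 calibration trees, or with degenerate all-identical times,
borrow the group's pooled fit and are flagged.

Fits are maximum-likelihood (the test oracle) or Bayesian: random-walk
Metropolis on (log shape, log mean) — a near-orthogonal parameterization
that mixes well even for narrow time distributions — with wide
(sd 10) normal priors on the log parameters, three chains, and
Gelman–Rubin checks. For a window [2014, 2016] surveyed in 2016, a snag
died in-window iff *t* ≤ T* = 3 years, so its window probability is
q = GammaCDF(T*); Bayesian fits average the CDF over the posterior draws.

## Mortality model

Per (group × height class) cell: living trees observed in the survey year
are survivors; each dead tree carries its dating probability q. A latent
indicator z<sub>j</sub> marks whether snag *j* died in-window (then it
belongs to the start-of-window cohort and counts as a death) or earlier
(then it is outside the cohort). Given z, the cohort is L + Σz with Σz
deaths and a binomial likelihood in the cell's mortality m, parameterized
on the logit scale.

The sampler is Metropolis-within-Gibbs (three unthinned chains of 20,000
iterations, 5,000 burn-in by default; proposal scales adapt only during
burn-in; chains independently seeded). Two z-update schemes are provided:

* **conditional** (joint Bayes): z is drawn from its full conditional
  P(z=1) = q·m/(q·m + 1 − q), so the m-marginal is
  prior(m)·(1−m)^L·Π(q<sub>j</sub>m + 1 − q<sub>j</sub>) — exactly the
  closed-form beta-mixture oracle the tests compare against.
* **imputation**: z is redrawn from its prior Bernoulli(q) each
  iteration, mixing complete-data posteriors over dating uncertainty.

The schemes coincide when every q is 0 or 1. They differ materially when
q is interior: the joint scheme lets a cell's own low mortality argue
uncertain snags back out of the window, which is coherent under its prior
but systematically understates mortality when q is an already-calibrated
external estimate (in the synthetic world, a true-mortality-0.04 cell is
pulled to ~0.006). The pipeline therefore estimates with the imputation
scheme, which keeps point estimates unbiased under calibrated q while
still widening credible intervals for dating uncertainty; the conditional
scheme remains the library default for its exact closed-form oracle.

Two priors on logit m: **uniform on m** (standard-logistic on the logit;
makes the all-certain-q posterior exactly Beta(D+1, L+1)) and a
**diffuse normal** (sd 10), which is nearly flat on the logit scale and
so behaves like a Beta(D, L) — in particular a cell with zero observed
deaths keeps essentially all posterior mass at ~0 mortality. The
pipeline default is the normal prior, so a zero-death cell reports ~0
rather than a +1-pseudo-count-inflated mean that would distort the
standardized counterfactual through small cells.

Summaries report the posterior mean, central 95% interval, the classic
Gelman–Rubin R̂ (floor √((n−1)/n)), and a Geyer initial-positive-sequence
effective sample size (cells under 400 effective draws are flagged).
Start-of-window populations and deaths are back-calculated as
n₂₀₁₃ = n₂₀₁₆/(1 − m) and d = n₂₀₁₃ − n₂₀₁₆, per posterior draw for the
pooled-mortality credible band and at the posterior mean for the tables.

## Synthetic data: what it emulates, and what it does not

The default configuration generates ≈89 plots × 66 trees (≈5,900 stems
≥5 m, near the study scale), three groups whose shares shift from
angiosperm-heavy short classes (57/35/8%) through to conifer/pine-heavy
tall classes (6/72/22%), and group × height mortalities of
(0.08, 0.04, 0.01) for angiosperms, (0.26, 0.21, 0.17) for other
conifers, and (0.17, 0.35, 0.56) for pines — low/declining,
intermediate/declining, high/rising, with pines ≈11% of stems. Height
class marginals (0.50/0.35/0.15) and a 4% sub-5-m fraction are
realistic old-growth size-structure choices. Trees are generated
height-class-first and assigned a DBH by inverting the species curve
(truncated lognormal within the class interval, floored to 5-cm bins), so
the analysis side must re-derive classes from diameter alone.

Death years in the window are uniform over 2014–2016; pre-window snags
are added per cell at 30% of standing dead (Poisson), with death years
uniform over the preceding 12 years. Snag decay is conditioned on a
continuous elapsed time (death year ± half a year), and retention classes
follow an ordered-logit model with cutpoints (1, 3, 6, 12) years and
logistic scale 0.75 (scale 0 gives a deterministic step that separates
in-window from pre-window deaths exactly). The calibration set (default
2,297 snags) is drawn from the same death-year mixture as the surveyed
snag population — the condition under which class-conditional gamma fits
yield calibrated window probabilities, which is also the implicit
assumption of the field method.

Not emulated: spatial structure (plots are exchangeable; the mortality
model has no plot term), tree growth, beetle dynamics, species-level
mortality heterogeneity within groups, and measurement error in species
or condition. Passing tests therefore demonstrate the statistical
machinery under the stated generating process, not robustness to those
real-data features.

The parameter-recovery benchmark builds independent cells (500 trees,
true mortality uniform in [0.02, 0.6], 30/70 old-snag mix) whose dead
trees carry *exactly calibrated* q's derived from a Gaussian condition
signal (±1 means, sd 0.35). The sd keeps most q near 0/1, matching the
method's premise that snag condition dates deaths reliably; recovery
degrades as dating blurs (see limitations).

## Numerical choices

Gamma MLE via `scipy.stats.gamma.fit` with location fixed at 0;
degenerate all-identical samples raise. Threshold inversion by Brent
bracketing, xtol 0.01 cm; nearest-5 rounding with ties up. MCMC proposal
scales adapt in batches of 50 toward ~40% acceptance, frozen after
burn-in. All randomness flows from explicit `numpy` Generators;
per-chain streams are spawned from one seed, so runs are bit-reproducible
and chains are independent. Probability-vector sums are validated to
1e-12; empty height classes and zero-population groups raise rather than
propagate NaNs.

## Known limitations

* The plug-in q treats the dating calibration as external truth. If the
  calibration population's death-time distribution does not match the
  surveyed snags', q is miscalibrated and mortality biased; and even with
  calibrated q, the gamma family cannot follow the sharp edge a 3-year
  mortality pulse puts in the class-conditional time distributions, which
  leaves a few-percent downward bias in recovered deaths in the synthetic
  world.
* With blunt dating (many interior q's), the joint z-update scheme is
  substantially biased low in low-mortality cells, and even the
  imputation scheme's intervals are only as good as q. The recovery
  benchmark's sharp-dating default reflects the method's premise, not a
  guarantee about degraded field classifications.
* The back-calculation n₂₀₁₃ = n₂₀₁₆/(1 − m) assumes all window deaths
  remain standing and detectable at survey.
* The saturated cell-means model shares no information across cells; tiny
  cells (e.g. tall angiosperms) have wide, prior-sensitive posteriors.
* The mid→tall step of the composition-standardized counterfactual is
  small relative to its sampling noise at the study's sample size, so
  only the short-versus-tall contrast is a stable qualitative signature
  of the estimated counterfactual; the full monotone decline is stable in
  the generator's exact (truth-level) decomposition.
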