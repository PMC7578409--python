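# Methods

This note documents the models, numerical choices and limitations of
`fptargets`: a desk-scale pipeline that converts demand-satisfied (DS)
goals for family planning into modern-contraceptive-prevalence (mCPR)
targets via the accelerated transition (AT) method, with a demand-based
(DB) comparator.

## Indicators and units

All quantities refer to married/in-union women of reproductive age
(MWRA, 15–49).  A country-year state is (modern prevalence, traditional
prevalence, unmet need), each a proportion, non-negative, summing to at
most 1 (tolerance 1e-9 for floating-point accumulation).  Total demand
is the sum of the three; demand satisfied is modern prevalence divided
by total demand, defined as 0 at zero demand (a documented convention —
zero demand never occurs on a projected trajectory with positive
prevalence).  Everything internal is a proportion in [0, 1]; files and
reports use percent, converted exactly once at the I/O boundary.

## The transition model

The projection engine is a deliberately simple stand-in for a full
Bayesian multi-country estimation model.  It is deterministic,
single-country, and designed so that the AT method — which is agnostic
to how the BAU trajectory is produced — can be exercised and tested
end to end.

Three curves with seven parameters:

* **Total prevalence** `P(t) = P_max / (1 + exp(−ω (t − Ω)))` — a
  logistic in calendar time: a gradual start, a rapid middle, and a
  slow-down as prevalence approaches its ceiling.  `P_max ∈ (0, 0.95]`
  (default shrinkage centre 0.85), `ω ∈ (0, 1]` per year (centre
  0.07/yr, a typical transition pace), `Ω` the midpoint year.
* **Modern share** `s(t) = expit(a_s + b_s (t − Ω))` — the modern
  fraction of all use, logistic in time and centred on the same
  midpoint.  Modern prevalence is `s·P`, traditional is `(1−s)·P`.
* **Unmet need** `U(t) = (1 − P) · expit(a_u + b_u P)` — a fraction of
  non-users whose log-odds are linear in prevalence.  This form
  structurally guarantees `P + U ≤ 1`, and with `b_u < 0` reproduces
  the empirical pattern of unmet need shrinking as the transition
  completes.

By construction every evaluated state satisfies the indicator
invariants: `0 ≤ modern ≤ P ≤ P_max` and `P + U ≤ 1`.

### Fitting

Observed quantities per survey: total prevalence, modern share of use,
and unmet need as a fraction of non-users.  The fit minimises the
weighted squared error of all three on the log-odds scale (proportions
clamped to [1e-6, 1−1e-6] before the transform), with weights
proportional to `1/obs_sd²` when every observation carries a sampling
SD and equal otherwise, plus quadratic penalties:

* `0.05 · (P_max − 0.85)²` and `0.05 · (ω − 0.07)²` — light shrinkage
  toward documented defaults.  For data-rich series these perturb the
  optimum by well under 1e-3 in relative terms (measured on noise-free
  eight-survey fits); for one- or two-survey countries they decide the
  otherwise-unidentified parameters, playing the role that hierarchical
  borrowing plays in a multi-country Bayesian fit.
* a ridge of weight 1e-6 on the two slope parameters, which keeps the
  single-observation problem fully determined (seven residuals, seven
  parameters).

The optimiser is SciPy's bounded trust-region reflective least-squares
solver with per-parameter scales (the midpoint lives on a calendar-year
scale, the rates near 0.05/yr), tight tolerances (1e-12) and a fixed,
documented starting point: penalty centres for `P_max` and `ω`, a line
fit of `logit(P_obs/0.85)` against year for the midpoint (degenerating,
for a single observation, to placing the default curve exactly through
that observation — which is then the analytic optimum), and line fits
of the corresponding log-odds for the share and unmet parameters.  No
multistart: the fit is bit-reproducible, at the documented cost that a
pathological series can settle in a local optimum.  Non-convergence
raises an error carrying the optimiser diagnostics; it is never
silently replaced by a fallback.

Identifiability caveat: for countries whose transition midpoint lies
beyond the survey era (the late-transition scenario), the asymptote and
midpoint are only weakly identified — many (P_max, Ω, ω) combinations
fit the observed early tail almost equally well.  Recovery of such
countries is therefore assessed on the fitted indicator curves inside
the observation window, not on raw parameters; the parameter-recovery
results below use a mid-transition truth whose rise is essentially
complete by 2019.

## The AT method

Given a BAU trajectory on an annual integer grid covering
[current_year, cap_year] (defaults 2019 and 2100) and a DS target
(default 0.75) for a goal year (default 2030):

1. **t\*** is the first grid year at or above the DS target.  If none
   exists by the cap year, `t* = cap_year` and the result is flagged
   `capped`.  The integer-grid, first-at-or-above convention is a
   choice; published assessments report integer years only, and the
   brute-force fine-grid crossing always lies in `(t*−1, t*]` for
   non-decreasing DS (property-tested).
2. **Relative acceleration** `(t* − current)/(goal − current)`,
   unrounded internally; the reporting layer rounds to one decimal,
   half away from zero.  It equals 1 exactly when `t* = goal`, and a
   country is on track iff it is ≤ 1.
3. **Target mCPR** is the BAU mCPR at `t*`; for capped countries this
   is the cap-year projection — a deliberately attainable compromise
   rather than the (never-reached) DS-consistent level.
4. **Gaps.**  mCPR gap = target − current mCPR; users gap = gap ×
   MWRA.  On-track countries report both gaps as 0 with an explicit
   flag rather than printing negative gaps.
5. **Accelerated trajectory.**  Between current and goal year the
   accelerated state at `t` is the BAU state at
   `current + rel_accel · (t − current)` (linear interpolation between
   grid years), so the goal-year state equals the BAU state at `t*`
   *exactly* on grid points — DS reaches the target precisely on time,
   and every accelerated state lies on the (piecewise-linear) BAU
   path, preserving the joint evolution of mCPR and demand.  Beyond
   the goal year the path continues as BAU shifted by `t* − goal`
   (the published construction ends at the goal year; the continuation
   is this package's documented extension).  `t* = goal` is the
   identity rescaling and returns BAU; earlier `t*` is an error.

## The DB comparator

`tmod_DB = ds_target × BAU demand at the goal year`, with the gap taken
against the same current-year mCPR baseline as the AT gap so that
differences isolate the target definition.  For any country with
non-decreasing demand that *attains* the DS target at `t* > goal`,

    tmod_AT = DS(t*)·demand(t*) ≥ ds_target·demand(goal) = tmod_DB,

so AT dominance over DB is a theorem under those hypotheses, and is
tested as such.  It does **not** extend to capped countries: their AT
target is the (lower) cap-year mCPR while the DB formula keeps scaling
the goal-year demand, so a high-unmet-need capped country can show a DB
target above its AT target.  With constant demand the two targets
coincide exactly.

## Synthetic data

The generator emulates the survey record such assessments are fitted
to: by default eight survey rounds per country at distinct years in
[1968, 2019], observed with sampling noise, on a known transition.

* **Noise.**  Each observed quantity (total prevalence, modern share,
  unmet fraction of non-users) gets independent Gaussian noise on the
  log-odds scale, sized like binomial sampling error with a fixed
  effective sample size: `noise_sd` (default 0.02) is the
  proportion-scale SD at prevalence 0.5, equivalent to an effective n
  of `1/(4·noise_sd²)` = 625 — survey-scale uncertainty after design
  effects.  The log-odds SD `2·noise_sd/√(q(1−q))` is capped at 1.5 so
  near-zero proportions stay near zero under noise, as in real
  surveys.  Components reconstructed from the noisy quantities always
  form a valid state, verified at extreme noise.
* **Scenarios.**  Truth parameters are drawn uniformly from documented
  boxes per class: `on_track` (DS target already met in the current
  year), `late` (crossing strictly between goal and cap year) and
  `capped` (modern share — an upper bound on DS — stays below the
  target through the cap year).  The box bounds guarantee the class
  property at every corner, and the test suite re-checks it on draws.
  The `mixed` preset mixes classes 18:47:3 — the observed split of the
  68 assessed countries — and pins the first three countries to one
  class each so all classes are non-empty.
* **Randomness.**  NumPy `default_rng` (PCG64) throughout; panels and
  observation sets are bit-reproducible given their seeds.

What passing synthetic tests do *not* show: the generator draws from
the model family the fitter assumes, with independent noise and no
source-specific biases, no sample-population differences, and no
real-world distortions from the expected trend.  Recovery results are
therefore a correctness check of the pipeline, not evidence about the
accuracy of any real-country projection.

## Problem sizes and measured behaviour

The test suite runs panels of 10–68 synthetic countries and a
200-replicate recovery study (n = 8 surveys, noise 0.02), which
completes in a few seconds in total.  Under those conditions the median
absolute error of the prevalence asymptote is ≈ 0.015 (criterion:
< 0.05), and noise-free eight-survey fits recover every parameter of
the mid-transition truth within 1e-3 relative error.  The published
50-country table reproduces its acceleration column exactly from the
printed target years, and its headline counts (50 accelerating, 35 at
factor ≥ 3, gaps 4.3–50.8 pp) by direct summary.

## Known limitations

* The transition model is a single-country simplification: no
  hierarchical borrowing across countries, no time-series distortions,
  no data-source or sample-population bias terms, and no uncertainty
  intervals on the core path (a parametric bootstrap helper provides a
  rough spread).  Equivalence with full Bayesian estimates for real
  countries is not claimed, and the published country-specific targets
  are shipped as printed inputs, not recomputed.
* Long-horizon projections (t\* decades beyond the last survey) are
  extrapolations of a fitted logistic; their parameters are weakly
  identified from pre-transition data.
* The unmet-need curve ties unmet need to prevalence only; period
  effects (e.g. supply shocks) are out of scope.
* All-women (unmarried) denominators and age-disaggregated variants are
  out of scope.
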