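# Methods

## The kinetic model

Serial radiographic tumor burden — the RECIST sum of target-lesion diameters
(SOD) — is normalized to its baseline value, so every subject's trajectory
starts at f(0) = 1 and time t is measured in days from the baseline scan.
Two simultaneous first-order processes act on the burden: exponential
regression (decay) of treatment-sensitive disease at rate d per day and
exponential growth or regrowth of resistant disease at rate g per day.  Four
candidate models cover the shapes seen in treated patients:

| class  | f(t)                              | parameters | interpretation              |
|--------|-----------------------------------|------------|-----------------------------|
| dx     | e^(−dt)                           | d          | regression only             |
| gx     | e^(gt)                            | g          | growth only                 |
| gd     | e^(−dt) + e^(gt) − 1              | g, d       | additive decay + regrowth   |
| gdphi  | φ·e^(−dt) + (1−φ)·e^(gt)          | g, d, φ    | sensitive fraction φ decays, resistant fraction regrows; fits a prolonged nadir |

The fitted g is the *g-score*.  Decay-only (dx) subjects have, by convention,
a g-score of exactly 0 — growth was not detectable in the data collected.
The g-score maps to a tumor doubling time TDT = ln(2)/g (defined only for
g > 0).  The additive and convex-mixture families are distinct
parameterizations and are never interconverted.

## Per-subject fitting and classification

Each trajectory is fitted to every candidate whose parameter count does not
exceed its number of post-baseline points; the baseline point is structural
(its residual is identically zero after normalization) and contributes no
residual.  Fitting is bounded nonlinear least squares on the normalized
burden scale (g, d ≥ 0; φ in [0, 1]) with a multi-start grid
(g, d ∈ {1e-4, 1e-3, 1e-2}/day; φ ∈ {0.2, 0.5, 0.8}); starts are screened by
initial residual sum and only the best few are polished, best RSS wins.
Log-scale residuals are a configuration option, as is AICc.

A candidate is *admissible* when every one of its parameters is retained at
p < 0.1; among admissible candidates the smallest AIC
(AIC = n·ln(RSS/n) + 2k, n = post-baseline points, k = parameters; ties
within 1e-9 resolve toward fewer parameters) is selected.  A subject with no
admissible candidate is `not_fit`.  A subject with exactly one post-baseline
assessment that changed less than 20% from baseline (the RECIST progression
threshold for a single scan) is excluded as `single_scan_small_change`; with
a ≥ 20% change the single scan supports a pure growth or pure decay fit.

Statistical conventions (several are not determined by the model equations;
they are fixed here and were chosen once):

- **Wald tests with a normal reference.**  Standard errors come from the
  Gauss–Newton covariance RSS/(n−k)·(JᵀJ)⁻¹ and parameters are referred to
  the normal distribution (two-sided, against 0; φ uses the same convention
  for uniformity).  A t reference on n−k degrees of freedom was considered
  and rejected: with the 1–2 residual df typical of interim looks it makes
  nearly every short trajectory unclassifiable, which contradicts the way
  interim g analyses behave on few scans.
- **No truncated pseudo-inverse.**  When JᵀJ is numerically singular
  (condition number > 1e12) the covariance is set to infinity rather than
  pseudo-inverted.  This matters in the gdphi corner φ → 1, where g is
  unidentified: a truncating pinv reports spuriously tiny errors there and
  floods the fast quartile with phantom growth rates.
- **Saturated fits carry no evidence.**  A k-parameter model fitted to
  exactly k ≥ 2 points interpolates any data (RSS ≈ 0) and its parameters
  are treated as unsupported (p = 1).  The single-scan path (n = k = 1) is
  the sanctioned exception: there "detected" simply means the rate is
  nonzero, and the 20% gate screens noise when enabled.
- **Exact fits of overdetermined models** (RSS < 1e-16, n > k) retain
  interior parameters (p = 0) and reject parameters pinned at 0 — this is
  what reduces gd to gx/dx on noise-free data.  Inside the AIC the RSS is
  floored at 1e-24 so that exactly-fitting models of different sizes are
  still ordered by the 2k penalty.
- **Degenerate measurements.**  A 0 mm SOD (target lesions resolved) is
  floored at half the smallest positive measurement of that subject and the
  subject is flagged; relative-burden machinery is undefined at zero.

## Cohort-level analyses

- **Arm comparison**: median and IQR of g over subjects fit to a model (dx
  contributes g = 0), two-sided Mann–Whitney.  Reports render g in the
  ×10⁻² /day display convention and TDT in units of 100 days.
- **Quartiles**: cutpoints are the 25/50/75th percentiles of g over subjects
  with g > 0 pooled across both arms; dx subjects form their own "no growth"
  stratum.  Values at a cutpoint go to the lower quartile.  The alternative
  convention (cutpoints over all modeled subjects including g = 0) is a
  flag, because the published stratum definitions are ambiguous on this
  point.
- **Survival**: Kaplan–Meier per stratum (median = first time the estimate
  drops to ≤ 0.5, not reached if it never does; 1-year rate = S(365)·100)
  and a stratum-indicator Cox model versus Q4 with Efron tie handling.  A
  stratum with zero events has an unbounded partial likelihood and is
  reported as HR 0.0 with CI (0, ∞) rather than dropped.
- **Concordance**: Harrell's C from Cox models among subjects with g > 0 —
  one with continuous g (log g optional), one with the categorical
  best-percent-change response (3-level responder ≤ −30% / progression ≥
  +20% / stable; binary coding optional).  Covariates are z-scored before
  the Cox fit (a monotone transform, so the rank statistic is unchanged) and
  a ridge penalty is escalated only if the unpenalized likelihood has no
  finite optimum; a constant predictor scores 0.5 by definition.
- **d-quartiles**: the identical machinery applied to the fitted decay rate
  over d > 0 subjects, as a negative-control analysis.
- **Early look**: the interim cut when the k-th randomized subject has been
  followed 14 weeks (98 days): each of the first k subjects keeps only scans
  acquired by that calendar date, g is refit from the truncated series
  (mirroring a real database cut rather than reusing full-data fits), and
  the arms are compared as above.
- No multiplicity adjustment anywhere; all p-values are reported unadjusted.

## The synthetic cohort generator

Patient-level trial data are not public, so the generator is the testbed; it
emulates a two-arm phase-3 trial with known ground truth.  Per subject: an
arm, a kinetic class from a per-arm mixture, parameters (lognormal g and d,
Beta(8, 2) φ), a 6-weekly scan schedule with ±7-day uniform jitter,
multiplicative lognormal measurement noise (sd 0.05; additive optional),
assessment stop at the first scan ≥ 20% above the running nadir
(RECIST-like progression-triggered stop), a 5% fraction truncated to a
single post-baseline scan, Poisson accrual at 5.2 subjects/week (optional
linear site-activation ramp), and exponential OS/PFS with log-hazard linear
in the subject's true g (PFS is the earlier of progression and death;
administrative censoring at 900 days).

Defaults encode the published second-line HER2+ trial conditions: arm sizes
245/232; class mixtures among evaluable subjects ≈ {dx .49, gd .44,
gdphi .05, gx .02} (experimental) and {dx .28, gd .41, gdphi .12, gx .19}
(control); grower g medians 7e-4 vs 1.8e-3 /day with log-sd 1.0 chosen to
match the printed grower IQRs.  Decay is arm-specific — d median 1.2e-2
(deep, fast regressions under the experimental ADC) vs 1.5e-3 /day (shallow
regressions under control, log-sd 0.5) — reflecting the large difference in
response depth between the two drugs; d is not printed in the source
tables, so its scale was calibrated once so that the simulated trial
reproduces the published qualitative findings (classification fractions,
arm ordering of g with p < 1e-4, detectability of the arm difference at the
60-subject interim look).  The survival link (log-hazard slopes 1400 for OS
and 1100 for PFS per unit g; baseline hazards 1.4e-4 and 8e-4 /day) is
deliberately strong so that the monotone quartile gradient is a
deterministic property of the generator at trial scale rather than
small-sample luck.

What the generator does *not* emulate: non-target and new lesions, reader
variability beyond i.i.d. multiplicative noise, informative censoring or
dropout tied to toxicity, scan schedules coupled to death, frailty beyond g
in the hazard, and any within-subject change of kinetics over time.  Tests
that pass on these cohorts therefore validate the estimation and analysis
machinery under the stated model, not the biological fidelity of that model
to any real trial.

## Validation design and problem sizes

- Model algebra: f(0) = 1 and the four reduction identities (gd→gx at d = 0,
  gd→dx at g = 0, gdphi→gx at φ = 0, gdphi→dx at φ = 1) over randomized
  parameter grids, tolerance 1e-12.
- Fitter vs oracle: bounded least squares matches a dense log-grid search on
  50 short trajectories (the optimizer's RSS never exceeds the best grid
  node's).
- Recovery: 500 trajectories per class on a fixed 8-assessment protocol
  schedule (no stop rules — the target is the fitter, not the censoring
  mechanics): median relative error of ĝ ≈ 3% (gx) and ≈ 8% (gd) at 5%
  noise; noise-free classification agreement 100%.  Noisy 4-class agreement
  is intrinsically limited (~60%): gd and gdphi are near-degenerate
  families, and a shallow decay is often indistinguishable from none.
- Trial-scale run at n = 245/232 and 100 interim-look replicates at
  n = 45/45; survival machinery checked against hand product-limit tables,
  brute-force partial-likelihood maximization (n = 8, distinct event times,
  where Breslow and Efron coincide) and exhaustive pair counting (n = 50).

## Known limitations

- The gd/gdphi families are weakly identified at realistic noise; class
  labels between them should not be over-interpreted, although the g-score
  itself transfers well.
- Wald retention with a normal reference is anti-conservative on very short
  trajectories; interim-look g-scores from 1–2 scans are noisy, and the
  package deliberately reproduces that behavior rather than hiding it.
- The per-arm Cox tables on small strata can be unstable (few events); the
  pooled-stratum tables are the primary output.
- The exponential survival model has no shape flexibility; it is a link for
  testing association machinery, not a survival model of record.
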