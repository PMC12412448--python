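# Methods

## The model

The package's core is a three-source variant of the two-high-threshold
source-monitoring model for a feedback-memory paradigm.  Statements are
studied with one of three feedback labels ("true", "false", "?") or are
new at test; test responses fall into the four categories
("true", "false", "?", "new"), where the first three imply an "old"
judgment.  One processing tree per plausibility (plausible/implausible) ×
item type (true-/false-/?-feedback, new) gives eight trees.

For a studied statement, detection succeeds with probability *D* (statement
memory).  Given detection, the feedback is retrieved with probability *d*
(feedback memory) and reproduced; otherwise the participant guesses whether
feedback was shown (*a*_fb) and, if so, whether it was "true" (*a*_true).
Undetected statements are guessed "old" with probability *b*; a guessed-old
response triggers the parallel guessing chain *g*_fb, *g*_true.  New
statements are detected as new with probability *D*_new, else enter the
same guessing chain.  All parameters carry a plausibility index (P/I) and,
for *D* and *d*, a feedback index.  This gives 24 parameters against 24
free response categories; the conventional baseline constraint
*D*_? = *D*_new within each plausibility condition leaves 22 free
parameters and a goodness-of-fit test with df = 2.

A note on that constraint: at random interior points the *unconstrained*
model is numerically locally identifiable (the 24-column Jacobian of cell
probabilities has full rank, with smallest singular values of order
1e-2…1e-4), but it is exactly saturated (df = 0) and poorly conditioned.
The baseline constraint buys a testable goodness-of-fit statistic and a
well-conditioned estimation problem; the package represents it as a
removable equality constraint rather than hard-coding it.

## Estimation

Frequencies are pooled over participants (complete pooling), matching the
aggregate-fitting convention of standard MPT tools; per-participant or
hierarchical fitting is out of scope.  The product-multinomial
log-likelihood kernel Σ *n* log *p* is maximised on logit-transformed
parameters (boundary-safe bijection of (0,1) onto the reals) with L-BFGS-B,
analytic gradients, and seeded uniform multi-start (20 starts by default
for user-facing fits).  Branches are compiled to index arrays once per
model, so one likelihood-plus-gradient evaluation is a handful of
vectorised operations; a full 22-parameter fit takes ~10 ms, which is what
makes the simulation studies below practical.

Goodness of fit is *G*² = 2 Σ *n* ln(*n*/*m̂*) with the conventions:
observed 0 contributes 0 regardless of the expectation; expected 0 with
observed > 0 yields +∞ (model rejected).  p-values use the central
χ²(df) upper tail.  For Δ*G*² tests of order-constrained parameters whose
estimate sits at the boundary (s = 1), the central χ² reference is known to
be conservative; the package follows the plain-χ² convention throughout.

Confidence intervals are Wald intervals on the probability scale from the
inverse observed information (numerical Hessian of the analytic gradient),
clipped to [0,1].  When the information matrix is singular or an estimate
lies within .01 of a boundary, a profile-likelihood interval (bisection on
the likelihood-ratio threshold, refitting nuisance parameters with warm
starts) is substituted and flagged per parameter.  In calibration runs at
study-like values the pooled empirical coverage of the 95% intervals is
≈ .95; individual parameters (notably the weakly identified *d*_? s) run a
point or two lower.

Nested tests share seed and start count between base and restricted fits,
and the restricted fit is additionally warm-started from the base MLE
projected onto the constraint set (class means), which in practice
eliminates negative Δ*G*²; residual negatives within 1e-6 are clamped, and
anything larger triggers one refit with doubled starts plus a warning.

## The shrinkage reparametrisation

Expectation-consistent feedback is "true" for plausible and "false" for
implausible statements.  The order constraint
*d*_consistent = *s* · *d*_inconsistent (with *s* ∈ [0,1]) is implemented
by branch rewriting: a factor *d*_c becomes *s* · *d*_i, and a complement
(1 − *d*_c) splits the branch in two via
1 − *s·d* = (1 − *s*) + *s*(1 − *d*).  The result is again a pure
product-form MPT (EQN-expressible, same fitting machinery, unchanged free
parameter count), rather than a model with a derived-parameter layer.
Smaller *s* means a larger expectation-violation effect; *s* fixed at 1
reproduces the equal-*d* restriction exactly.

## Behavioral measures

Per participant and plausibility × feedback ("true"/"false") cell:
CSIM = correct feedback attributions / correct "old" responses (undefined
on an empty denominator), SIM = correct attributions / all 6 targets.
"?"-feedback trials enter the MPT frequencies but not CSIM/SIM, which are
defined for true/false feedback only.  Pr = hit rate (36 targets) − false
alarm rate (12 new); participants with Pr ≤ 0, self-reported non-serious
participation, note-taking, or insufficient language skills are excluded,
with a per-reason log.

The 2 × 2 within-subject ANOVA is computed from per-participant difference
scores; with two-level factors each effect's F is exactly the squared
paired t on the corresponding contrast (the implementation is
cross-checked against an independent repeated-measures ANOVA routine in
the tests), df = (1, n − 1), and η_p² = F/(F + df2).  CSIM analyses drop
participants with any undefined cell listwise; SIM analyses keep everyone.

## Synthetic data

The generator emulates only the test phase, which is all the analysis
consumes: per participant, 6 trials in each of the 8 design cells
(48 trials; 36 old + 12 new, with new statements split 6 plausible / 6
implausible so that both new trees receive data).  Responses are drawn from
the tree category probabilities at a single shared parameter vector
(complete pooling, matching the fitting assumption); optional Beta-mixing
around those values is available for robustness checks only.  A master
seed spawns one substream per participant, so datasets are bit-reproducible
and prefix-stable in the participant count.  For simulation studies that
only need aggregated tables, an equivalent aggregate-level multinomial
sampler is provided (identical in distribution under homogeneity, ~50×
faster).

What the generator does *not* emulate: statement-level content and
difficulty variation, participant heterogeneity (by default), study-phase
timing, buffers and the retention task, and sequential/order effects.
Passing calibration tests therefore show that the pipeline is correct and
well-calibrated *under the model's own assumptions*, not that real data
meet them.

Named scenarios fix the generating values:

* `paper-estimates` — the study's aggregate point estimates (e.g.
  *D*_P,true = .75, *d*_I,false = .62, *g*_true,P = .65, *g*_true,I = .36);
* `null` — every tested pair equated at the mean of those estimates
  (matched null for tests 1, 2a, 3);
* `expectation-violation-d` — feedback-memory effect of Δ*d* = .10 planted
  in both plausibility conditions on the null background
  (*d*_inconsistent = .75, *d*_consistent = .65, hence equal interior
  shrinkage *s* = .867 in both conditions — the matched null for test 2b);
* `guessing-only` — all *D* (.73) and *d* (.60) flat; only
  *a*_true/*g*_true vary by plausibility (at the study's asymmetric
  values).  Under this vector any observable plausibility × feedback
  interaction in SIM/CSIM is produced by guessing alone.

## Power

Δ*G*² power is estimated purely by simulation through the package's own
simulate → fit → nested-test path (no closed-form noncentrality for the
difference statistic is assumed); required-N searches double then bisect on
N with per-N seeds derived deterministically from the master seed.  The
goodness-of-fit power against a misfit of size Cohen's *w* uses the
noncentral χ² with λ = *n·w*²; at *w* = .05, df = 2, *n* = 15,744,
α = .001 this gives power ≈ .996.  The ANOVA required-N uses the
noncentral-F convention λ = *f*²·N·m/(1 − ρ) with numerator df 1 and
denominator df N − 1; at *f* = .10, ρ = .50, m = 4, α = .05, target power
.90 it yields N = 134.  External power programs differ in this convention
by a few participants, which is why it is explicit and configurable.

## Numerical and design choices

* Optimisation: L-BFGS-B, ftol 1e-13, gtol 1e-9, up to 2000 iterations;
  starting points uniform on (.02, .98); estimates at a refit of exact
  model-implied frequencies return *G*² below 1e-6.
* Simulation studies (calibration, power, recovery) use 2 random starts
  plus a warm start per fit; at the study's cell sizes the likelihood
  surface is effectively unimodal and dev-time checks found no start-count
  sensitivity, while the user-facing default stays at 20.
* Problem sizes: calibration runs in the test suite use 1000 replicates
  for type-I rates (Monte-Carlo SE ≈ .007 at .05), 200 for recovery and
  coverage, and 100 for the guessing-only demonstration; the acceptance
  script uses 400/100/100 and ~1 minute of runtime.
* Ties and degeneracies: equality constraints are collapsed by union-find
  with the lexicographically smallest member as class representative;
  contradictory constant fixings raise immediately; zero-count cells never
  contribute to *G*² or the likelihood.
* EQN dialect: header line with the branch count, then
  `tree category factor factor ...` with complements written `(1-name)`;
  `*`-separated products are accepted on input.  Equality constraints are
  not part of the EQN format and must be re-applied after reading.  Files
  whose trees do not sum to one at random interior parameter values are
  rejected.

## Known limitations

* Aggregate fitting ignores participant heterogeneity; with strong
  heterogeneity, aggregate parameter estimates are biased averages and the
  *G*² test can over-reject.  The Beta-mixing option exists to explore
  this, but no hierarchical estimator is provided.
* Wald intervals for weakly identified parameters (the *d*_? family)
  undercover slightly (~.93 rather than .95 at study size).
* The χ² reference for boundary-constrained shrinkage tests is
  conservative (mixture-distribution issue); results near s = 1 should be
  read accordingly.
* Exact reproduction of the published statistics requires the deposited
  frequency table; the package ships only the pipeline and scenario-based
  synthetic approximations of it.
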