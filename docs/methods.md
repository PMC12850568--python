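# Methods

## The question the simulator answers

Pair-feeding is meant to remove food intake as an explanation for group
differences: whatever the non-pair-fed (ad-libitum) group eats determines
what the pair-fed group is offered the next day. The usual analysis then
tests "no effect of treatment assignment" *without* any intake term, on the
assumption that intake is equal across arms by construction. That assumption
fails in distribution: capping a random draw at another random draw strictly
lowers its expectation, so the pair-fed group eats less on average even under
a perfect null, and any intake-driven outcome becomes systematically biased
between arms. `pairfeedsim` quantifies the resulting type I error inflation
for the two standard pair-feeding variants and shows which analysis models
repair it.

## Generative model

One simulated trial with m animals per group and n study days:

1. **Baseline.** W_j0 ~ N(μ_w, σ_w²) grams and F_j0 ~ N(μ_f, σ_f²) kcal,
   independently per animal and of each other. Defaults μ_w = 33, σ_w = 0.6,
   μ_f = 13.3, σ_f = 0.3 are mouse-scale values. Draws are *not* truncated at
   zero — at the defaults a non-positive intake draw has negligible
   probability — but configurations with μ_f < 6σ_f are rejected outright so
   the model stays well posed.
2. **Randomization.** A uniformly random balanced permutation assigns
   exactly m animals to each arm (not per-animal coin flips), making every
   1:1 split equally likely.
3. **Pairing (individual design).** Animals are ranked by baseline weight
   within arm, ascending, and matched rank-to-rank. Ties are broken by
   animal id, so the pairing is deterministic given the seed. (Note the
   pairing covariate, baseline weight, is unrelated to intake in this model;
   the within-pair outcome correlation that the mixed models target comes
   from the cap itself, and is of order 1/(2n) — small, and often estimated
   at the zero boundary.)
4. **Intake.** Every animal proposes each day's intake from the same
   N(μ_f, σ_f²). Non-pair-fed animals always eat their proposal. Pair-fed
   animals eat min(proposal, cap), where the cap is the non-pair-fed group's
   previous-day mean (group design) or the partner's previous-day intake
   (individual design). Because non-pair-fed intake is never truncated, caps
   depend only on non-pair-fed proposals and truncation cannot cascade. On
   day 1 the "previous day" is the baseline day, which is drawn from the
   same distribution as study days, so the day-1 cap is the non-pair-fed
   baseline mean (group) or the partner's baseline intake (individual); this
   preserves stationarity of the cap process from day 1 on.
5. **Weight.** W_ji = W_j,i−1 + (F_ji − F_j0)·δ, with the baseline intake
   F_j0 acting as a fixed maintenance requirement and δ (default 1/3500
   g/kcal, the standard calories-to-mass heuristic) converting surplus
   kcal to grams. The recursion telescopes exactly:
   ΔW_j = δ·(Σ_i F_ji − n·F_j0). δ is a config field, so sensitivity
   analyses can force other values.

Closed forms used throughout the tests: with proposal X ~ N(μ, σ²)
independent of its cap C, E[X − min(X, C)] = sd(X − C)/√(2π). Hence the
per-day deficit is σ/√π ≈ 0.169 kcal (individual) and
σ√(1+1/m)/√(2π) ≈ 0.121 kcal (group, m=40); the pair-fed mean weight change
is −δ·n times these; and without truncation Var(ΔW) = δ²σ_f²(n + n²), the n²
coming from the shared baseline maintenance term.

## Analysis models

Treatment is coded non-pair-fed = 0, pair-fed = 1; all tests are two-sided
at the configured α. The adjustment covariate is the within-animal mean
*realized* intake over study days 1..n — the baseline day is a maintenance
constant, not a study-day intake, and is excluded.

- **crude_lm / adjusted_lm** — OLS via statsmodels, p-values from the t
  distribution with 2m−2 and 2m−3 residual df. The crude model is
  algebraically the pooled-variance two-sample t-test, which the tests
  verify to machine precision.
- **pair_lmm / pair_lmm_adjusted** — REML linear mixed models (statsmodels
  `MixedLM`) with a random intercept per pair. Zero (boundary) variance
  estimates are accepted as valid fits. The Wald t p-value needs a df
  convention: the default is a Satterthwaite approximation, computed here
  directly because the fitting backend only offers normal-based p-values.
  With θ = (σ_e², σ_b²) and φ(θ) the GLS variance of the treatment
  coefficient, df = 2φ²/(g'Ag), where g = ∇φ and A is the inverse observed
  REML information, both obtained by central finite differences (relative
  steps 1e−4 for g, 1e−3 for A; the matrices are at most 2m×2m so dense
  algebra is exact and cheap). At the σ_b² = 0 boundary (detected at
  σ_b² ≤ 1e−6·σ_e²) the model is OLS and the residual df is used. On
  strongly paired data this reproduces the paired t-test (df = m−1) to
  high accuracy. `df_method="residual"` switches to 2m − rank(X) for
  sensitivity analyses; at 80 animals the two conventions are practically
  indistinguishable, at 16 animals the residual-df variant rejects somewhat
  more often.
- **Degenerate inputs** are flagged, never dropped, so rejection
  proportions keep their full denominator K: zero within-group outcome
  variance reports p = 1 with a flag; a constant covariate falls back to
  the unadjusted model; a MixedLM failure (exception or non-finite
  standard error) is refit with the pair variance at its zero boundary,
  i.e. plain OLS, and flagged.

## Monte Carlo engine

The empirical type I error rate of a model is Σ_k 1(p_k < α)/K. It is
compared with nominal α by a one-sample Pearson chi-square test on
{reject, not-reject} counts versus {αK, (1−α)K}, 1 df, without continuity
correction (at K = 10,000 the correction is negligible); the tests check
this statistic agrees with an exact binomial test's significance
classification in all reported scenarios. The two designs' intake deficits
are compared by collecting, per simulation, the difference in group means
of the within-animal mean intake (pair-fed minus non-pair-fed, so negative
under truncation) and applying Welch's t-test between the designs' K-vectors
(pooled-variance variant available by flag).

Reproducibility: iteration k of a scenario uses the stream
`SeedSequence([seed, k])`, so any iteration can be reproduced independently
and results are invariant to execution order. Re-running a scenario with
the same seed reproduces every statistic bit for bit.

**Problem sizes.** The reported tables use the full K = 10,000 iterations
for all OLS-based rates. The mixed-model rates use K = 2,000: each REML fit
plus its Satterthwaite df costs ~50–150 ms, and 2,000 iterations already
give a Monte Carlo standard error below 0.006 at p ≈ 0.06 and ~0.010 at
p ≈ 0.7, which is sufficient to resolve every qualitative and quantitative
claim the package makes. Test-suite property checks run at smaller K with
correspondingly wider binomial bands (3·√(p(1−p)/K)).

## What the generator does and does not emulate

It emulates the *statistical* structure of a pair-feeding experiment:
stationary iid intake, a deterministic intake-to-weight link, and the two
truncation rules. It deliberately omits behavioural and metabolic feedback
(appetite depending on weight or restriction, adaptive thermogenesis),
measurement error in intake, spillage (food provided is equated with food
consumed up to the cap), weight-dependent maintenance, group housing
correlations, and any treatment effect (everything is simulated under the
null). Passing tests therefore demonstrate the interference mechanism and
the behaviour of the analysis models under that mechanism — not that real
experiments have these exact error rates. In real data the inflation could
be larger or smaller depending on how strongly the outcome tracks intake
and on sources of variance this model excludes.

## Design choices that were genuinely open

- **Day-1 cap** from baseline values (see above): the natural stationary
  completion of the previous-day recursion.
- **δ literal**: 1/3500 g/kcal, the standard conversion consistent with
  gram-scale weights; configurable for sensitivity checks.
- **Satterthwaite as default LMM df** with the residual-df convention
  exposed, since small-sample mixed-model p-values depend visibly on the
  choice at 16 animals.
- **Welch as default design-comparison t-test**: the two designs' deficit
  distributions have unequal variances by construction.
- **Randomize-after-draw**: under iid baselines the order is irrelevant;
  drawing first keeps the cohort fixed under re-randomization, which the
  label-independence test exploits.

## Known limitations

- **Small-sample mixed-model inflation is intrinsic, not a bug.** When the
  true pair variance is zero (as in the no-truncation diagnostic, and very
  nearly so under individual pair-feeding), REML estimates it on the
  boundary about half the time, and the data-driven switch between the
  interior fit (equivalent to a paired t-test) and the boundary fit
  (equivalent to OLS) conditions on the same sums of squares that form the
  test statistic. At 8 pairs this inflates the null rejection rate of the
  pair-intercept models to ~0.06 even with nothing else going on;
  lme4+lmerTest (Satterthwaite) reproduces the same rate on identical data.
  The effect vanishes by ~40 pairs (measured null rate 0.049 over 1,500
  replicates). The calibration tests therefore check the OLS models (exactly
  calibrated at any size) at 8 pairs and the mixed models at 40 pairs, and
  part of the tabulated small-sample inflation of the doubly adjusted mixed
  model should be read as this boundary-REML effect rather than as
  pair-feeding interference per se.
- The mixed-model rates at 16 animals are sensitive at the ~0.01 level to
  the df convention; both conventions are implemented but only the default
  is tabulated.
- The Satterthwaite machinery assumes the single-random-intercept
  structure; it does not generalize to crossed or nested designs.
- Long studies with very small σ_f make the outcome nearly collinear with
  the covariate; the adjusted models then rely on the baseline-intake noise
  term for identification, which is the intended behaviour of the model but
  can look numerically extreme (flagged when exact).
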