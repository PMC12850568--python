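# pairfeedsim

Monte Carlo simulator of **pair-feeding animal experiments** for quantifying
how this widely used design element distorts statistical inference.

In a pair-feeding study, the food offered to one group (the *pair-fed* group)
is capped by what another group (the *non-pair-fed*, ad-libitum group) ate the
day before — either at the non-pair-fed group's previous-day mean intake
(*group pair-feeding*) or at the previous-day intake of a one-to-one matched
partner (*individual pair-feeding*, matched here by baseline body-weight
rank). The intent is to equalize intake across arms so that treatment effects
can be read independently of food intake; the side effect is that one
animal's behaviour determines another's exposure — a violation of the
no-interference component of the stable unit treatment value assumption
(SUTVA). Because a normal draw capped at another normal draw has a *lower
mean* than an uncapped one, pair-feeding systematically depresses the
pair-fed group's intake, and any outcome downstream of intake inherits that
bias even when no treatment effect exists.

`pairfeedsim` simulates this situation under the null. For animals
j = 1..m per group over days i = 1..n:

- baseline weight W_j0 ~ N(μ_w = 33 g, σ_w = 0.6 g) and baseline intake
  F_j0 ~ N(μ_f = 13.3 kcal, σ_f = 0.3 kcal), independent, with 1:1
  randomization to the two groups (mouse-scale defaults);
- daily intake proposals from the same N(μ_f, σ_f²), with the pair-fed
  group truncated by the applicable cap: F_jp,i = min(F_jp,i, cap_j,i−1);
- weight updated recursively, W_ji = W_j,i−1 + (F_ji − F_j0)·δ with
  δ = 1/3500 g per kcal, so the outcome ΔW_j = W_jn − W_j0 is driven by
  realized intake relative to the fixed maintenance level F_j0.

Each simulated trial is analyzed for a treatment effect on ΔW with up to four
models: OLS without covariates, OLS adjusted for the within-animal mean daily
intake, and (individual design) linear mixed models with a random intercept
per pair, with and without the intake covariate. The **empirical type I error
rate** of a model is the fraction of K null simulations with treatment
p < α = 0.05; it is compared with the nominal α by a one-sample Pearson
chi-square test. The simulator reproduces the headline phenomenon: unadjusted
analyses reject a true null up to ~70% of the time, while adjusting for
realized food intake restores ~5%.

## Worked example

```python
from pairfeedsim import DesignConfig, estimate_t1er
from pairfeedsim.reporting import summaries_to_frame

cfg = DesignConfig(m_per_group=40, n_days=50, design="group_pf",
                   n_reps=2000, seed=42)
summary = estimate_t1er(cfg)
print(summaries_to_frame([summary]).to_string(index=False))
```

prints

```
  design  n_animals  n_days    K  Model_1  p_value_1  Model_2  p_value_2
group_pf         80      50 2000    0.424        0.0     0.05        1.0
```

Model_1 (no covariate) falsely rejects the null in 42.4% of 2,000 simulated
trials — an order of magnitude above the nominal 5% — and its chi-square
p-value against nominal is numerically 0; Model_2, which adds each animal's
mean realized intake as a covariate, rejects in 5.0% (chi-square p = 1.0:
exactly the expected 100 rejections). Comparing the two designs at the same
settings:

```python
from pairfeedsim import compare_designs
comp = compare_designs(cfg.replace(n_reps=400),
                       cfg.replace(design="individual_pf", n_reps=400, seed=43))
```

gives a mean per-day intake deficit of 0.121 kcal under group pair-feeding
versus 0.169 kcal under individual pair-feeding (Welch t = 119.7, p ≈ 0) —
matching the closed forms σ·√(1+1/m)/√(2π) and σ/√π.

The same scenarios are available from the shell:

```bash
pairfeed simulate --design group_pf -m 40 -n 50 --reps 2000 --seed 42 --out results/
pairfeed reproduce-tables --reps 10000 --lmm-reps 2000 --out results/
pairfeed compare-designs -m 40 -n 50 --reps 10000 --out results/
pairfeed figures --design individual_pf --out results/
```

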