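"""Monte Carlo engine: run trials, estimate type-I-error rates, compare designs.

Every iteration draws a fresh null experiment (no treatment effect exists
anywhere in the generative model), analyzes it with the models applicable to
the design, and records the treatment p-values. The empirical type-I-error
rate of a model is the fraction of iterations with p < alpha, and is tested
against the nominal alpha with a one-sample Pearson chi-square test.

Reproducibility contract: iteration k of a scenario uses the RNG stream
derived from ``SeedSequence([config.seed, k])``, so iterations are
reproducible independently and in any order.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import analysis
from .analysis import ModelFit, TrialPValues
from .cohort import BaselineCohort, draw_baseline
from .config import GROUP_PF, INDIVIDUAL_PF, ConfigError, DesignConfig
from .designs import (
    IntakeMatrix,
    PairAssignment,
    apply_group_pf,
    apply_individual_pf,
    generate_proposals,
    pair_by_weight,
)
from .dynamics import WeightTrajectory, compute_outcome, update_weights

GROUP_MODELS = (analysis.CRUDE_LM, analysis.ADJUSTED_LM)
INDIVIDUAL_MODELS = analysis.ALL_MODELS


def default_models(config: DesignConfig) -> tuple[str, ...]:
    return GROUP_MODELS if config.design == GROUP_PF else INDIVIDUAL_MODELS


def iteration_rng(seed: int, iteration_index: int) -> np.random.Generator:
    """Deterministic per-iteration stream derived from (root seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([seed, iteration_index]))


@dataclasses.dataclass
class ExperimentData:
    """One fully simulated trial."""

    cohort: BaselineCohort
    pairs: PairAssignment | None
    intakes: IntakeMatrix
    trajectory: WeightTrajectory


def simulate_experiment(config: DesignConfig, rng: np.random.Generator) -> ExperimentData:
    """Simulate one trial: baseline -> randomize -> [pair] -> intakes -> weights."""
    cohort = draw_baseline(config, rng)
    pairs = pair_by_weight(cohort) if config.design == INDIVIDUAL_PF else None
    intakes = generate_proposals(config, cohort, rng)
    if not config.no_truncation:
        if config.design == GROUP_PF:
            intakes = apply_group_pf(intakes, cohort, config)
        else:
            intakes = apply_individual_pf(intakes, cohort, pairs, config)
    trajectory = update_weights(intakes, cohort, config)
    return ExperimentData(cohort, pairs, intakes, trajectory)


def analyze_trial(
    data: ExperimentData,
    config: DesignConfig,
    iteration: int = 0,
    models: Sequence[str] | None = None,
) -> TrialPValues:
    """Fit the requested models to one simulated trial."""
    if models is None:
        models = default_models(config)
    outcome = compute_outcome(data.trajectory)
    is_pf = data.cohort.is_pf
    covariate = analysis.compute_within_animal_mean_intake(data.intakes)
    mean_intake_diff = float(covariate[is_pf].mean() - covariate[~is_pf].mean())
    fits: dict[str, ModelFit] = {}
    for tag in models:
        if tag == analysis.CRUDE_LM:
            fits[tag] = analysis.fit_crude_lm(outcome, is_pf)
        elif tag == analysis.ADJUSTED_LM:
            fits[tag] = analysis.fit_adjusted_lm(outcome, is_pf, covariate)
        elif tag == analysis.PAIR_LMM:
            fits[tag] = analysis.fit_pair_lmm(
                outcome, is_pf, data.pairs, data.cohort.animal_id, config.df_method
            )
        elif tag == analysis.PAIR_LMM_ADJUSTED:
            fits[tag] = analysis.fit_pair_lmm_adjusted(
                outcome, is_pf, data.pairs, data.cohort.animal_id, covariate, config.df_method
            )
        else:
            raise ValueError(f"unknown model tag {tag!r}")
    return TrialPValues(iteration=iteration, fits=fits, mean_intake_diff=mean_intake_diff)


def run_trial(
    config: DesignConfig,
    iteration_index: int,
    models: Sequence[str] | None = None,
) -> TrialPValues:
    """Simulate and analyze iteration ``iteration_index`` of a scenario."""
    rng = iteration_rng(config.seed, iteration_index)
    data = simulate_experiment(config, rng)
    return analyze_trial(data, config, iteration_index, models)


# ----------------------------------------------------------------------
# Aggregation
# ----------------------------------------------------------------------

@dataclasses.dataclass
class ModelT1Er:
    """Rejection summary for one model over K iterations."""

    model_tag: str
    rejections: int
    K: int
    t1er: float
    chisq_stat: float
    chisq_p: float
    n_flagged: int  # degenerate / fallback fits (kept in the denominator)


@dataclasses.dataclass
class T1ErSummary:
    """Per-scenario type-I-error summary across all fitted models."""

    design: str
    m_per_group: int
    n_days: int
    alpha: float
    K: int
    seed: int
    models: dict[str, ModelT1Er]
    intake_diffs: np.ndarray  # per-iteration pf-minus-non-pf mean intake
    runtime_s: float = 0.0

    def t1er(self, tag: str) -> float:
        return self.models[tag].t1er


def test_against_nominal(
    rejection_count: int, K: int, alpha: float
) -> tuple[float, float]:
    """Pearson chi-square GOF of {reject, not} counts vs {alpha*K, (1-alpha)*K}.

    One df, no continuity correction.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if not (0 <= rejection_count <= K):
        raise ValueError("rejection_count must be between 0 and K")
    observed = np.array([rejection_count, K - rejection_count], dtype=float)
    expected = np.array([alpha * K, (1.0 - alpha) * K])
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p)


def estimate_t1er(
    config: DesignConfig,
    models: Sequence[str] | None = None,
    collect: bool = False,
    progress: bool = False,
) -> T1ErSummary | tuple[T1ErSummary, pd.DataFrame]:
    """Monte Carlo estimate of per-model type-I-error rates for one scenario.

    With ``collect=True`` also returns the per-iteration long-format table
    (iteration, design, m, n, model_tag, beta1, se, p_value, converged_flag,
    mean_intake_diff).
    """
    if models is None:
        models = default_models(config)
    t0 = time.perf_counter()
    rejections = {tag: 0 for tag in models}
    flagged = {tag: 0 for tag in models}
    diffs = np.empty(config.n_reps)
    rows: list[dict] = []
    for k in range(config.n_reps):
        trial = run_trial(config, k, models)
        diffs[k] = trial.mean_intake_diff
        for tag, fit in trial.fits.items():
            if fit.p_value < config.alpha:
                rejections[tag] += 1
            if fit.flag is not None:
                flagged[tag] += 1
            if collect:
                rows.append(
                    {
                        "iteration": k,
                        "design": config.design,
                        "m": config.m_per_group,
                        "n": config.n_days,
                        "model_tag": tag,
                        "beta1": fit.beta1,
                        "se": fit.se,
                        "p_value": fit.p_value,
                        "converged_flag": fit.flag or "ok",
                        "mean_intake_diff": trial.mean_intake_diff,
                    }
                )
        if progress and (k + 1) % max(1, config.n_reps // 20) == 0:
            print(f"  {config.design} m={config.m_per_group} n={config.n_days}: "
                  f"{k + 1}/{config.n_reps}", flush=True)
    model_summaries = {}
    for tag in models:
        stat, p = test_against_nominal(rejections[tag], config.n_reps, config.alpha)
        model_summaries[tag] = ModelT1Er(
            model_tag=tag,
            rejections=rejections[tag],
            K=config.n_reps,
            t1er=rejections[tag] / config.n_reps,
            chisq_stat=stat,
            chisq_p=p,
            n_flagged=flagged[tag],
        )
    summary = T1ErSummary(
        design=config.design,
        m_per_group=config.m_per_group,
        n_days=config.n_days,
        alpha=config.alpha,
        K=config.n_reps,
        seed=config.seed,
        models=model_summaries,
        intake_diffs=diffs,
        runtime_s=time.perf_counter() - t0,
    )
    if collect:
        return summary, pd.DataFrame(rows)
    return summary


# ----------------------------------------------------------------------
# Design comparison
# ----------------------------------------------------------------------

@dataclasses.dataclass
class DesignComparison:
    """Per-simulation pf-minus-non-pf mean-intake differences, both designs."""

    group_diffs: np.ndarray
    individual_diffs: np.ndarray
    t_stat: float
    t_p: float
    welch: bool

    @property
    def group_mean(self) -> float:
        return float(self.group_diffs.mean())

    @property
    def individual_mean(self) -> float:
        return float(self.individual_diffs.mean())

    @property
    def group_sd(self) -> float:
        return float(self.group_diffs.std(ddof=1))

    @property
    def individual_sd(self) -> float:
        return float(self.individual_diffs.std(ddof=1))


def _intake_diffs(config: DesignConfig) -> np.ndarray:
    diffs = np.empty(config.n_reps)
    for k in range(config.n_reps):
        diffs[k] = run_trial(config, k, models=()).mean_intake_diff
    return diffs


def compare_designs(
    config_group: DesignConfig,
    config_individual: DesignConfig,
    welch: bool = True,
) -> DesignComparison:
    """Compare the two designs' per-simulation mean intake deficits by t-test.

    Welch's unequal-variance test by default; ``welch=False`` uses the
    pooled-variance version.
    """
    if config_group.design != GROUP_PF or config_individual.design != INDIVIDUAL_PF:
        raise ConfigError("compare_designs needs one group_pf and one individual_pf config")
    for field in ("m_per_group", "n_days", "n_reps"):
        if getattr(config_group, field) != getattr(config_individual, field):
            raise ConfigError(f"both designs must share {field}")
    g = _intake_diffs(config_group)
    i = _intake_diffs(config_individual)
    t, p = stats.ttest_ind(g, i, equal_var=not welch)
    return DesignComparison(g, i, float(t), float(p), welch)
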