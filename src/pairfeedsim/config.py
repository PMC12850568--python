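"""Scenario configuration for pair-feeding simulations.

A :class:`DesignConfig` holds every knob of one simulated study: group size,
duration, the baseline weight/intake distributions, the calorie-to-weight
conversion constant, the pair-feeding design variant, and the Monte Carlo
settings (nominal alpha, number of replicates, root seed).
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping

import yaml

GROUP_PF = "group_pf"
INDIVIDUAL_PF = "individual_pf"
DESIGNS = (GROUP_PF, INDIVIDUAL_PF)

DF_METHODS = ("satterthwaite", "residual")

#: grams of body-weight change per kcal of intake above/below maintenance
DEFAULT_DELTA = 1.0 / 3500.0


class ConfigError(ValueError):
    """A scenario configuration field is invalid; the message names the field."""


@dataclasses.dataclass(frozen=True)
class DesignConfig:
    """All parameters of one simulated pair-feeding scenario.

    Defaults are the mouse-study conditions the simulator emulates:
    baseline weight ~ N(33, 0.6^2) g, intake ~ N(13.3, 0.3^2) kcal/day,
    delta = 1/3500 g per kcal, alpha = 0.05, 10,000 Monte Carlo replicates.

    Parameters
    ----------
    m_per_group : int
        Animals per group (the study has ``2 * m_per_group`` animals total).
    n_days : int
        Number of study days after the baseline day.
    mu_w, sigma_w : float
        Mean and SD of baseline body weight, grams.
    mu_f, sigma_f : float
        Mean and SD of daily food intake, kcal (also the baseline intake
        distribution and the maintenance requirement).
    delta : float
        Weight change per kcal of intake deviating from maintenance, g/kcal.
    design : {"group_pf", "individual_pf"}
        Pair-feeding variant: cap at the non-pair-fed group's previous-day
        mean, or at the weight-rank-matched partner's previous-day intake.
    alpha : float
        Nominal type-I-error level used for the rejection threshold.
    n_reps : int
        Monte Carlo iterations.
    seed : int
        Root seed; each iteration derives its own stream from (seed, index).
    no_truncation : bool
        Diagnostic mode: skip the pair-feeding cap entirely, so both groups
        eat their proposal draws and every analysis model is exactly null
        calibrated.
    df_method : {"satterthwaite", "residual"}
        Degrees of freedom used for mixed-model Wald t p-values.
    """

    m_per_group: int = 40
    n_days: int = 50
    mu_w: float = 33.0
    sigma_w: float = 0.6
    mu_f: float = 13.3
    sigma_f: float = 0.3
    delta: float = DEFAULT_DELTA
    design: str = GROUP_PF
    alpha: float = 0.05
    n_reps: int = 10_000
    seed: int = 0
    no_truncation: bool = False
    df_method: str = "satterthwaite"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.m_per_group, (int,)) or self.m_per_group < 2:
            raise ConfigError(f"m_per_group must be an integer >= 2, got {self.m_per_group!r}")
        if not isinstance(self.n_days, (int,)) or self.n_days < 1:
            raise ConfigError(f"n_days must be an integer >= 1, got {self.n_days!r}")
        if not (self.sigma_w >= 0):
            raise ConfigError(f"sigma_w must be >= 0, got {self.sigma_w!r}")
        if not (self.sigma_f >= 0):
            raise ConfigError(f"sigma_f must be >= 0, got {self.sigma_f!r}")
        if not (self.mu_f > 0):
            raise ConfigError(f"mu_f must be > 0, got {self.mu_f!r}")
        # Keep intakes effectively positive without truncating the normal:
        # at mu_f >= 6 sigma_f a non-positive draw is a ~1e-9 event per draw.
        if self.mu_f < 6.0 * self.sigma_f:
            raise ConfigError(
                f"mu_f must be at least 6 * sigma_f so intake draws are positive "
                f"in practice, got mu_f={self.mu_f!r}, sigma_f={self.sigma_f!r}"
            )
        if not (self.delta > 0):
            raise ConfigError(f"delta must be > 0, got {self.delta!r}")
        if self.design not in DESIGNS:
            raise ConfigError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha!r}")
        if not isinstance(self.n_reps, int) or self.n_reps < 1:
            raise ConfigError(f"n_reps must be an integer >= 1, got {self.n_reps!r}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")
        if self.df_method not in DF_METHODS:
            raise ConfigError(f"df_method must be one of {DF_METHODS}, got {self.df_method!r}")

    # -- convenience ----------------------------------------------------
    @property
    def n_animals(self) -> int:
        return 2 * self.m_per_group

    def replace(self, **changes: Any) -> "DesignConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    # -- construction from flat key-value sources -----------------------
    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "DesignConfig":
        """Build a config from a flat key-value mapping.

        Unknown keys raise :class:`ConfigError` so typos in config files
        do not silently fall back to defaults.
        """
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str) -> "DesignConfig":
        """Load a flat YAML (or ``key: value`` text) config file."""
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {path!r} must contain a flat key-value mapping")
        return cls.from_mapping(loaded)
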