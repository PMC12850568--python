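"""Baseline cohort generation and 1:1 randomization.

Baseline body weight (g) and baseline food intake (kcal) are drawn
independently per animal from normal distributions; animals are then
assigned to the pair-fed ("pf") or non-pair-fed ("non_pf") group by a
uniformly random balanced split, so groups are exactly equal sized.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ConfigError, DesignConfig

PF = "pf"
NON_PF = "non_pf"


@dataclasses.dataclass
class BaselineCohort:
    """Baseline records for ``2m`` animals, optionally group-labelled.

    ``group`` is ``None`` for an unlabeled cohort (before randomization),
    otherwise an array of ``"pf"`` / ``"non_pf"`` labels.
    """

    animal_id: np.ndarray  # int, 1..2m
    weight: np.ndarray     # W_j0, grams
    intake: np.ndarray     # F_j0, kcal (also the maintenance requirement)
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_id = np.asarray(self.animal_id, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        self.intake = np.asarray(self.intake, dtype=float)
        n = self.animal_id.size
        if self.weight.size != n or self.intake.size != n:
            raise ValueError("animal_id, weight and intake must have equal length")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype="U6")
            if self.group.size != n:
                raise ValueError("group labels must match the number of animals")

    @property
    def n_animals(self) -> int:
        return self.animal_id.size

    @property
    def is_pf(self) -> np.ndarray:
        if self.group is None:
            raise ValueError("cohort has no group labels yet")
        return self.group == PF

    def subset_ids(self, pf: bool) -> np.ndarray:
        mask = self.is_pf if pf else ~self.is_pf
        return self.animal_id[mask]


def draw_baseline(config: DesignConfig, rng: np.random.Generator) -> BaselineCohort:
    """Draw baseline weights/intakes for ``2m`` animals and randomize groups.

    Weights are iid N(mu_w, sigma_w^2), intakes iid N(mu_f, sigma_f^2),
    mutually independent; group labels are a uniform balanced split.
    """
    config.validate()
    n = config.n_animals
    weights = rng.normal(config.mu_w, config.sigma_w, size=n)
    intakes = rng.normal(config.mu_f, config.sigma_f, size=n)
    cohort = BaselineCohort(np.arange(1, n + 1), weights, intakes, group=None)
    return randomize_groups(cohort, rng)


def randomize_groups(cohort: BaselineCohort, rng: np.random.Generator) -> BaselineCohort:
    """Attach pf / non_pf labels by a uniformly random balanced split.

    Implemented as a random permutation of the animals with the first half
    labelled pf, which makes every balanced split equally likely and
    guarantees the exact 1:1 ratio.
    """
    n = cohort.n_animals
    if n % 2 != 0:
        raise ConfigError(f"1:1 randomization needs an even number of animals, got {n}")
    perm = rng.permutation(n)
    labels = np.empty(n, dtype="U6")
    labels[perm[: n // 2]] = PF
    labels[perm[n // 2:]] = NON_PF
    return BaselineCohort(cohort.animal_id, cohort.weight, cohort.intake, group=labels)
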