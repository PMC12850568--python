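"""Body-weight dynamics: recursive update from intake and the trial outcome.

The baseline intake F_j0 is treated as the animal's fixed maintenance
requirement. Each day the animal gains (loses) delta grams per kcal eaten
above (below) maintenance:

    W_ji = W_j,i-1 + (F_ji - F_j0) * delta

which telescopes to dW_j = delta * (sum_i F_ji - n * F_j0).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import BaselineCohort
from .config import DesignConfig
from .designs import IntakeMatrix


@dataclasses.dataclass
class WeightTrajectory:
    """Per-animal weights for days 0..n and the post-minus-pre change."""

    animal_id: np.ndarray
    weights: np.ndarray        # (2m, n+1), column 0 is baseline
    weight_change: np.ndarray  # dW_j = W_jn - W_j0

    def to_frame(self) -> pd.DataFrame:
        n_animals, n_cols = self.weights.shape
        return pd.DataFrame(
            {
                "animal_id": np.repeat(self.animal_id, n_cols),
                "day": np.tile(np.arange(n_cols), n_animals),
                "weight": self.weights.ravel(),
            }
        )


def update_weights(
    intakes: IntakeMatrix, cohort: BaselineCohort, config: DesignConfig
) -> WeightTrajectory:
    """Run the daily weight recursion for every animal."""
    realized = intakes.realized
    if realized.shape != (cohort.n_animals, config.n_days) or not np.all(np.isfinite(realized)):
        raise ValueError("intake matrix is incomplete (wrong shape or non-finite entries)")
    surplus = realized - cohort.intake[:, None]  # kcal above maintenance
    weights = np.empty((cohort.n_animals, config.n_days + 1))
    weights[:, 0] = cohort.weight
    weights[:, 1:] = cohort.weight[:, None] + config.delta * np.cumsum(surplus, axis=1)
    return WeightTrajectory(
        animal_id=cohort.animal_id,
        weights=weights,
        weight_change=weights[:, -1] - weights[:, 0],
    )


def compute_outcome(traj: WeightTrajectory) -> np.ndarray:
    """Trial outcome: final minus baseline weight, per animal."""
    return traj.weights[:, -1] - traj.weights[:, 0]
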