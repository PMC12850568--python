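"""Daily intake generation and the pair-feeding truncation rules.

Both groups propose each day's intake from the same normal distribution as
baseline. Non-pair-fed animals always eat their proposal. Pair-fed animals
are capped:

* group pair-feeding  — at the non-pair-fed group's *previous-day* mean
  realized intake;
* individual pair-feeding — at the *previous-day* realized intake of the
  baseline-weight-rank-matched partner in the non-pair-fed group.

On day 1 the only available "previous day" is baseline, which is drawn from
the same distribution as the study days, so the day-1 cap is the non-pair-fed
baseline mean (group design) or the partner's baseline intake (individual
design). Because non-pair-fed animals are never truncated, every cap is a
function of non-pair-fed *proposals*, so there is no cascading truncation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import BaselineCohort
from .config import DesignConfig


@dataclasses.dataclass
class PairAssignment:
    """Weight-rank pairing: rank j pf animal <-> rank j non-pf animal."""

    pf_animal_id: np.ndarray      # ordered by ascending pf baseline weight
    non_pf_animal_id: np.ndarray  # ordered by ascending non-pf baseline weight

    def __post_init__(self) -> None:
        self.pf_animal_id = np.asarray(self.pf_animal_id, dtype=int)
        self.non_pf_animal_id = np.asarray(self.non_pf_animal_id, dtype=int)
        if self.pf_animal_id.size != self.non_pf_animal_id.size:
            raise ValueError("pairing must be a bijection between equal-sized groups")

    @property
    def n_pairs(self) -> int:
        return self.pf_animal_id.size

    def pair_rank_of(self, animal_id: np.ndarray) -> np.ndarray:
        """Pair rank (1..m) for each animal id, pf or non-pf."""
        rank = np.full(np.max(animal_id) + 1, -1, dtype=int)
        rank[self.pf_animal_id] = np.arange(1, self.n_pairs + 1)
        rank[self.non_pf_animal_id] = np.arange(1, self.n_pairs + 1)
        out = rank[np.asarray(animal_id, dtype=int)]
        if np.any(out < 0):
            raise ValueError("animal id not covered by the pairing")
        return out


@dataclasses.dataclass
class IntakeMatrix:
    """Per-animal, per-day proposal and realized intakes plus caps.

    Rows follow ``animal_id`` order; columns are study days 1..n. ``caps``
    is +inf wherever no truncation applies (all non-pf rows; every row in
    the no-truncation diagnostic mode).
    """

    animal_id: np.ndarray
    baseline: np.ndarray   # F_j0, kcal
    proposals: np.ndarray  # (2m, n) untruncated draws
    realized: np.ndarray   # (2m, n) after the applicable cap
    caps: np.ndarray       # (2m, n)

    def __post_init__(self) -> None:
        self.proposals = np.asarray(self.proposals, dtype=float)
        self.realized = np.asarray(self.realized, dtype=float)
        self.caps = np.asarray(self.caps, dtype=float)
        if self.proposals.shape != self.realized.shape or self.caps.shape != self.realized.shape:
            raise ValueError("proposals, realized and caps must share one shape")

    @property
    def n_days(self) -> int:
        return self.realized.shape[1]

    def to_frame(self, group: np.ndarray) -> pd.DataFrame:
        """Long-format audit table: animal_id, group, day, proposal, realized, cap."""
        n_animals, n_days = self.realized.shape
        return pd.DataFrame(
            {
                "animal_id": np.repeat(self.animal_id, n_days),
                "group": np.repeat(np.asarray(group), n_days),
                "day": np.tile(np.arange(1, n_days + 1), n_animals),
                "proposal": self.proposals.ravel(),
                "realized": self.realized.ravel(),
                "cap": self.caps.ravel(),
            }
        )


def pair_by_weight(cohort: BaselineCohort) -> PairAssignment:
    """Match pf and non-pf animals by ascending baseline-weight rank.

    Ties (measure zero under continuous draws) are broken by animal id so
    the pairing is deterministic given the seed.
    """
    pf_mask = cohort.is_pf
    if pf_mask.sum() * 2 != cohort.n_animals:
        raise ValueError("pairing requires a balanced cohort")
    order = np.lexsort((cohort.animal_id, cohort.weight))
    ordered_ids = cohort.animal_id[order]
    ordered_pf = pf_mask[order]
    return PairAssignment(
        pf_animal_id=ordered_ids[ordered_pf],
        non_pf_animal_id=ordered_ids[~ordered_pf],
    )


def generate_proposals(
    config: DesignConfig, cohort: BaselineCohort, rng: np.random.Generator
) -> IntakeMatrix:
    """Draw the untruncated intake proposals for both groups.

    All ``2m x n`` entries are iid N(mu_f, sigma_f^2), independent of the
    baseline draws. The returned matrix has ``realized == proposals`` and
    infinite caps; the design-specific truncation is applied afterwards.
    """
    config.validate()
    shape = (cohort.n_animals, config.n_days)
    proposals = rng.normal(config.mu_f, config.sigma_f, size=shape)
    return IntakeMatrix(
        animal_id=cohort.animal_id,
        baseline=cohort.intake.copy(),
        proposals=proposals,
        realized=proposals.copy(),
        caps=np.full(shape, np.inf),
    )


def _row_index(cohort: BaselineCohort, animal_id: np.ndarray) -> np.ndarray:
    order = np.argsort(cohort.animal_id)
    pos = np.searchsorted(cohort.animal_id[order], animal_id)
    return order[pos]


def apply_group_pf(
    proposals: IntakeMatrix, cohort: BaselineCohort, config: DesignConfig
) -> IntakeMatrix:
    """Apply the group pair-feeding cap.

    Each pf animal's day-i intake is min(proposal, previous-day non-pf group
    mean); the day-1 cap is the non-pf baseline mean. Non-pf rows are
    returned untouched.
    """
    pf = cohort.is_pf
    np_rows = proposals.proposals[~pf]  # realized == proposal for non-pf
    caps_by_day = np.empty(config.n_days)
    caps_by_day[0] = cohort.intake[~pf].mean()
    if config.n_days > 1:
        caps_by_day[1:] = np_rows[:, :-1].mean(axis=0)
    caps = np.full_like(proposals.caps, np.inf)
    caps[pf] = caps_by_day[None, :]
    realized = proposals.proposals.copy()
    realized[pf] = np.minimum(realized[pf], caps[pf])
    return IntakeMatrix(proposals.animal_id, proposals.baseline, proposals.proposals, realized, caps)


def apply_individual_pf(
    proposals: IntakeMatrix,
    cohort: BaselineCohort,
    pairs: PairAssignment | None,
    config: DesignConfig,
) -> IntakeMatrix:
    """Apply the individual pair-feeding cap.

    The pf animal of pair j is capped at its partner's previous-day realized
    intake (the partner's proposal, since non-pf animals are never
    truncated); the day-1 cap is the partner's baseline intake.
    """
    if pairs is None:
        raise ValueError("individual pair-feeding requires a PairAssignment")
    pf_rows = _row_index(cohort, pairs.pf_animal_id)
    partner_rows = _row_index(cohort, pairs.non_pf_animal_id)
    partner_prev = np.column_stack(
        [cohort.intake[partner_rows], proposals.proposals[partner_rows, :-1]]
    )
    caps = np.full_like(proposals.caps, np.inf)
    caps[pf_rows] = partner_prev
    realized = proposals.proposals.copy()
    realized[pf_rows] = np.minimum(realized[pf_rows], partner_prev)
    return IntakeMatrix(proposals.animal_id, proposals.baseline, proposals.proposals, realized, caps)


def expected_daily_deficit(config: DesignConfig) -> float:
    """Closed-form expected per-day intake deficit (non-pf minus pf mean).

    With proposal X ~ N(mu, s^2) independent of its cap C,
    E[X - min(X, C)] = sd(X - C) / sqrt(2*pi). The cap is a single partner
    draw (individual design, sd = s*sqrt(2), giving s/sqrt(pi)) or the mean
    of m draws (group design, sd = s*sqrt(1 + 1/m)).
    """
    s = config.sigma_f
    if config.no_truncation:
        return 0.0
    if config.design == "individual_pf":
        return s / np.sqrt(np.pi)
    return s * np.sqrt(1.0 + 1.0 / config.m_per_group) / np.sqrt(2.0 * np.pi)
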