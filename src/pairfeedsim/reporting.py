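"""Tables, run manifests and figures for simulation summaries.

Tables follow the field's reporting convention: one row per scenario
(number of animals x number of days), one ``Model_k`` column per analysis
model plus a matching ``p_value_k`` column from the chi-square test against
the nominal alpha. Model numbering depends on the design:

* group design:      Model_1 = crude OLS, Model_2 = intake-adjusted OLS
* individual design: Model_1 = crude OLS, Model_2 = pair-intercept LMM,
                     Model_3 = intake-adjusted OLS, Model_4 = adjusted LMM
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import analysis
from .config import GROUP_PF
from .engine import DesignComparison, ExperimentData, T1ErSummary

logger = logging.getLogger("pairfeedsim")

MODEL_NUMBERING = {
    "group_pf": (analysis.CRUDE_LM, analysis.ADJUSTED_LM),
    "individual_pf": (
        analysis.CRUDE_LM,
        analysis.PAIR_LMM,
        analysis.ADJUSTED_LM,
        analysis.PAIR_LMM_ADJUSTED,
    ),
}


def summaries_to_frame(summaries: Iterable[T1ErSummary]) -> pd.DataFrame:
    """Flatten scenario summaries into the tabular reporting layout."""
    rows = []
    for s in summaries:
        row: dict = {
            "design": s.design,
            "n_animals": 2 * s.m_per_group,
            "n_days": s.n_days,
            "K": s.K,
        }
        for k, tag in enumerate(MODEL_NUMBERING[s.design], start=1):
            if tag in s.models:
                m = s.models[tag]
                row[f"Model_{k}"] = m.t1er
                row[f"p_value_{k}"] = m.chisq_p
        rows.append(row)
    return pd.DataFrame(rows)


def render_tables(
    summaries: Sequence[T1ErSummary], out_dir: str | Path, stem: str = "t1er_tables"
) -> pd.DataFrame:
    """Write the summary table as CSV and JSON; returns the DataFrame."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = summaries_to_frame(summaries)
    frame.to_csv(out_dir / f"{stem}.csv", index=False)
    frame.to_json(out_dir / f"{stem}.json", orient="records", indent=2)
    return frame


def tables_round_trip(path_json: str | Path) -> pd.DataFrame:
    """Read a JSON table back into the same layout (lossless round trip)."""
    return pd.read_json(path_json, orient="records")


def write_manifest(path: str | Path, payload: dict) -> None:
    """JSON run manifest: configs, seeds, runtimes, convergence counts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)


def summary_manifest_entry(s: T1ErSummary) -> dict:
    return {
        "design": s.design,
        "m_per_group": s.m_per_group,
        "n_days": s.n_days,
        "alpha": s.alpha,
        "K": s.K,
        "seed": s.seed,
        "runtime_s": round(s.runtime_s, 2),
        "rng": f"SeedSequence([{s.seed}, iteration]) per iteration",
        "models": {
            tag: {
                "rejections": m.rejections,
                "t1er": m.t1er,
                "chisq_stat": m.chisq_stat,
                "chisq_p": m.chisq_p,
                "n_flagged": m.n_flagged,
            }
            for tag, m in s.models.items()
        },
    }


# ----------------------------------------------------------------------
# Figures
# ----------------------------------------------------------------------

def render_distribution_figure(
    data: ExperimentData, out_path: str | Path, rng: np.random.Generator | None = None
) -> Path | None:
    """Six-panel figure for one simulated trial.

    A: baseline weight by group; B: baseline intake; C: intake on a randomly
    selected day (pf truncation visible); D: group mean intake over time;
    E: within-animal mean intake; F: weight change.
    """
    rng = rng or np.random.default_rng(0)
    cohort = data.cohort
    is_pf = cohort.is_pf
    realized = data.intakes.realized
    day = int(rng.integers(realized.shape[1]))
    covariate = analysis.compute_within_animal_mean_intake(data.intakes)
    outcome = data.trajectory.weight_change

    fig, axes = plt.subplots(2, 3, figsize=(13, 7))
    panels = [
        ("A  Baseline weight (g)", cohort.weight),
        ("B  Baseline intake (kcal)", cohort.intake),
        (f"C  Intake on day {day + 1} (kcal)", realized[:, day]),
        (None, None),  # panel D is a line plot
        ("E  Within-animal mean intake (kcal)", covariate),
        ("F  Weight change (g)", outcome),
    ]
    for ax, (title, values) in zip(axes.ravel(), panels):
        if title is None:
            continue
        ax.hist(values[~is_pf], bins=15, alpha=0.6, label="non-pair-fed")
        ax.hist(values[is_pf], bins=15, alpha=0.6, label="pair-fed")
        ax.set_title(title, loc="left", fontsize=10)
        ax.legend(fontsize=7)
    ax_d = axes.ravel()[3]
    days = np.arange(1, realized.shape[1] + 1)
    ax_d.plot(days, realized[~is_pf].mean(axis=0), label="non-pair-fed")
    ax_d.plot(days, realized[is_pf].mean(axis=0), label="pair-fed")
    ax_d.set_title("D  Group mean intake by day (kcal)", loc="left", fontsize=10)
    ax_d.set_xlabel("day")
    ax_d.legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def render_comparison_figure(
    comparison: DesignComparison, out_path: str | Path
) -> Path | None:
    """Histograms of per-simulation mean intake differences, both designs."""
    if comparison.group_diffs.size == 0 or comparison.individual_diffs.size == 0:
        logger.info("empty design-comparison vectors; figure skipped")
        return None
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(comparison.group_diffs, bins=40, alpha=0.6, label="group pair-feeding")
    ax.hist(comparison.individual_diffs, bins=40, alpha=0.6, label="individual pair-feeding")
    ax.set_xlabel("mean intake difference, pf - non-pf (kcal/day)")
    ax.set_ylabel("simulations")
    ax.set_title(
        f"t = {comparison.t_stat:.1f}, p = {comparison.t_p:.2e} "
        f"({'Welch' if comparison.welch else 'pooled'})",
        fontsize=10,
    )
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
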