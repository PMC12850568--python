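"""Monte Carlo engine: determinism, chi-square reporting, design comparison,
tables and the CLI surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner
from scipy import stats

from pairfeedsim import (
    GROUP_PF,
    INDIVIDUAL_PF,
    ConfigError,
    DesignConfig,
    compare_designs,
    estimate_t1er,
    expected_daily_deficit,
    run_trial,
)
from pairfeedsim import test_against_nominal as chisq_vs_nominal
from pairfeedsim.cli import main as cli_main
from pairfeedsim.reporting import render_tables, tables_round_trip, write_manifest


class TestRunTrial:
    def test_bit_identical_repetition(self, small_indiv_cfg):
        a = run_trial(small_indiv_cfg, 3)
        b = run_trial(small_indiv_cfg, 3)
        for tag in a.fits:
            assert a.fits[tag].p_value == b.fits[tag].p_value
            assert a.fits[tag].beta1 == b.fits[tag].beta1
        assert a.mean_intake_diff == b.mean_intake_diff

    def test_iterations_use_distinct_streams(self, small_group_cfg):
        a = run_trial(small_group_cfg, 0)
        b = run_trial(small_group_cfg, 1)
        assert a.fits["crude_lm"].p_value != b.fits["crude_lm"].p_value

    def test_design_determines_populated_p_values(self, small_group_cfg, small_indiv_cfg):
        g = run_trial(small_group_cfg, 0)
        assert set(g.fits) == {"crude_lm", "adjusted_lm"}
        assert g.p_pair_lmm is None
        i = run_trial(small_indiv_cfg, 0)
        assert set(i.fits) == {"crude_lm", "adjusted_lm", "pair_lmm", "pair_lmm_adjusted"}
        for fit in i.fits.values():
            assert 0.0 <= fit.p_value <= 1.0

    def test_no_truncation_p_values_uniform(self):
        cfg = DesignConfig(m_per_group=8, n_days=5, design=GROUP_PF,
                           no_truncation=True, n_reps=800, seed=5)
        pvals = [run_trial(cfg, k, models=("crude_lm",)).fits["crude_lm"].p_value
                 for k in range(cfg.n_reps)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestChiSquareReporting:
    def test_observed_equals_expected_gives_zero_statistic(self):
        stat, p = chisq_vs_nominal(500, 10_000, 0.05)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_inflation_is_astronomically_significant(self):
        stat, p = chisq_vs_nominal(4251, 10_000, 0.05)
        assert p < 2.2e-16

    def test_moderate_inflation_p_value(self):
        # 626 rejections of 10,000 at alpha 0.05
        stat, p = chisq_vs_nominal(626, 10_000, 0.05)
        assert p == pytest.approx(7.414e-9, rel=1e-3)

    def test_agrees_with_exact_binomial_classification(self):
        for count in (4251, 475, 1155, 494, 6943, 7137, 491, 1720, 626, 500, 560):
            _, chi_p = chisq_vs_nominal(count, 10_000, 0.05)
            bin_p = stats.binomtest(count, 10_000, 0.05).pvalue
            assert (chi_p < 0.001) == (bin_p < 0.001)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            chisq_vs_nominal(0, 0, 0.05)


class TestEstimateT1Er:
    def test_summary_bookkeeping(self):
        cfg = DesignConfig(m_per_group=4, n_days=4, design=GROUP_PF, n_reps=120, seed=2)
        summary, iterations = estimate_t1er(cfg, collect=True)
        for m in summary.models.values():
            assert m.t1er == m.rejections / cfg.n_reps
            assert 0.0 <= m.chisq_p <= 1.0
        assert summary.intake_diffs.shape == (120,)
        assert set(iterations.columns) >= {
            "iteration", "design", "m", "n", "model_tag", "beta1", "se",
            "p_value", "converged_flag", "mean_intake_diff",
        }
        assert len(iterations) == 120 * 2

    def test_reproducible_across_runs(self):
        cfg = DesignConfig(m_per_group=4, n_days=4, design=GROUP_PF, n_reps=60, seed=3)
        a = estimate_t1er(cfg)
        b = estimate_t1er(cfg)
        assert {t: m.rejections for t, m in a.models.items()} == \
               {t: m.rejections for t, m in b.models.items()}
        np.testing.assert_array_equal(a.intake_diffs, b.intake_diffs)

    def test_unadjusted_inflation_grows_with_sample_size(self):
        # at 80 animals the bias/SE ratio is larger than at 16 animals
        rates = {}
        for m in (8, 40):
            cfg = DesignConfig(m_per_group=m, n_days=15, design=GROUP_PF,
                               n_reps=2000, seed=6)
            rates[m] = estimate_t1er(cfg, models=("crude_lm",)).t1er("crude_lm")
        assert rates[40] > rates[8]


class TestCompareDesigns:
    def test_no_truncation_differences_center_at_zero(self):
        cfg_g = DesignConfig(m_per_group=8, n_days=10, design=GROUP_PF,
                             no_truncation=True, n_reps=400, seed=8)
        cfg_i = cfg_g.replace(design=INDIVIDUAL_PF, seed=9)
        comp = compare_designs(cfg_g, cfg_i)
        se_g = comp.group_sd / np.sqrt(comp.group_diffs.size)
        assert abs(comp.group_mean) < 4 * se_g
        assert comp.t_p > 0.01

    def test_individual_deficit_larger_and_significant(self):
        cfg_g = DesignConfig(m_per_group=40, n_days=50, design=GROUP_PF,
                             n_reps=200, seed=10)
        cfg_i = cfg_g.replace(design=INDIVIDUAL_PF, seed=11)
        comp = compare_designs(cfg_g, cfg_i)
        assert comp.individual_mean < comp.group_mean < 0
        assert comp.t_p < 1e-10
        assert -comp.group_mean == pytest.approx(expected_daily_deficit(cfg_g), abs=0.002)
        assert -comp.individual_mean == pytest.approx(expected_daily_deficit(cfg_i), abs=0.002)

    def test_mismatched_configs_rejected(self):
        cfg_g = DesignConfig(m_per_group=8, n_days=10, design=GROUP_PF, n_reps=10)
        with pytest.raises(ConfigError):
            compare_designs(cfg_g, cfg_g.replace(design=INDIVIDUAL_PF, n_days=5))


class TestTables:
    def _summaries(self):
        out = []
        for m, n in [(8, 5), (4, 3)]:
            cfg = DesignConfig(m_per_group=m, n_days=n, design=GROUP_PF, n_reps=40,
                               seed=12)
            out.append(estimate_t1er(cfg))
        return out

    def test_group_table_layout(self, tmp_path):
        frame = render_tables(self._summaries(), tmp_path)
        assert list(frame["n_animals"]) == [16, 8]
        for col in ("Model_1", "Model_2", "p_value_1", "p_value_2"):
            assert col in frame.columns
        assert (tmp_path / "t1er_tables.csv").exists()
        assert (tmp_path / "t1er_tables.json").exists()

    def test_json_csv_json_round_trip_identity(self, tmp_path):
        frame = render_tables(self._summaries(), tmp_path)
        back = tables_round_trip(tmp_path / "t1er_tables.json")
        back.to_csv(tmp_path / "again.csv", index=False)
        import pandas as pd

        again = pd.read_csv(tmp_path / "again.csv")
        pd.testing.assert_frame_equal(
            frame.reset_index(drop=True), again, check_dtype=False
        )

    def test_manifest_round_trip(self, tmp_path):
        write_manifest(tmp_path / "m.json", {"seed": 3, "scenarios": []})
        payload = json.loads((tmp_path / "m.json").read_text())
        assert payload["seed"] == 3


class TestCli:
    def test_simulate_writes_summary_and_iterations(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--design", "group_pf", "-m", "4", "-n", "3",
             "--reps", "25", "--seed", "1", "--out", str(tmp_path), "--dump-intakes"],
        )
        assert result.exit_code == 0, result.output
        for name in ("summary.csv", "summary.json", "iterations.csv",
                     "manifest.json", "intakes_iter0.csv"):
            assert (tmp_path / name).exists()

    def test_config_file_with_flag_override(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text("m_per_group: 4\nn_days: 3\nn_reps: 10\n")
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--config", str(tmp_path / "cfg.yaml"), "--reps", "15",
             "--seed", "2", "--out", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["config"]["m_per_group"] == 4
        assert manifest["config"]["n_reps"] == 15  # flag wins over file

    def test_compare_designs_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["compare-designs", "-m", "6", "-n", "5", "--reps", "50",
             "--seed", "3", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads((tmp_path / "design_comparison.json").read_text())
        assert payload["individual_mean"] < 0

    def test_figures_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["figures", "--design", "individual_pf", "-m", "6", "-n", "8",
             "--reps", "40", "--seed", "4", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "distributions_individual_pf.png").exists()
        assert (tmp_path / "design_comparison.png").exists()
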