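"""Scenario engine: full published-table reproduction, sweeps, CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from brainpbpk import (ScenarioSpec, run_scenario, run_table, parameter_sweep,
                       packaged_scenarios, builtin_parameters)
from brainpbpk.cli import main as cli_main
from brainpbpk.scenarios import pct_change, fold, TABLE_COLUMNS
from conftest import assert_printed
from published_tables import PROPRANOLOL_ROWS, IMIPRAMINE_ROWS, WIDENED_CELLS


class TestRunScenario:
    def test_active_efflux_scenario(self):
        rep = run_scenario(ScenarioSpec(label="aet", base="propranolol",
                                        overrides={"k4": 9.4}))
        assert_printed(rep.steady.LF, "20.6")
        assert_printed(rep.steady.LM, "2.1")

    def test_metabolism_scenario(self):
        rep = run_scenario(ScenarioSpec(label="met", base="imipramine",
                                        overrides={"k9": 6}))
        assert_printed(rep.steady.LF, "25.6")
        assert_printed(rep.steady.LM, "6.78")

    def test_self_comparison_is_zero(self):
        spec = ScenarioSpec(label="basal", base="propranolol")
        rep = run_scenario(spec)
        cmp = rep.compare(rep)
        assert cmp == {"pct_LF": 0.0, "pct_LM": 0.0}

    def test_unknown_override_key_named(self):
        with pytest.raises(KeyError, match="k42"):
            ScenarioSpec(label="x", base="propranolol", overrides={"k42": 1})

    def test_percent_and_fold_conventions(self):
        assert pct_change(20.6, 10.2) == pytest.approx(101.96, abs=0.01)
        assert fold(50, 10) == 5
        assert np.isnan(pct_change(1.0, 0.0)) and np.isnan(fold(1.0, 0.0))


class TestPublishedTableReproduction:
    @pytest.mark.parametrize("drug,printed", [
        ("propranolol", PROPRANOLOL_ROWS),
        ("imipramine", IMIPRAMINE_ROWS),
    ])
    def test_every_cell_matches_printed_table(self, drug, printed):
        """All 90 numeric cells per drug, at one unit of the last printed
        digit (tables are rounded)."""
        specs = {s.label: s for s in packaged_scenarios(drug)}
        df = run_table([specs[label] for label in printed]).set_index("label")
        cols = TABLE_COLUMNS[:6] + ["LM", "PL", "PF", "Kp_brain"]
        for label, cells in printed.items():
            row = df.loc[label]
            for col, cell in zip(cols, cells):
                units = WIDENED_CELLS.get((label, col), 1.0)
                assert_printed(row[col], cell, units=units)

    def test_prose_reference_comparisons(self):
        """Headline enhancement figures: ~102% and ~258% for propranolol,
        18- and 31-fold for imipramine (printed values are rounded, so the
        tolerance propagates the half-unit rounding of each operand)."""
        prop = {s.label: run_scenario(s) for s in packaged_scenarios(
            "propranolol")[:3]}
        imip = {s.label: run_scenario(s) for s in packaged_scenarios(
            "imipramine")[:3]}
        assert prop["sim1_basal"].pct_lf_vs_lf0 == pytest.approx(102, abs=2)
        assert prop["sim3_cancer_plasma_proteins"].pct_lf_vs_lf0 == \
            pytest.approx(258, abs=5)
        assert imip["sim11_basal"].fold_lf_vs_lf0 == pytest.approx(18, abs=0.5)
        assert imip["sim13_cancer_plasma_proteins"].fold_lf_vs_lf0 == \
            pytest.approx(31, abs=0.5)

    def test_supplementary_kp_values(self):
        """Reduced brain tissue protein lowers K_p,brain: 2.1 at 1,000 nM,
        1.2 at 500 nM (vs 9.8 basal); extreme k5 values bracket basal."""
        specs = {s.label: s for s in packaged_scenarios("propranolol")}
        kp = {lbl: run_scenario(specs[lbl]).steady.Kp_brain
              for lbl in ("supp_PT_1000", "supp_PT_500", "supp_k5_x10",
                          "supp_k5_div10", "sim30_no_plasma_binding")}
        assert kp["supp_PT_1000"] == pytest.approx(2.1, abs=0.1)
        assert kp["supp_PT_500"] == pytest.approx(1.2, abs=0.1)
        assert kp["supp_k5_x10"] > 9.8 > kp["supp_k5_div10"]
        s30 = run_scenario(specs["sim30_no_plasma_binding"]).steady
        assert s30.arterial.LF0 == pytest.approx(100, rel=1e-9)
        assert s30.LF == pytest.approx(100, rel=1e-9)
        assert s30.LM == pytest.approx(100, rel=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_table([])

    def test_failed_scenario_isolated_in_batch(self):
        good = ScenarioSpec(label="ok", base="propranolol")
        bad = ScenarioSpec(label="bad", base="nonexistent_file.json")
        df = run_table([good, bad])
        assert df.loc[df.label == "ok", "error"].item() == ""
        assert "bad" in df.loc[df.label == "bad", "error"].item() \
            or df.loc[df.label == "bad", "error"].item() != ""


class TestParameterSweep:
    def test_pt_sweep_leaves_lm_constant(self):
        base = builtin_parameters("propranolol")
        df = parameter_sweep(base, "PT", np.linspace(100, 10_000, 12))
        assert np.ptp(df["LM"]) <= 1e-9 * df["LM"].mean()
        assert df["PL"].is_monotonic_increasing

    def test_pt_sweep_kp_values(self):
        base = builtin_parameters("propranolol")
        df = parameter_sweep(base, "PT", [500, 1_000, 5_000]).set_index("PT")
        assert df.loc[500, "Kp_brain"] == pytest.approx(1.2, abs=0.1)
        assert df.loc[1_000, "Kp_brain"] == pytest.approx(2.1, abs=0.1)
        assert df.loc[5_000, "Kp_brain"] == pytest.approx(9.8, abs=0.1)

    def test_metabolism_sweep_decreases_lm(self):
        base = builtin_parameters("propranolol")
        df = parameter_sweep(base, "k9", [0, 6])
        assert df["LM"].iloc[1] < df["LM"].iloc[0]

    def test_unknown_field_rejected(self):
        with pytest.raises(KeyError, match="bogus"):
            parameter_sweep(builtin_parameters("propranolol"), "bogus", [1])


class TestCli:
    def test_steady_subcommand(self, tmp_path):
        out = tmp_path / "report.csv"
        res = CliRunner().invoke(cli_main, ["steady", "--drug", "propranolol",
                                            "--set", "k4=9.4",
                                            "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert out.exists()
        import pandas as pd
        df = pd.read_csv(out)
        assert df["LM"].iloc[0] == pytest.approx(2.06, abs=0.01)

    def test_sweep_subcommand(self, tmp_path):
        out = tmp_path / "sweep.csv"
        res = CliRunner().invoke(cli_main, ["sweep", "--drug", "propranolol",
                                            "--param", "PT",
                                            "--values", "500,1000,5000",
                                            "--out", str(out)])
        assert res.exit_code == 0, res.output
        import pandas as pd
        assert len(pd.read_csv(out)) == 3

    def test_table_subcommand_deterministic(self, tmp_path):
        """Identical spec files produce bit-identical CSV output."""
        import importlib.resources as resources
        src = resources.files("brainpbpk.data") / "scenarios" / \
            "imipramine_simulations.yaml"
        spec_file = tmp_path / "specs.yaml"
        spec_file.write_text(src.read_text())
        outs = []
        for name in ("a.csv", "b.csv"):
            out = tmp_path / name
            res = CliRunner().invoke(cli_main, ["table", "--specs",
                                                str(spec_file),
                                                "--out", str(out)])
            assert res.exit_code == 0, res.output
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_unknown_drug_fails_nonzero(self):
        res = CliRunner().invoke(cli_main, ["steady", "--drug", "aspirin"])
        assert res.exit_code != 0
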