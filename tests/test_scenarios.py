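"""Scenario configs, presets, sweeps and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from gliocart import (
    Scenario,
    build_her2_schedule,
    list_presets,
    load_preset,
    run_scenario,
    run_sweep,
    scenario_from_config,
)
from gliocart.cli import main
from gliocart.scenarios import parse_endpoint, parse_schedule

SHORT_CFG = """
name = smoke
model = delay
schedule = egfr:5e8
horizon = 30
endpoints = value_at:T:30, peak_time:C
param.tau = 2
"""


class TestConfigParsing:
    def test_round_trip_scenario(self):
        s = scenario_from_config(SHORT_CFG)
        assert s.name == "smoke"
        assert s.model == "delay"
        assert s.schedule.entries == ((0.0, 5e8),)
        assert s.endpoints == ("value_at:T:30", "peak_time:C")

    def test_invalid_key_named_in_error(self):
        with pytest.raises(ValueError, match="banana"):
            scenario_from_config(SHORT_CFG + "banana = 1\n")

    def test_unknown_param_override_rejected(self):
        with pytest.raises(ValueError, match="param.gamma"):
            scenario_from_config(SHORT_CFG + "param.gamma = 1\n")

    def test_missing_required_keys(self):
        with pytest.raises(ValueError, match="missing"):
            scenario_from_config("name = x\nmodel = delay\n")

    @pytest.mark.parametrize("tok,err", [
        ("nope", "unknown endpoint"),
        ("value_at:T", "value_at"),
        ("first_above:T", "first_above"),
    ])
    def test_endpoint_parse_errors(self, tok, err):
        with pytest.raises(ValueError, match=err):
            parse_endpoint(tok)

    def test_schedule_strings(self):
        assert parse_schedule("her2:1e8:2:42").entries == (
            (0.0, 1e8), (42.0, 1e8), (84.0, 1e8),
        )
        assert parse_schedule("0:2e6,7:1e7").entries == ((0.0, 2e6), (7.0, 1e7))
        with pytest.raises(ValueError):
            parse_schedule("her2:1e8")

    def test_scenario_invariants(self):
        with pytest.raises(ValueError, match="horizon"):
            Scenario(name="x", model="delay",
                     schedule=build_her2_schedule(1e8, 6, 84), horizon=100.0)
        with pytest.raises(ValueError, match="model"):
            Scenario(name="x", model="gompertz",
                     schedule=build_her2_schedule(1e8, 0, 42), horizon=100.0)


class TestPresets:
    def test_all_presets_load(self):
        names = list_presets()
        assert {"fig2-il13", "fig4-her2-high", "fig5-egfr", "fig9-sweep"} <= set(names)
        for name in names:
            loaded = load_preset(name)
            if name.endswith("-sweep"):
                assert loaded["kind"] == "sweep"
            else:
                assert isinstance(loaded, Scenario)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            load_preset("fig99")


class TestRunScenario:
    def test_deterministic_byte_identical_output(self, tmp_path):
        s = scenario_from_config(SHORT_CFG)
        run_scenario(s, outdir=tmp_path / "a")
        run_scenario(s, outdir=tmp_path / "b")
        assert (tmp_path / "a/smoke.csv").read_bytes() == (
            tmp_path / "b/smoke.csv"
        ).read_bytes()
        recs = json.loads((tmp_path / "a/smoke.endpoints.json").read_text())
        assert {r["endpoint"] for r in recs} == {"value_at:T:30", "peak_time:C"}

    def test_single_cell_sweep_matches_scenario(self):
        table = run_sweep(
            "her2", endpoint="value_at:T:60",
            doses=[1.89e8], n_additional=[0], intervals=[42.0],
            horizon=60.0, dt=0.01,
        )
        assert len(table) == 1
        s = Scenario(
            name="cell", model="delay",
            schedule=build_her2_schedule(1.89e8, 0, 42), horizon=60.0,
            endpoints=("value_at:T:60",),
        )
        direct = run_scenario(s).endpoints["value_at:T:60"]["value"]
        assert table.value.iloc[0] == direct

    def test_sweep_row_complete_with_censoring_flag(self):
        table = run_sweep(
            "her2", endpoint="ttp",
            doses=[1.89e8], n_additional=[0, 1], intervals=[42.0, 84.0],
            horizon=120.0, dt=0.05,
        )
        assert len(table) == 4
        assert set(table.columns) == {"dose", "n_additional", "interval",
                                      "value", "censored"}
        # TTP beyond a 120-day horizon for this dose: censored, not dropped
        assert table.censored.any()


class TestSweepOptima:
    def test_high_dose_prefers_long_intervals(self):
        # day-540 burden, highest dose: six additional doses every 12 weeks
        # beat one additional dose and shorter intervals
        table = run_sweep(
            "her2", endpoint="value_at:T:540",
            doses=[1.89e8], n_additional=[1, 6], intervals=[42.0, 84.0],
            horizon=540.0,
        )
        best = table.loc[table.value.idxmin()]
        assert best.n_additional == 6 and best.interval == 84.0

    def test_lowest_dose_longest_interval_maximizes_ttp(self):
        # seven-dose interval sweep: 7.23e7 cells every 15 weeks wins
        table = run_sweep(
            "her2", endpoint="ttp",
            doses=[7.23e7, 1e8, 1.89e8], n_additional=[6],
            intervals=[49.0, 84.0, 105.0], horizon=2500.0,
        )
        assert not table.censored.any()
        best = table.loc[table.value.idxmax()]
        assert best.dose == 7.23e7 and best.interval == 105.0


class TestCli:
    def test_presets_list(self):
        res = CliRunner().invoke(main, ["presets", "list"])
        assert res.exit_code == 0
        assert "fig5-egfr" in res.output

    def test_simulate_config(self, tmp_path):
        cfg = tmp_path / "s.cfg"
        cfg.write_text(SHORT_CFG)
        res = CliRunner().invoke(
            main, ["simulate", "--config", str(cfg), "--out", str(tmp_path / "out")]
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out/smoke.csv").exists()
        assert "value_at:T:30" in res.output

    def test_simulate_rejects_bad_config(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text(SHORT_CFG + "banana = 1\n")
        res = CliRunner().invoke(main, ["simulate", "--config", str(cfg)])
        assert res.exit_code != 0
        assert "banana" in res.output

    def test_sweep_and_morris_commands(self, tmp_path):
        cfg = tmp_path / "sw.cfg"
        cfg.write_text(
            "kind = sweep\nfamily = her2\nendpoint = value_at:T:60\n"
            "doses = 1.89e8\nn_additional = 0\nintervals = 42\n"
            "horizon = 60\ndt = 0.05\n"
        )
        res = CliRunner().invoke(
            main, ["sweep", "--config", str(cfg), "--out", str(tmp_path / "sw.csv")]
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "sw.csv").exists()

        res = CliRunner().invoke(
            main,
            ["morris", "--model", "delay", "--r", "2", "--dt", "0.1",
             "--seed", "3", "--out", str(tmp_path / "m.csv")],
        )
        assert res.exit_code == 0, res.output
        header = (tmp_path / "m.csv").read_text().splitlines()[0]
        assert header == "input,mu_star,sigma,mu_star_norm,sigma_norm,output"
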