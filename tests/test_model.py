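"""Model/results interface, CSV round trips and the command-line pipeline."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from flowcascade import FlowAbundanceCascade, ScenarioConfig, generate_scenario
from flowcascade import io
from flowcascade.cli import main


class TestFitResults:
    def test_sr_cardinality_and_weights(self, mountainous_results):
        res = mountainous_results
        counts = res.sr.groupby(["species_id", "horizon"]).size()
        assert (counts == 16).all()
        w = res.weights["weight"].to_numpy()
        assert w.min() == 1.0 and w.max() == 2.0 and len(w) == 16
        assert not res.uniform_weights

    def test_species_summary_is_consistent_with_sr(self, mountainous_results):
        res = mountainous_results
        row = res.species_summary.iloc[0]
        grp = res.sr[(res.sr["species_id"] == row["species_id"])
                     & (res.sr["horizon"] == row["horizon"])]
        assert row["mean"] == pytest.approx(grp["sr_pct"].mean())
        assert row["min"] <= row["weighted_mean"] <= row["max"]
        assert row["weighted_mean"] == pytest.approx(
            res.weighted_sr(row["species_id"], row["horizon"])
        )

    def test_flow_summary_has_both_horizons(self, mountainous_results):
        assert set(mountainous_results.flow_summary["horizon"]) == {"h2050", "h2090"}

    def test_trait_groups_cover_all_species(self, mountainous_results):
        res = mountainous_results
        n_species = res.sr["species_id"].nunique()
        per_trait = res.assignments.groupby("trait").size()
        assert (per_trait == n_species).all()
        assert (res.coverage["coverage"] == 1.0).all()

    def test_summary_text_mentions_key_facts(self, mountainous_results):
        text = mountainous_results.summary()
        assert "climate models:       16" in text
        assert "baseline 1998-2017" in text
        assert "h2090" in text

    def test_refit_is_deterministic(self, mountainous_data):
        res1 = FlowAbundanceCascade.from_scenario(mountainous_data).fit()
        res2 = FlowAbundanceCascade.from_scenario(mountainous_data).fit()
        pd.testing.assert_frame_equal(res1.sr, res2.sr)
        pd.testing.assert_frame_equal(res1.weights, res2.weights)

    def test_no_observed_series_falls_back_to_uniform(self, mountainous_data):
        discharge = {k: v for k, v in mountainous_data.discharge.items()
                     if k[1] != "observed"}
        model = FlowAbundanceCascade(
            discharge=discharge, sites=mountainous_data.sites,
            curves=mountainous_data.curves, occurrences=mountainous_data.occurrences,
        )
        res = model.fit()
        assert res.uniform_weights
        row = res.species_summary.iloc[0]
        assert row["weighted_mean"] == pytest.approx(row["mean"])

    def test_to_csv_writes_all_tables(self, mountainous_results, tmp_path):
        paths = mountainous_results.to_csv(tmp_path)
        for name in ("sr", "weights", "species_summary", "flags", "group_summary",
                     "manifest"):
            assert paths[name].exists()
        manifest = yaml.safe_load(paths["manifest"].read_text())
        assert manifest["row_counts"]["sr"] == len(mountainous_results.sr)
        assert manifest["scenario"]["seed"] == 1


class TestCSVRoundTrip:
    def test_scenario_csvs_reload_identically(self, tmp_path):
        data = generate_scenario(ScenarioConfig.mountainous(seed=2, n_sites=3,
                                                            n_models=2, n_species=3))
        paths = io.write_scenario_csvs(data, tmp_path)
        discharge = io.read_discharge_csv(paths["discharge"])
        assert set(discharge) == set(data.discharge)
        key = next(iter(discharge))
        assert np.allclose(discharge[key].flow, data.discharge[key].flow)
        sites = io.read_sites_csv(paths["sites"])
        for got, want in zip(sites, data.sites):
            assert got.site_id == want.site_id
            assert got.ecological_status == want.ecological_status
            assert got.flow_accumulation == pytest.approx(want.flow_accumulation)
        curves = io.read_curves_csv(paths["curves"])
        assert set(curves) == set(data.curves)
        for sp in curves:
            assert curves[sp].optimum == pytest.approx(data.curves[sp].optimum)
            assert curves[sp].breadth == pytest.approx(data.curves[sp].breadth)

    def test_from_csv_fit_matches_in_memory_fit(self, tmp_path):
        data = generate_scenario(ScenarioConfig.mountainous(seed=2, n_sites=3,
                                                            n_models=2, n_species=3))
        paths = io.write_scenario_csvs(data, tmp_path)
        res_mem = FlowAbundanceCascade.from_scenario(data).fit()
        res_csv = FlowAbundanceCascade.from_csv(
            paths["discharge"], paths["sites"], paths["curves"],
            paths["occurrences"], paths["traits"],
        ).fit()
        pd.testing.assert_frame_equal(
            res_mem.sr.sort_values(["species_id", "model_id", "horizon"]).reset_index(drop=True),
            res_csv.sr.sort_values(["species_id", "model_id", "horizon"]).reset_index(drop=True),
        )


@pytest.fixture(scope="module")
def cli_data_dir(tmp_path_factory):
    """A small generated study plus all stage outputs, via the CLI."""
    data_dir = tmp_path_factory.mktemp("cli") / "fixture"
    runner = CliRunner()
    result = runner.invoke(main, [
        "generate", "--out", str(data_dir), "--seed", "3",
        "--archetype", "mountainous", "--n-sites", "4", "--n-models", "3",
        "--n-species", "4",
    ])
    assert result.exit_code == 0, result.output
    return data_dir


class TestCLI:
    def test_stagewise_pipeline(self, cli_data_dir):
        runner = CliRunner()
        for args in (["metrics"], ["predict"], ["cascade"], ["ensemble"],
                     ["traits"], ["report"]):
            result = runner.invoke(main, args + ["--data", str(cli_data_dir)])
            assert result.exit_code == 0, f"{args}: {result.output}"
        sr = pd.read_csv(cli_data_dir / "sr.csv")
        assert sr.groupby(["species_id", "horizon"]).size().eq(3).all()
        weights = pd.read_csv(cli_data_dir / "weights.csv")
        assert len(weights) == 3
        assert (cli_data_dir / "flags.csv").exists()

    def test_run_from_scenario_config(self, tmp_path):
        config = {
            "scenario": {"archetype": "mountainous", "seed": 3, "n_sites": 4,
                         "n_models": 3, "n_species": 4},
            "out_dir": str(tmp_path / "out"),
        }
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(config))
        runner = CliRunner()
        result = runner.invoke(main, ["run", "--config", str(cfg_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "sr.csv").exists()
        assert "Flow-abundance uncertainty cascade" in result.output

    def test_run_rejects_ambiguous_config(self, tmp_path):
        cfg_path = tmp_path / "bad.yaml"
        cfg_path.write_text(yaml.safe_dump({"scenario": {}, "inputs": {}}))
        result = CliRunner().invoke(main, ["run", "--config", str(cfg_path)])
        assert result.exit_code != 0
        assert "exactly one" in result.output

    def test_run_aborts_naming_stage_on_missing_file(self, tmp_path):
        config = {
            "inputs": {"discharge": str(tmp_path / "nope.csv"),
                       "sites": str(tmp_path / "nope.csv"),
                       "curves": str(tmp_path / "nope.csv"),
                       "occurrences": str(tmp_path / "nope.csv")},
        }
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(config))
        result = CliRunner().invoke(main, ["run", "--config", str(cfg_path)])
        assert result.exit_code != 0
        assert "run" in result.output
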