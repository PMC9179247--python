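"""Scenario table parsing, single runs, batch execution, summary tables."""

import numpy as np
import pandas as pd
import pytest

import pycmsy as pc
from pycmsy.scenarios import (SUMMARY_COLUMNS, format_summary_table,
                              packaged_scenarios, read_summary_table, run_all,
                              summarize_ensemble, write_summary_table)

MINIMAL_ROW = {
    "run": 1, "label": "demo", "start.yr": 1992, "end.yr": 2020,
    "r.low": 0.045, "r.hi": 0.3, "stb.low": 0.4, "stb.hi": 0.8,
    "intb.yr": 2011, "intb.low": 0.2, "intb.hi": 0.9,
    "endb.low": 0.1, "endb.hi": 0.7, "btype": "None", "force.cmsy": True,
}


class TestLoadScenarios:
    def test_packaged_design_has_fourteen_runs(self):
        configs = packaged_scenarios()
        assert len(configs) == 14
        assert [c.run_id for c in configs] == list(range(1, 15))
        catch_only = [c for c in configs if c.btype == "None"]
        assert {c.run_id for c in catch_only} == {1, 8}
        assert all(c.force_cmsy for c in catch_only)
        # narrower growth-rate cap on the last three runs, as configured
        assert all(c.r_range.high == 0.1 for c in configs if c.run_id >= 12)
        assert all(c.r_range.high == 0.3 for c in configs if c.run_id <= 11)

    def test_end_window_parsed(self):
        cfg = pc.load_scenarios([MINIMAL_ROW])[0]
        assert (cfg.end_window.low, cfg.end_window.high) == (0.1, 0.7)

    def test_missing_column_named_in_error(self):
        row = {k: v for k, v in MINIMAL_ROW.items() if k != "intb.yr"}
        with pytest.raises(ValueError, match="intb.yr"):
            pc.load_scenarios([row])

    def test_intermediate_year_at_start_rejected(self):
        row = dict(MINIMAL_ROW, **{"intb.yr": 1992})
        with pytest.raises(ValueError):
            pc.load_scenarios([row])

    def test_btype_none_requires_force_cmsy(self):
        row = dict(MINIMAL_ROW, **{"force.cmsy": False})
        with pytest.raises(ValueError):
            pc.load_scenarios([row])

    def test_yaml_text_round_trip(self):
        import yaml
        text = yaml.safe_dump({"runs": [MINIMAL_ROW]})
        cfg = pc.load_scenarios(text)[0]
        assert cfg.label == "demo"
        assert cfg.r_range.high == 0.3

    def test_truncation_preserves_catch_values(self, fixture_data):
        catches, _ = fixture_data
        sub = catches.truncate(1992, 2020)
        keep = (catches.years >= 1992) & (catches.years <= 2020)
        np.testing.assert_array_equal(sub.catch, catches.catch[keep])


class TestRunScenario:
    def test_summary_ratios_are_per_draw_medians(self, cmsy_run):
        ensemble, row, config = cmsy_run
        b_final = ensemble.biomass[:, -1]
        f_final = ensemble.catch_effective[:, -1] / b_final
        # recompute from the serialized ensemble: F/Fmsy = median of (C/B)/(r/2)
        assert row.F_Fmsy == pytest.approx(
            float(np.median(f_final / (ensemble.r / 2.0))), rel=1e-12)
        assert row.B_Bmsy == pytest.approx(
            float(np.median(b_final / (ensemble.k / 2.0))), rel=1e-12)
        assert row.MSY == pytest.approx(
            float(np.median(ensemble.r * ensemble.k / 4.0)), rel=1e-12)

    def test_same_seed_identical_summary(self, nominal_data):
        catches, lib = nominal_data
        config = packaged_scenarios()[7]  # catch-only short series
        _, row1 = pc.run_scenario(config, catches, lib,
                                  settings=pc.SamplerSettings.fast(seed=21))
        _, row2 = pc.run_scenario(config, catches, lib,
                                  settings=pc.SamplerSettings.fast(seed=21))
        assert row1 == row2

    def test_force_cmsy_run_marks_mode_and_ignores_index(self, nominal_data):
        catches, lib = nominal_data
        config = packaged_scenarios()[7]
        ensemble, row = pc.run_scenario(config, catches, lib,
                                        settings=pc.SamplerSettings.fast(seed=4))
        assert row.mode == "CMSY"
        assert ensemble.index_labels == ()

    def test_missing_index_is_an_error(self, nominal_data):
        catches, _ = nominal_data
        config = packaged_scenarios()[10]  # needs the JP index
        with pytest.raises(ValueError, match="JP"):
            pc.run_scenario(config, catches, {}, settings=pc.SamplerSettings.fast(seed=1))

    def test_start_year_truncation_applied_before_fit(self, fixture_data):
        catches, lib = fixture_data
        config = packaged_scenarios()[7]  # 1992 start on the 1971 series
        ensemble, row = pc.run_scenario(config, catches, lib,
                                        settings=pc.SamplerSettings.fast(seed=2))
        assert row.start_year == 1992
        assert int(ensemble.years[0]) == 1992


class TestRunAll:
    def _small_settings(self, seed):
        return pc.SamplerSettings.fast(seed=seed, n_steps=400, min_draws=100)

    def test_subset_executes_and_orders_rows(self, fixture_data):
        catches, lib = fixture_data
        configs = [c for c in packaged_scenarios() if c.run_id in (1, 4, 8)]
        table = run_all(configs[::-1], catches, lib, seed=3,
                        settings_factory=self._small_settings)
        assert list(table["run"]) == [1, 4, 8]
        assert list(table.columns) == SUMMARY_COLUMNS
        assert table.attrs["errors"] == []

    def test_order_invariance(self, fixture_data):
        catches, lib = fixture_data
        configs = [c for c in packaged_scenarios() if c.run_id in (1, 8)]
        fwd = run_all(configs, catches, lib, seed=3, settings_factory=self._small_settings)
        rev = run_all(configs[::-1], catches, lib, seed=3, settings_factory=self._small_settings)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_empty_config_list(self, fixture_data):
        catches, lib = fixture_data
        table = run_all([], catches, lib, seed=1)
        assert len(table) == 0

    def test_failing_run_reported_not_fatal(self, fixture_data):
        catches, _ = fixture_data
        configs = [c for c in packaged_scenarios() if c.run_id in (1, 4)]
        table = run_all(configs, catches, indices={}, seed=3,
                        settings_factory=self._small_settings)
        assert list(table["run"]) == [1]       # the index-less BSM run is skipped
        errs = table.attrs["errors"]
        assert len(errs) == 1 and errs[0]["run"] == 4


class TestSummaryTables:
    def test_write_read_round_trip(self, cmsy_run, tmp_path):
        _, row, _ = cmsy_run
        table = pd.DataFrame([row.as_dict()], columns=SUMMARY_COLUMNS)
        path = tmp_path / "summary.tsv"
        write_summary_table(table, path)
        back = read_summary_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_formatting_conventions(self):
        table = pd.DataFrame([{
            "run": 1, "label": "x", "start_year": 1971, "end_year": 2020,
            "mode": "CMSY", "converged": True,
            "r": 0.0741234, "K": 2026.8, "MSY": 37.4995, "Bmsy": 1013.4,
            "B": 652.3, "B_Bmsy": 1.28765, "F": 0.021456, "Fmsy": 0.0370617,
            "F_Fmsy": 0.716253,
        }])
        out = format_summary_table(table)
        assert out.loc[0, "r"] == 0.0741
        assert out.loc[0, "K"] == 2027          # integers at the kt-thousands scale
        assert out.loc[0, "B"] == 652.0         # 3 significant figures below 1000
        assert out.loc[0, "B_Bmsy"] == 1.29
        assert out.loc[0, "F_Fmsy"] == 0.716
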