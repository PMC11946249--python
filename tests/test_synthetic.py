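"""Generator contracts: determinism, duplicates, and the closed-form
expected-cell oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from faerspv import synthetic
from faerspv.signal_stats import ror
from faerspv.synthetic import ConfigError, SignalSpec, SimulationConfig


def small_config(**overrides):
    base = dict(
        n_reports=2000,
        drug_vocab=[("drug x", 0.05, ["drug x"])],
        event_vocab=[("ev a", 0.5, ""), ("ev b", 0.5, "")],
        seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestGenerate:
    def test_no_duplicates_means_one_primaryid_per_case(self):
        tables = synthetic.generate(small_config(duplicate_rate=0.0))
        demo = tables.frames["DEMO"]
        assert demo.caseid.nunique() == demo.primaryid.nunique() == 2000

    def test_duplicates_are_later_resubmissions_of_existing_cases(self):
        tables = synthetic.generate(small_config(duplicate_rate=0.3))
        demo = tables.frames["DEMO"]
        assert demo.caseid.nunique() == 2000
        dups = demo[demo.duplicated("caseid", keep=False)].sort_values("primaryid")
        assert len(dups) > 0
        for _, grp in dups.groupby("caseid"):
            assert len(grp) == 2
            rows = sorted(grp.itertuples(index=False), key=lambda r: r.primaryid)
            assert rows[1].fda_dt > rows[0].fda_dt

    def test_same_seed_same_tables(self):
        cfg = synthetic.default_study_config(n_reports=3000, seed=11)
        t1 = synthetic.generate(cfg)
        t2 = synthetic.generate(cfg)
        for kind in t1.frames:
            pd.testing.assert_frame_equal(t1.frames[kind], t2.frames[kind])

    def test_write_tables_byte_identical_across_runs(self, tmp_path):
        cfg = synthetic.default_study_config(n_reports=1500, seed=4)
        p1 = synthetic.write_tables(synthetic.generate(cfg), tmp_path / "a")
        p2 = synthetic.write_tables(synthetic.generate(cfg), tmp_path / "b")
        for kind in p1:
            assert p1[kind].read_bytes() == p2[kind].read_bytes()

    def test_injected_pair_count_matches_closed_form(self, one_pt_config):
        # expected a = n p_d q_d(pt): 100000 * 0.01 * (5*0.02)/(1+0.02*4) ~ 92.6
        exp = synthetic.expected_table(one_pt_config, "drug x", "target event")
        assert exp.a == pytest.approx(100_000 * 0.01 * 0.1 / 1.08, rel=1e-12)
        tables = synthetic.generate(one_pt_config)
        drug = tables.frames["DRUG"]
        reac = tables.frames["REAC"]
        with_drug = set(drug[drug.drugname.isin(["drug x", "BRAND X"])].primaryid)
        a_obs = sum(
            pid in with_drug and pt == "target event"
            for pid, pt in zip(reac.primaryid, reac.pt)
        )
        p = exp.a / one_pt_config.n_reports
        sigma = math.sqrt(one_pt_config.n_reports * p * (1 - p))
        assert abs(a_obs - exp.a) < 4 * sigma

    @pytest.mark.parametrize(
        "overrides, fragment",
        [
            (dict(n_reports=0), "n_reports"),
            (dict(duplicate_rate=1.5), "duplicate_rate"),
            (dict(missing_age_rate=-0.1), "missing_age_rate"),
            (dict(pts_per_report=0.5), "pts_per_report"),
            (
                dict(drug_vocab=[("a", 0.7, ["a"]), ("b", 0.6, ["b"])]),
                "drug marginal",
            ),
            (
                dict(event_vocab=[("ev a", 0.5, ""), ("ev b", 0.2, "")]),
                "background probabilities",
            ),
            (
                dict(signals=[SignalSpec("nope", "ev a", 2.0)]),
                "unknown drug",
            ),
            (
                dict(signals=[SignalSpec("drug x", "ev a", -1.0)]),
                "reporting_rate_ratio",
            ),
        ],
    )
    def test_invalid_config_names_violated_invariant(self, overrides, fragment):
        with pytest.raises(ConfigError, match=fragment):
            synthetic.generate(small_config(**overrides))


class TestExpectedTable:
    def test_null_model_expected_ror_is_one(self):
        cfg = small_config(signals=[])
        t = synthetic.expected_table(cfg, "drug x", "ev a")
        assert ror(t).ror == pytest.approx(1.0, abs=1e-12)

    def test_cells_sum_to_report_count(self, one_pt_config):
        t = synthetic.expected_table(one_pt_config, "drug x", "target event")
        assert t.n == pytest.approx(one_pt_config.n_reports)

    def test_unknown_drug_or_pt_raises(self, one_pt_config):
        with pytest.raises(KeyError):
            synthetic.expected_table(one_pt_config, "nope", "target event")
        with pytest.raises(KeyError):
            synthetic.expected_table(one_pt_config, "drug x", "nope")

    def test_multi_pt_config_refused(self):
        cfg = small_config(pts_per_report=2.0)
        with pytest.raises(ValueError, match="pts_per_report"):
            synthetic.expected_table(cfg, "drug x", "ev a")

    def test_empirical_cells_converge_to_expectation(self):
        # large-n agreement between sampled cells and the exact expectation
        events = [("ev a", 0.02, "")] + [(f"f{i}", 0.98 / 14, "") for i in range(14)]
        cfg = SimulationConfig(
            n_reports=1_000_000,
            drug_vocab=[("drug x", 0.01, ["drug x"])],
            event_vocab=events,
            signals=[SignalSpec("drug x", "ev a", 5.0)],
            pts_per_report=1.0,
            seed=42,
        )
        exp = synthetic.expected_table(cfg, "drug x", "ev a")
        tables = synthetic.generate(cfg)
        drug, reac = tables.frames["DRUG"], tables.frames["REAC"]
        with_drug = set(drug[drug.drugname == "drug x"].primaryid)
        with_event = set(reac[reac.pt == "ev a"].primaryid)
        n = cfg.n_reports
        a = len(with_drug & with_event)
        b = len(with_drug) - a
        c = len(with_event) - a
        d = n - a - b - c
        for obs, expected in [(a, exp.a), (b, exp.b), (c, exp.c), (d, exp.d)]:
            assert abs(obs - expected) / expected < 0.05
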