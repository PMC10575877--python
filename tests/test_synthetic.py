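"""The synthetic-data generator: structure, determinism, and moments."""

import json

import numpy as np
import pandas as pd
import pytest

import thermocog as tc
from thermocog.data_model import DOMAINS
from thermocog.synthetic import (LagResponse, QuadraticResponse,
                                 SyntheticConfig, SyntheticTruth,
                                 gen_county_graph, gen_exposures, gen_records,
                                 write_dataset)


class TestCountyGraph:
    def test_2x2_grid(self):
        g = gen_county_graph(SyntheticConfig(seed=1, n_counties=4,
                                             grid_shape=(2, 2)))
        assert g.n == 4
        assert len(g.edges) == 4

    def test_path_graph(self):
        g = gen_county_graph(SyntheticConfig(seed=1, n_counties=6,
                                             grid_shape=(1, 6)))
        assert len(g.edges) == 5
        degs = sorted(g.degree().values())
        assert degs == [1, 1, 2, 2, 2, 2]

    def test_5x8_lattice_edge_formula(self):
        g = gen_county_graph(SyntheticConfig(seed=1))
        assert g.n == 40
        assert len(g.edges) == 2 * 5 * 8 - 5 - 8  # 67

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not hold"):
            SyntheticConfig(seed=1, n_counties=10, grid_shape=(3, 4))

    def test_connected(self):
        g = gen_county_graph(SyntheticConfig(seed=1))
        assert len(g.components()) == 1


class TestExposures:
    def test_deterministic_same_seed(self):
        cfg = SyntheticConfig(seed=5, n_counties=12, grid_shape=(3, 4),
                              n_months=12)
        g = gen_county_graph(cfg)
        a = gen_exposures(cfg, g)
        b = gen_exposures(cfg, g)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_flat_gradient_hits_range_ends(self):
        cfg = SyntheticConfig(seed=5, n_counties=12, grid_shape=(3, 4),
                              n_months=24, temp_noise_sd=0.0,
                              spatial_gradient=0.0)
        g = gen_county_graph(cfg)
        exp = gen_exposures(cfg, g)
        assert exp["temperature_c"].min() == pytest.approx(-14.0)
        assert exp["temperature_c"].max() == pytest.approx(31.0)
        # all counties share a single sinusoid
        wide = exp.pivot_table(index=["year", "month"], columns="county_id",
                               values="temperature_c")
        assert np.allclose(wide.std(axis=1), 0.0, atol=1e-12)

    def test_full_county_month_coverage(self):
        cfg = SyntheticConfig(seed=6, n_counties=12, grid_shape=(3, 4),
                              n_months=12, lag_buffer=2)
        g = gen_county_graph(cfg)
        exp = gen_exposures(cfg, g)
        assert len(exp) == 12 * (12 + 4)
        assert not exp.duplicated(["county_id", "year", "month"]).any()

    def test_pm25_regression_recovers_coefficient(self):
        cfg = SyntheticConfig(seed=7)
        g = gen_county_graph(cfg)
        exp = gen_exposures(cfg, g)
        t = exp["temperature_c"].to_numpy()
        X = np.column_stack([np.ones(len(t)), t])
        for col, slope in (("pm25_ugm3", cfg.pm25_slope),
                           ("precipitation_mm", cfg.precip_slope)):
            y = exp[col].to_numpy()
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            sig2 = res[0] / (len(t) - 2)
            se = np.sqrt(sig2 * np.linalg.inv(X.T @ X)[1, 1])
            assert abs(beta[1] - slope) < 3 * se


class TestRecords:
    def _flat_truth(self, **kw):
        base = dict(alpha0=24.0, beta0_time=0.0,
                    response=QuadraticResponse(peak=-7.0, curvature=0.0),
                    beta_precip=0.0, beta_pm25=0.0,
                    sd_county_structured=0.0, sd_county_iid=0.0,
                    sd_county_slope=0.0, sd_month=0.0, sd_month_slope=0.0,
                    sd_interaction=0.0, sd_interaction_slope=0.0,
                    sd_nu=0.0, sd_epsilon=0.0)
        base.update(kw)
        return SyntheticTruth(**base)

    def test_deterministic_limit_constant_score(self):
        cfg = SyntheticConfig(seed=8, n_counties=12, grid_shape=(3, 4),
                              n_months=12, n_subjects=200,
                              truth=self._flat_truth())
        g = gen_county_graph(cfg)
        recs, _ = gen_records(cfg, g, gen_exposures(cfg, g))
        assert np.allclose(recs["global_score"], 24.0)

    def test_time_trend_only(self):
        cfg = SyntheticConfig(seed=8, n_counties=12, grid_shape=(3, 4),
                              n_months=12, n_subjects=200,
                              truth=self._flat_truth(beta0_time=0.1))
        g = gen_county_graph(cfg)
        recs, _ = gen_records(cfg, g, gen_exposures(cfg, g))
        # score is alpha0 + 0.1 * centered study-month index
        am = recs["year"] * 12 + recs["month"] - 1
        t0 = am.min() - cfg.lag_buffer  # earliest exposure month
        n_total = cfg.n_months + 2 * cfg.lag_buffer
        tc_ = (am - t0) - (n_total - 1) / 2
        assert np.allclose(recs["global_score"], 24.0 + 0.1 * tc_)

    def test_domain_scores_sum_to_global(self):
        cfg = SyntheticConfig(seed=9, n_counties=12, grid_shape=(3, 4),
                              n_months=12, n_subjects=300)
        g = gen_county_graph(cfg)
        recs, _ = gen_records(cfg, g, gen_exposures(cfg, g))
        total = sum(recs[f"score_{d}"] for d in DOMAINS)
        assert np.allclose(total, recs["global_score"], atol=1e-9)

    def test_clamped_scores_stay_integer_in_range(self):
        cfg = SyntheticConfig(seed=9, n_counties=12, grid_shape=(3, 4),
                              n_months=12, n_subjects=300, clamp_scores=True)
        g = gen_county_graph(cfg)
        recs, echo = gen_records(cfg, g, gen_exposures(cfg, g))
        assert recs["global_score"].between(0, 30).all()
        assert (recs["global_score"] % 1 == 0).all()
        total = sum(recs[f"score_{d}"] for d in DOMAINS)
        assert np.array_equal(total, recs["global_score"])
        assert echo["clamp_scores"] is True

    def test_variance_decomposition_moment_oracle(self):
        truth = self._flat_truth(sd_county_iid=1.0, sd_epsilon=2.0)
        cfg = SyntheticConfig(seed=10, n_counties=40, grid_shape=(5, 8),
                              n_months=12, n_subjects=10_000,
                              county_concentration=50.0, truth=truth)
        g = gen_county_graph(cfg)
        recs, _ = gen_records(cfg, g, gen_exposures(cfg, g))
        total_var = recs["global_score"].var()
        assert total_var == pytest.approx(1.0 + 4.0, rel=0.10)
        within = recs.groupby("county_id")["global_score"].var().mean()
        assert within == pytest.approx(4.0, rel=0.10)

    def test_subject_allocation_uneven(self):
        cfg = SyntheticConfig(seed=11, n_counties=12, grid_shape=(3, 4),
                              n_months=12, n_subjects=1200,
                              county_concentration=0.5)
        g = gen_county_graph(cfg)
        recs, _ = gen_records(cfg, g, gen_exposures(cfg, g))
        counts = recs["county_id"].value_counts()
        assert counts.max() > 2 * 100  # far from the uniform 100 per county


class TestWriteDataset:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SyntheticConfig(seed=12, n_counties=12, grid_shape=(3, 4),
                              n_months=12, n_subjects=100)
        p1 = write_dataset(cfg, tmp_path / "a")
        p2 = write_dataset(cfg, tmp_path / "b")
        for key in p1:
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, key

    def test_truth_echo_readable(self, tmp_path):
        cfg = SyntheticConfig(seed=13, n_counties=4, grid_shape=(2, 2),
                              n_months=12, n_subjects=50)
        paths = write_dataset(cfg, tmp_path)
        echo = json.load(open(paths["truth"]))
        assert echo["seed"] == 13
        assert echo["response"]["form"] == "QuadraticResponse"

    def test_emitted_files_round_trip_through_readers(self, tmp_path):
        cfg = SyntheticConfig(seed=14, n_counties=12, grid_shape=(3, 4),
                              n_months=12, n_subjects=150)
        paths = write_dataset(cfg, tmp_path)
        recs = tc.read_records_csv(paths["records"])
        exps = tc.read_exposures_csv(paths["exposures"])
        edges = tc.read_adjacency(paths["adjacency"])
        graph = tc.CountyGraph.from_edges(sorted(recs["county_id"].unique()
                                                 .tolist() +
                                                 [c for e in edges for c in e]),
                                          edges)
        kept, log = tc.filter_records(recs)
        assert len(kept) == 150 and len(log) == 0
        linked = tc.link_exposures(kept, exps, graph, lag_window=3)
        assert linked.n == 150  # buffer months make every window complete


class TestLagTruthGeneration:
    def test_lag_contribution_uses_shifted_months(self):
        truth = SyntheticTruth(
            alpha0=0.0, beta0_time=0.0,
            response=LagResponse(weights=(0.0, 1.0, 0.0, 0.0)),
            beta_precip=0.0, beta_pm25=0.0,
            sd_county_structured=0.0, sd_county_iid=0.0, sd_county_slope=0.0,
            sd_month=0.0, sd_month_slope=0.0, sd_interaction=0.0,
            sd_interaction_slope=0.0, sd_nu=0.0, sd_epsilon=0.0)
        cfg = SyntheticConfig(seed=15, n_counties=4, grid_shape=(2, 2),
                              n_months=12, n_subjects=100, truth=truth)
        g = gen_county_graph(cfg)
        exps = gen_exposures(cfg, g)
        recs, _ = gen_records(cfg, g, exps)
        kept, _ = tc.filter_records(recs)
        linked = tc.link_exposures(kept, exps, g, lag_window=1)
        # score equals exactly the previous month's temperature
        assert np.allclose(linked.df["global_score"],
                           linked.df["temperature_c_lag1"])
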