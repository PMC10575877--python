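"""Record scoring, filtering, exposure linkage and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

import thermocog as tc
from thermocog.data_model import (DOMAINS, MMSEConfig, filter_records,
                                  link_exposures, quartile_summary,
                                  read_adjacency, score_mmse, write_adjacency)


class TestScoreMMSE:
    def test_extremes(self):
        d_all, g_all = score_mmse(np.ones(24, dtype=int))
        assert g_all == 30
        d_none, g_none = score_mmse(np.zeros(24, dtype=int))
        assert g_none == 0
        assert np.all(d_none == 0)

    def test_mixed_vector_matches_tally_oracle(self):
        rng = np.random.default_rng(0)
        cfg = MMSEConfig()
        for _ in range(20):
            resp = rng.integers(0, 2, 24)
            # independent spreadsheet-style tally
            expected = {d: 0 for d in DOMAINS}
            for i in range(24):
                if resp[i]:
                    expected[cfg.partition[i]] += cfg.weights[i]
            dom, glob = score_mmse(resp, cfg)
            assert list(dom) == [expected[d] for d in DOMAINS]
            assert glob == sum(expected.values())

    def test_monotone_in_item_flips(self):
        rng = np.random.default_rng(1)
        resp = rng.integers(0, 2, 24)
        _, g0 = score_mmse(resp)
        for i in np.where(resp == 0)[0]:
            r2 = resp.copy()
            r2[i] = 1
            _, g1 = score_mmse(r2)
            assert g1 >= g0

    @pytest.mark.parametrize("bad,err", [
        (np.ones(23), "24 item"),
        (np.ones(24), "sum to 30"),
    ])
    def test_errors(self, bad, err):
        if len(bad) == 24:
            cfg = MMSEConfig(weights=tuple([1] * 24))  # sums to 24, not 30
            with pytest.raises(ValueError, match=err):
                score_mmse(bad, cfg)
        else:
            with pytest.raises(ValueError, match=err):
                score_mmse(bad)

    def test_unknown_domain_rejected(self):
        cfg = MMSEConfig(partition=tuple(["general"] * 23 + ["bogus"]))
        with pytest.raises(ValueError, match="unknown domain"):
            score_mmse(np.ones(24, dtype=int), cfg)


class TestFilterRecords:
    def test_toy_table_counts(self, toy_records):
        kept, log = filter_records(toy_records)
        assert len(kept) == 6
        assert sorted(log["reason"].value_counts().to_dict().items()) == [
            ("duplicate id", 1), ("incomplete domains", 1),
            ("missing covariates", 2)]

    def test_missing_location(self, toy_records):
        df = toy_records.copy()
        df.loc[0, "county_id"] = None
        kept, log = filter_records(df)
        assert "missing location" in set(log["reason"])
        assert "s0" in set(log["subject_id"])

    def test_duplicate_keeps_first(self, toy_records):
        kept, log = filter_records(toy_records)
        # the duplicate row (index 8, id s0) is excluded, the original kept
        assert (kept["subject_id"] == "s0").sum() == 1
        assert kept.index[kept["subject_id"] == "s0"][0] == 0

    def test_idempotent(self, toy_records):
        once, _ = filter_records(toy_records)
        twice, log2 = filter_records(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(log2) == 0


def _toy_exposures():
    rows = []
    for cid in ("a", "b"):
        for m in range(1, 7):
            rows.append({"county_id": cid, "year": 2010, "month": m,
                         "temperature_c": 10.0 * (cid == "b") + m,
                         "precipitation_mm": 50.0, "pm25_ugm3": 40.0})
    return pd.DataFrame(rows)


def _toy_graph():
    return tc.CountyGraph.from_edges(["a", "b"], [("a", "b")])


class TestLinkExposures:
    def test_lag0_carries_own_month(self):
        recs = pd.DataFrame([
            {"subject_id": "s1", "county_id": "a", "year": 2010, "month": 3,
             "global_score": 20.0}])
        linked = link_exposures(recs, _toy_exposures(), _toy_graph())
        assert linked.n == 1
        assert linked.df.loc[0, "temperature_c"] == 3.0

    def test_first_month_dropped_with_lag_window(self):
        recs = pd.DataFrame([
            {"subject_id": "s1", "county_id": "a", "year": 2010, "month": 1,
             "global_score": 20.0}])
        linked = link_exposures(recs, _toy_exposures(), _toy_graph(),
                                lag_window=3)
        assert linked.n == 0
        assert "incomplete lag window" in linked.drop_log["reason"].iloc[0]

    def test_manual_join_oracle(self):
        recs = pd.DataFrame([
            {"subject_id": f"s{i}", "county_id": c, "year": 2010, "month": m,
             "global_score": 20.0}
            for i, (c, m) in enumerate([("a", 2), ("a", 5), ("b", 3), ("b", 6)])])
        linked = link_exposures(recs, _toy_exposures(), _toy_graph(),
                                lag_window=1)
        # hand-built join: temp = 10*(county=='b') + month; lag1 = temp - 1
        expect_now = [2.0, 5.0, 13.0, 16.0]
        expect_lag = [1.0, 4.0, 12.0, 15.0]
        assert linked.df["temperature_c"].tolist() == expect_now
        assert linked.df["temperature_c_lag1"].tolist() == expect_lag

    def test_no_silent_loss(self):
        recs = pd.DataFrame([
            {"subject_id": f"s{i}", "county_id": "a", "year": 2010,
             "month": m, "global_score": 20.0}
            for i, m in enumerate([1, 2, 3])])
        linked = link_exposures(recs, _toy_exposures(), _toy_graph(),
                                lag_window=2)
        assert linked.n + len(linked.drop_log) == 3

    def test_empty_exposures_rejected(self):
        with pytest.raises(ValueError, match="empty exposure"):
            link_exposures(pd.DataFrame({"county_id": [], "year": [],
                                         "month": []}),
                           pd.DataFrame(), _toy_graph())

    def test_gapless_time_index(self):
        linked = link_exposures(pd.DataFrame(
            [{"subject_id": "s", "county_id": "a", "year": 2010, "month": 2,
              "global_score": 1.0}]), _toy_exposures(), _toy_graph())
        vals = sorted(linked.time_index.values())
        assert vals == list(range(6))


class TestQuartileSummary:
    def _mk(self, temps, scores):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(temps))],
            "county_id": "a", "year": 2010, "month": 1,
            "global_score": scores, "temperature_c": temps,
            "precipitation_mm": 0.0, "pm25_ugm3": 0.0, "tindex": 0})
        return tc.LinkedDataset(df=df, graph=_toy_graph(),
                                time_index={(2010, 1): 0},
                                drop_log=pd.DataFrame())

    def test_one_per_bin(self):
        out = quartile_summary(self._mk([0, 10, 20, 30], [30, 20, 10, 0]))
        assert out["n"].tolist() == [1, 1, 1, 1]
        assert out["mean_score"].tolist() == [30, 20, 10, 0]

    def test_constant_temperature_degenerate(self):
        out = quartile_summary(self._mk([5.0] * 8, [10.0] * 8))
        assert out["n"].sum() == 8
        assert (out["n"] == 0).sum() == 3

    def test_groupby_oracle(self):
        rng = np.random.default_rng(3)
        t = rng.normal(10, 8, 100)
        s = rng.normal(20, 3, 100)
        out = quartile_summary(self._mk(t, s))
        cuts = np.percentile(t, [25, 50, 75])
        lab = np.searchsorted(cuts, t, side="right")
        for q in range(4):
            assert out.loc[q, "n"] == (lab == q).sum()
            assert out.loc[q, "mean_score"] == pytest.approx(s[lab == q].mean())

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least 4"):
            quartile_summary(self._mk([1, 2, 3], [1, 2, 3]))


class TestGraphIO:
    def test_adjacency_roundtrip(self, tmp_path):
        g = tc.CountyGraph.from_edges(["x", "y", "z"], [("x", "y"), ("y", "z")])
        p = tmp_path / "adj.txt"
        write_adjacency(g, p)
        edges = read_adjacency(p)
        g2 = tc.CountyGraph.from_edges(["x", "y", "z"], edges)
        assert g2.edges == g.edges

    def test_comma_delimited_and_order_insensitive(self, tmp_path):
        p = tmp_path / "adj.txt"
        p.write_text("y,x\nz y\n")
        edges = read_adjacency(p)
        g = tc.CountyGraph.from_edges(["x", "y", "z"], edges)
        assert len(g.edges) == 2

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            tc.CountyGraph.from_edges(["x"], [("x", "x")])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown county"):
            tc.CountyGraph.from_edges(["x"], [("x", "q")])
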