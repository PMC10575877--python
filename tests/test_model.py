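"""Design assembly, inference engines, DIC and basis selection."""

import numpy as np
import pandas as pd
import pytest

import thermocog as tc
from thermocog.basis import BasisSpec
from thermocog.engine import DesignBundle, run_engine
from thermocog.model import (DistributedLag, InferenceConfig, ModelSpec,
                             TemperatureBasis, TemperatureLinear,
                             build_design, compute_dic, fit, select_basis,
                             interaction_index)
from thermocog.structure import rw1_precision


class TestBuildDesign:
    def test_degenerate_spec_minimal_columns(self, small_linked):
        linked, _ = small_linked
        spec = ModelSpec(temperature_term=TemperatureLinear(),
                         county_bym_intercept=False, county_slope=False,
                         month_rw_intercept=False, month_slope=False,
                         interaction=False, interaction_slope=False,
                         global_time_rw=False, precipitation=False, pm25=False)
        d = build_design(linked, spec)
        assert d.fixed_names == ("alpha0", "beta0_time", "temp")
        assert not d.blocks
        assert np.allclose(d.X[:, 2], linked.df["temperature_c"])

    def test_month_prior_cyclic_december_january(self, small_linked):
        linked, _ = small_linked
        d = build_design(linked, ModelSpec(interaction=False,
                                           interaction_slope=False))
        blk = next(b for b in d.blocks if b.name == "month_intercept")
        # reconstruct the structure on the full month scale: A S A' = Q
        Q = blk.A @ blk.S @ blk.A.T
        expect = rw1_precision(12, cyclic=True).toarray()
        assert np.allclose(Q, expect, atol=1e-10)
        assert expect[11, 0] == -1  # December–January adjacency

    def test_interaction_index_row_major_enumeration(self):
        # 4-county toy: exhaustive enumeration of the flat pair index
        for c in range(4):
            for m in range(1, 13):
                assert interaction_index(np.array([c]), np.array([m]))[0] \
                    == c * 12 + (m - 1)

    def test_full_spec_block_roster(self, small_linked):
        linked, _ = small_linked
        d = build_design(linked, ModelSpec())
        names = [b.name for b in d.blocks]
        assert names == ["county_intercept_structured", "county_intercept_iid",
                         "county_slope", "month_intercept", "month_slope",
                         "interaction_intercept", "interaction_slope",
                         "nu_time"]

    def test_missing_lag_columns_rejected(self, small_linked):
        linked, _ = small_linked
        spec = ModelSpec(temperature_term=DistributedLag(l_max=2))
        with pytest.raises(ValueError, match="lag exposure"):
            build_design(linked, spec)

    def test_sum_to_zero_constraint_on_blocks(self, small_linked):
        linked, _ = small_linked
        spec = ModelSpec(interaction=False, interaction_slope=False,
                         temperature_term=TemperatureLinear())
        fr = fit(linked, spec)
        for name in ("county_intercept_structured", "county_intercept_iid",
                     "month_intercept", "nu_time"):
            blk = fr.block(name)
            scale = max(float(np.mean(blk.sd)), 1e-12)
            assert abs(blk.mean.sum()) < 1e-6 * len(blk.mean) * scale


class TestFitFixedOnly:
    def test_noiseless_linear_recovery(self, fixed_only_spec):
        # y = 2 + 0.5 * temp exactly; posterior mean equals the exact solution
        rng = np.random.default_rng(0)
        n = 80
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "county_id": "a", "year": 2010, "month": rng.integers(1, 13, n),
            "temperature_c": rng.uniform(-10, 30, n),
            "precipitation_mm": 0.0, "pm25_ugm3": 0.0,
            "tindex": rng.integers(0, 12, n)})
        df["global_score"] = 2.0 + 0.5 * df["temperature_c"]
        graph = tc.CountyGraph.from_edges(["a"], [])
        linked = tc.LinkedDataset(df=df, graph=graph,
                                  time_index={(2010, m): m - 1 for m in range(1, 13)},
                                  drop_log=pd.DataFrame())
        spec = fixed_only_spec
        from dataclasses import replace
        spec = replace(spec, precipitation=False, pm25=False,
                       inference=InferenceConfig(sigma2_fixed=1.0, seed=0))
        fr = fit(linked, spec)
        assert fr.fixed_effect("alpha0")["mean"] == pytest.approx(2.0, abs=1e-8)
        assert fr.block("temperature_coefficients").mean[0] == \
            pytest.approx(0.5, abs=1e-9)

    def test_vague_fit_matches_ols_oracle(self, small_linked, fixed_only_spec):
        linked, _ = small_linked
        from dataclasses import replace
        spec = replace(fixed_only_spec,
                       inference=InferenceConfig(n_draws=400, seed=3))
        fr = fit(linked, spec)
        X = np.column_stack([
            np.ones(linked.n),
            linked.df["tindex"] - max(linked.time_index.values()) / 2,
            linked.df["temperature_c"], linked.df["precipitation_mm"],
            linked.df["pm25_ugm3"]])
        y = linked.df["global_score"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X))
                     * (resid @ resid) / (linked.n - X.shape[1]))
        means = [fr.fixed_effect("alpha0")["mean"],
                 fr.fixed_effect("beta0_time")["mean"],
                 fr.block("temperature_coefficients").mean[0],
                 fr.fixed_effect("beta_precip")["mean"],
                 fr.fixed_effect("beta_pm25")["mean"]]
        assert np.all(np.abs(np.array(means) - beta) < 0.01 * se)

    def test_identical_seed_identical_output(self, small_linked):
        linked, _ = small_linked
        spec = ModelSpec(temperature_term=TemperatureLinear(),
                         interaction=False, interaction_slope=False,
                         inference=InferenceConfig(n_draws=100, seed=11))
        f1 = fit(linked, spec)
        f2 = fit(linked, spec)
        assert np.array_equal(f1.engine_fit.fixed_draws,
                              f2.engine_fit.fixed_draws)
        assert f1.dic == f2.dic

    def test_singular_design_actionable_error(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            run_engine(DesignBundle(y=y, X=X, fixed_names=("a", "b", "c"),
                                    blocks=[]))


class TestGibbsEngine:
    def test_gibbs_agrees_with_laplace_on_fixed_effects(self, small_linked):
        linked, _ = small_linked
        base = ModelSpec(temperature_term=TemperatureLinear(),
                         county_slope=False, month_slope=False,
                         interaction=False, interaction_slope=False,
                         global_time_rw=False)
        from dataclasses import replace
        fl = fit(linked, replace(base, inference=InferenceConfig(seed=1)))
        fg = fit(linked, replace(base, inference=InferenceConfig(
            engine="mcmc", n_draws=400, warmup=200, seed=1)))
        for nm in ("alpha0", "beta_precip", "beta_pm25"):
            a, b = fl.fixed_effect(nm), fg.fixed_effect(nm)
            assert abs(a["mean"] - b["mean"]) < 3 * max(a["sd"], b["sd"]) \
                / np.sqrt(50)  # generous MC tolerance on 400 draws

    def test_record_permutation_invariance(self, small_linked):
        linked, _ = small_linked
        perm = np.random.default_rng(0).permutation(linked.n)
        linked_p = linked.subset(np.ones(linked.n, dtype=bool))
        linked_p.df = linked.df.iloc[perm].reset_index(drop=True)
        spec = ModelSpec(temperature_term=TemperatureLinear(),
                         interaction=False, interaction_slope=False,
                         inference=InferenceConfig(n_draws=300, seed=5))
        f1 = fit(linked, spec)
        f2 = fit(linked_p, spec)
        a = f1.block("temperature_coefficients")
        b = f2.block("temperature_coefficients")
        assert abs(a.mean[0] - b.mean[0]) < 3 * a.sd[0] / np.sqrt(30)


class TestDIC:
    def test_point_mass_has_zero_pd(self):
        y = np.array([1.0, 2.0, 3.0])
        mu = np.tile(np.array([[1.1], [2.0], [2.9]]), (1, 50))
        out = compute_dic(y, mu, 1.0)
        assert out["p_d"] == pytest.approx(0.0, abs=1e-10)
        assert out["dic"] == pytest.approx(out["dbar"])

    def test_conjugate_gaussian_mean_model_closed_form(self):
        # known sigma2, prior mu ~ N(m0, v0): closed-form dbar and p_d
        rng = np.random.default_rng(8)
        n, s2, m0, v0 = 40, 2.0, 0.0, 100.0
        y = rng.normal(1.5, np.sqrt(s2), n)
        vn = 1.0 / (1.0 / v0 + n / s2)
        mn = vn * (m0 / v0 + y.sum() / s2)
        draws = rng.normal(mn, np.sqrt(vn), 40000)
        mu = np.tile(draws, (n, 1))
        out = compute_dic(y, mu, s2)
        dbar_exact = (n * np.log(2 * np.pi * s2)
                      + (np.sum((y - mn) ** 2) + n * vn) / s2)
        assert out["dbar"] == pytest.approx(dbar_exact, rel=2e-3)
        assert out["p_d"] == pytest.approx(n * vn / s2, rel=0.05)


class TestSelectBasis:
    def test_tie_broken_by_declaration_order(self, small_linked):
        linked, _ = small_linked
        spec = ModelSpec(interaction=False, interaction_slope=False,
                         county_slope=False, month_slope=False,
                         inference=InferenceConfig(n_draws=150, seed=2))
        cand = [BasisSpec("polynomial", 2), BasisSpec("polynomial", 2)]
        sel = select_basis(linked, cand, spec)
        assert sel.table.loc[0, "dic"] == sel.table.loc[1, "dic"]
        assert sel.winner is cand[0]

    def test_table_bookkeeping(self, small_linked):
        linked, _ = small_linked
        spec = ModelSpec(interaction=False, interaction_slope=False,
                         county_slope=False, month_slope=False,
                         global_time_rw=False,
                         inference=InferenceConfig(n_draws=150, seed=2))
        cand = [BasisSpec("polynomial", 2), BasisSpec("polynomial", 3),
                BasisSpec("ncs3")]
        sel = select_basis(linked, cand, spec)
        assert len(sel.table) == 3
        assert set(sel.table.columns) >= {"kind", "n_columns", "dbar",
                                          "p_d", "dic"}

    def test_fewer_than_two_candidates_rejected(self, small_linked):
        linked, _ = small_linked
        with pytest.raises(ValueError, match="at least 2"):
            select_basis(linked, [BasisSpec("polynomial", 2)], ModelSpec())
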