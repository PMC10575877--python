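"""The Bayesian spatiotemporal score model.

Linear predictor for the score of one examined subject in county c, study
month t (month-of-year m, centered study-month index time):

    score = alpha0 + beta0 * time + f(temperature_ct)
          + (a_c + b_c * time)            # BYM county intercept, county slope
          + (a_m + b_m * time)            # cyclic RW1 month intercept/slope
          + (zeta_cm + psi_cm * time)     # county-month interaction
          + nu_t                          # RW1 over the full study-month index
          + beta1 * precipitation + beta2 * PM2.5
          + eps,  eps ~ N(0, sigma2_eps)

f is one of: a nonlinear basis in the current-month temperature, a single
linear temperature term (interval fits), or a distributed lag/lead sum over
monthly temperature offsets. The county intercept is Besag-York-Mollie:
ICAR-structured plus iid components. All structured and interaction blocks
carry sum-to-zero constraints. The record-level over-dispersion term is the
Gaussian residual itself (with a Gaussian likelihood the two coincide).

Model selection among the four temperature bases is by DIC, dic = dbar + p_d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .basis import BasisMatrix, BasisSpec, make_basis
from .data_model import LinkedDataset
from .engine import DesignBundle, EngineFit, RandomBlock, run_engine, _summaries
from .structure import constraint_basis, icar_precision, rw1_precision

__all__ = [
    "TemperatureBasis", "TemperatureLinear", "DistributedLag",
    "InferenceConfig", "HyperConfig", "ModelSpec", "EffectBlock", "FitResult",
    "build_design", "fit", "compute_dic", "select_basis", "BasisSelection",
]

N_MONTHS_OF_YEAR = 12


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemperatureBasis:
    """Nonlinear temperature term through a :class:`BasisSpec`."""
    spec: BasisSpec


@dataclass(frozen=True)
class TemperatureLinear:
    """Single linear temperature column (the interval-effect regressor)."""


@dataclass(frozen=True)
class DistributedLag:
    """Joint temperature offsets 0..l_max, lagged or led by whole months."""
    l_max: int = 3
    direction: str = "lag"  # or "lead"

    def __post_init__(self):
        if self.direction not in ("lag", "lead"):
            raise ValueError("direction must be 'lag' or 'lead'")
        if self.l_max < 0:
            raise ValueError("l_max must be >= 0")


@dataclass(frozen=True)
class InferenceConfig:
    engine: str = "laplace"     # or "mcmc"
    n_draws: int = 800
    warmup: int = 300
    chains: int = 1
    seed: int = 0
    sigma2_fixed: object = None
    maxfev: int = 500
    integrate_hyper: bool = False
    n_hyper: int = 9


@dataclass(frozen=True)
class HyperConfig:
    """Gamma(shape, rate) prior on every precision (including 1/sigma2)."""
    shape: float = 1.0
    rate: float = 5e-5


@dataclass(frozen=True)
class ModelSpec:
    """One fittable variant of the spatiotemporal model.

    All include-flags default on (the full model). ``overdispersion`` is
    recorded for provenance; with the Gaussian likelihood the term is the
    residual itself and cannot be switched off.
    """

    temperature_term: object = field(default_factory=TemperatureLinear)
    outcome: str = "global_score"
    county_bym_intercept: bool = True
    county_slope: bool = True
    month_rw_intercept: bool = True
    month_slope: bool = True
    interaction: bool = True
    interaction_slope: bool = True
    global_time_rw: bool = True
    overdispersion: bool = True
    precipitation: bool = True
    pm25: bool = True
    hyper: HyperConfig = field(default_factory=HyperConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    def with_temperature(self, term) -> "ModelSpec":
        return replace(self, temperature_term=term)

    def flags(self) -> dict:
        return {k: getattr(self, k) for k in (
            "county_bym_intercept", "county_slope", "month_rw_intercept",
            "month_slope", "interaction", "interaction_slope",
            "global_time_rw", "overdispersion", "precipitation", "pm25")}

    def to_dict(self) -> dict:
        term = self.temperature_term
        if isinstance(term, TemperatureBasis):
            tt = {"type": "basis", **term.spec.to_dict()}
        elif isinstance(term, DistributedLag):
            tt = {"type": "distributed_lag", "l_max": term.l_max,
                  "direction": term.direction}
        else:
            tt = {"type": "linear"}
        return {"temperature_term": tt, "outcome": self.outcome,
                **self.flags(),
                "hyper": {"shape": self.hyper.shape, "rate": self.hyper.rate},
                "inference": {"engine": self.inference.engine,
                              "n_draws": self.inference.n_draws,
                              "warmup": self.inference.warmup,
                              "seed": self.inference.seed}}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        tt = d.pop("temperature_term", {"type": "linear"})
        kind = tt.get("type", "linear")
        if kind == "basis":
            term = TemperatureBasis(BasisSpec.from_dict(
                {k: v for k, v in tt.items() if k != "type"}))
        elif kind == "distributed_lag":
            term = DistributedLag(l_max=int(tt.get("l_max", 3)),
                                  direction=tt.get("direction", "lag"))
        else:
            term = TemperatureLinear()
        hyper = HyperConfig(**d.pop("hyper", {}))
        inference = InferenceConfig(**d.pop("inference", {}))
        allowed = {k for k in cls.__dataclass_fields__} - {
            "temperature_term", "hyper", "inference"}
        return cls(temperature_term=term, hyper=hyper, inference=inference,
                   **{k: v for k, v in d.items() if k in allowed})


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _indicator(codes: np.ndarray, n_levels: int, weight=None) -> sp.csr_matrix:
    n = len(codes)
    data = np.ones(n) if weight is None else np.asarray(weight, dtype=float)
    return sp.csr_matrix((data, (np.arange(n), codes)), shape=(n, n_levels))


def centered_time(linked: LinkedDataset) -> np.ndarray:
    """Study-month index centered at mid-study (decorelates from intercept)."""
    tmax = max(linked.time_index.values())
    return linked.df["tindex"].to_numpy(dtype=float) - tmax / 2.0


def interaction_index(county_pos: np.ndarray, month: np.ndarray) -> np.ndarray:
    """Row-major flat index of the (county, month-of-year) pair."""
    return county_pos * N_MONTHS_OF_YEAR + (month - 1)


def build_design(linked: LinkedDataset, spec: ModelSpec) -> DesignBundle:
    """Assemble response, fixed columns and random blocks for ``spec``."""
    df = linked.df
    graph = linked.graph
    n = len(df)
    if n == 0:
        raise ValueError("no records to fit")
    y = df[spec.outcome].to_numpy(dtype=float)
    time_c = centered_time(linked)

    pos = {c: i for i, c in enumerate(graph.county_ids)}
    unknown = set(df["county_id"]) - set(graph.county_ids)
    if unknown:
        raise ValueError(f"records reference counties absent from the graph: "
                         f"{sorted(unknown)[:5]}")
    county_pos = df["county_id"].map(pos).to_numpy(dtype=int)
    month = df["month"].to_numpy(dtype=int)

    fixed_cols = [np.ones(n), time_c]
    fixed_names = ["alpha0", "beta0_time"]
    meta = {"outcome": spec.outcome, "temp_names": []}

    term = spec.temperature_term
    if isinstance(term, TemperatureBasis):
        bm = make_basis(df["temperature_c"].to_numpy(dtype=float), term.spec)
        for j in range(bm.n_columns):
            fixed_cols.append(bm.columns[:, j])
            fixed_names.append(f"temp_b{j + 1}")
        meta["basis"] = bm
        meta["temp_names"] = [f"temp_b{j + 1}" for j in range(bm.n_columns)]
    elif isinstance(term, TemperatureLinear):
        fixed_cols.append(df["temperature_c"].to_numpy(dtype=float))
        fixed_names.append("temp")
        meta["temp_names"] = ["temp"]
    elif isinstance(term, DistributedLag):
        names = ["temperature_c"] + [
            f"temperature_c_{term.direction}{L}" for L in range(1, term.l_max + 1)]
        missing = [c for c in names if c not in df.columns]
        if missing:
            raise ValueError(
                f"linked data lacks {term.direction} exposure columns "
                f"{missing}; re-link with a window of {term.l_max}")
        cols = [df[c].to_numpy(dtype=float) for c in names]
        if len(cols) > 1:
            cc = np.corrcoef(np.vstack(cols))
            hi = np.abs(cc[np.triu_indices_from(cc, k=1)]).max()
            if hi > 0.99:
                warnings.warn(
                    f"offset temperature columns are nearly collinear "
                    f"(max |corr| = {hi:.4f}); lag coefficients are weakly "
                    "identified")
        for L, c in enumerate(cols):
            fixed_cols.append(c)
            fixed_names.append(f"temp_L{L}")
        meta["temp_names"] = [f"temp_L{L}" for L in range(len(cols))]
    else:
        raise ValueError(f"unknown temperature term {term!r}")

    if spec.precipitation:
        fixed_cols.append(df["precipitation_mm"].to_numpy(dtype=float))
        fixed_names.append("beta_precip")
    if spec.pm25:
        fixed_cols.append(df["pm25_ugm3"].to_numpy(dtype=float))
        fixed_names.append("beta_pm25")

    blocks = []
    nc = graph.n
    if spec.county_bym_intercept:
        Zc = _indicator(county_pos, nc)
        comps = graph.components()
        groups = [np.array([pos[c] for c in comp]) for comp in comps]
        Q = icar_precision(graph)
        A = constraint_basis(nc, groups)
        blocks.append(RandomBlock("county_intercept_structured", Zc, A,
                                  A.T @ (Q @ A), tuple(graph.county_ids)))
        A2 = constraint_basis(nc)
        blocks.append(RandomBlock("county_intercept_iid", Zc, A2,
                                  A2.T @ A2, tuple(graph.county_ids)))
    if spec.county_slope:
        Zc = _indicator(county_pos, nc, weight=time_c)
        A = constraint_basis(nc)
        blocks.append(RandomBlock("county_slope", Zc, A, A.T @ A,
                                  tuple(graph.county_ids)))
    month_labels = tuple(range(1, 13))
    if spec.month_rw_intercept:
        Zm = _indicator(month - 1, N_MONTHS_OF_YEAR)
        Q = rw1_precision(N_MONTHS_OF_YEAR, cyclic=True)
        A = constraint_basis(N_MONTHS_OF_YEAR)
        blocks.append(RandomBlock("month_intercept", Zm, A, A.T @ (Q @ A),
                                  month_labels))
    if spec.month_slope:
        Zm = _indicator(month - 1, N_MONTHS_OF_YEAR, weight=time_c)
        Q = rw1_precision(N_MONTHS_OF_YEAR, cyclic=True)
        A = constraint_basis(N_MONTHS_OF_YEAR)
        blocks.append(RandomBlock("month_slope", Zm, A, A.T @ (Q @ A),
                                  month_labels))
    if spec.interaction or spec.interaction_slope:
        ii = interaction_index(county_pos, month)
        n_pairs = nc * N_MONTHS_OF_YEAR
        pair_labels = tuple(f"{c}:{m}" for c in graph.county_ids
                            for m in range(1, 13))
        if spec.interaction:
            Zi = _indicator(ii, n_pairs)
            A = constraint_basis(n_pairs)
            blocks.append(RandomBlock("interaction_intercept", Zi, A, A.T @ A,
                                      pair_labels))
        if spec.interaction_slope:
            Zi = _indicator(ii, n_pairs, weight=time_c)
            A = constraint_basis(n_pairs)
            blocks.append(RandomBlock("interaction_slope", Zi, A, A.T @ A,
                                      pair_labels))
    if spec.global_time_rw:
        nt = max(linked.time_index.values()) + 1
        Zt = _indicator(df["tindex"].to_numpy(dtype=int), nt)
        Q = rw1_precision(nt, cyclic=False)
        A = constraint_basis(nt)
        blocks.append(RandomBlock("nu_time", Zt, A, A.T @ (Q @ A),
                                  tuple(range(nt))))

    X = np.column_stack(fixed_cols)
    return DesignBundle(y=y, X=X, fixed_names=tuple(fixed_names),
                        blocks=blocks, meta=meta)


# ---------------------------------------------------------------------------
# fitting and summaries
# ---------------------------------------------------------------------------

@dataclass
class EffectBlock:
    """Posterior summaries for one named group of coefficients."""

    name: str
    labels: tuple
    mean: np.ndarray
    sd: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    hyper: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": list(self.labels), "mean": self.mean,
                             "sd": self.sd, "q025": self.q025,
                             "q975": self.q975})


@dataclass
class FitResult:
    """Everything produced by one model fit."""

    spec: ModelSpec
    blocks: dict                  # name -> EffectBlock
    dic: dict                     # dbar, p_d, dic
    fitted: np.ndarray            # posterior-mean predictor per record
    diagnostics: dict
    provenance: dict
    engine_fit: EngineFit
    basis: BasisMatrix | None = None

    def block(self, name: str) -> EffectBlock:
        return self.blocks[name]

    @property
    def temperature_names(self) -> tuple:
        return tuple(self.provenance["temp_names"])

    def temperature_draws(self) -> np.ndarray:
        """Draws of the temperature coefficients, (k, n_draws)."""
        idx = [self.engine_fit.fixed_names.index(nm)
               for nm in self.temperature_names]
        return self.engine_fit.fixed_draws[idx]

    def fixed_effect(self, name: str) -> dict:
        i = self.engine_fit.fixed_names.index(name)
        d = self.engine_fit.fixed_draws[i]
        s = _summaries(d)
        return {k: float(v) for k, v in s.items()}

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, blk in self.blocks.items():
            f = blk.to_frame()
            f.insert(0, "block", name)
            rows.append(f)
        return pd.concat(rows, ignore_index=True)

    def to_json_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "dic": self.dic,
            "diagnostics": self.diagnostics,
            "provenance": {k: v for k, v in self.provenance.items()
                           if k != "temp_names"} | {
                               "temp_names": list(self.temperature_names)},
            "effects": {
                name: {"labels": [str(x) for x in blk.labels],
                       "mean": blk.mean.tolist(), "sd": blk.sd.tolist(),
                       "q025": blk.q025.tolist(), "q975": blk.q975.tolist(),
                       "hyper": blk.hyper}
                for name, blk in self.blocks.items()},
        }


def compute_dic(y, mu_draws, sigma2_draws) -> dict:
    """Deviance information criterion from posterior draws.

    dbar is the posterior mean of the Gaussian deviance
    D = n log(2 pi sigma2) + ||y - mu||^2 / sigma2, p_d = dbar minus the
    deviance at the posterior-mean parameters, dic = dbar + p_d.
    """
    y = np.asarray(y, dtype=float)
    mu = np.atleast_2d(np.asarray(mu_draws, dtype=float))
    n, nd = mu.shape
    if n != y.size:
        raise ValueError("mu_draws must be (n_obs, n_draws)")
    s2 = np.broadcast_to(np.asarray(sigma2_draws, dtype=float), (nd,))
    rss = ((y[:, None] - mu) ** 2).sum(axis=0)
    dev = n * np.log(2 * np.pi * s2) + rss / s2
    dbar = float(dev.mean())
    mu_bar = mu.mean(axis=1)
    s2_bar = float(s2.mean())
    d_hat = n * np.log(2 * np.pi * s2_bar) + float(((y - mu_bar) ** 2).sum()) / s2_bar
    p_d = float(dbar - d_hat)
    return {"dbar": dbar, "p_d": p_d, "dic": float(dbar + p_d)}


def fit(linked: LinkedDataset, spec: ModelSpec) -> FitResult:
    """Fit ``spec`` on the linked records and summarise the posterior."""
    design = build_design(linked, spec)
    inf = spec.inference
    ef = run_engine(design, engine=inf.engine, n_draws=inf.n_draws,
                    warmup=inf.warmup, seed=inf.seed,
                    sigma2_fixed=inf.sigma2_fixed,
                    prior_shape=spec.hyper.shape, prior_rate=spec.hyper.rate,
                    maxfev=inf.maxfev, integrate_hyper=inf.integrate_hyper,
                    n_hyper=inf.n_hyper)

    blocks = {}
    fd = ef.fixed_draws
    for i, nm in enumerate(ef.fixed_names):
        if nm in design.meta["temp_names"]:
            continue
        s = _summaries(fd[i])
        blocks[nm] = EffectBlock(nm, (nm,), *(np.atleast_1d(s[k]) for k in
                                              ("mean", "sd", "q025", "q975")))
    tnames = design.meta["temp_names"]
    if tnames:
        idx = [list(ef.fixed_names).index(nm) for nm in tnames]
        s = _summaries(fd[idx])
        blocks["temperature_coefficients"] = EffectBlock(
            "temperature_coefficients", tuple(tnames),
            s["mean"], s["sd"], s["q025"], s["q975"])
    for name, draws in ef.block_draws.items():
        s = _summaries(draws)
        blocks[name] = EffectBlock(name, tuple(ef.block_labels[name]),
                                   s["mean"], s["sd"], s["q025"], s["q975"],
                                   hyper={"tau": ef.tau[name]})
    s2 = _summaries(ef.sigma2_draws)
    blocks["epsilon"] = EffectBlock(
        "epsilon", ("sigma2_eps",),
        *(np.atleast_1d(s2[k]) for k in ("mean", "sd", "q025", "q975")))

    dic = compute_dic(design.y, ef.mu_draws, ef.sigma2_draws)
    import thermocog
    provenance = {
        "engine": inf.engine, "seed": inf.seed, "n_draws": inf.n_draws,
        "version": getattr(thermocog, "__version__", "0"),
        "temp_names": tnames,
        "n_records": len(design.y),
        "basis": design.meta["basis"].spec.to_dict() if "basis" in design.meta else None,
        "basis_centers": design.meta["basis"].centers.tolist() if "basis" in design.meta else None,
    }
    return FitResult(spec=spec, blocks=blocks, dic=dic,
                     fitted=ef.theta_mean_mu, diagnostics=ef.diagnostics,
                     provenance=provenance, engine_fit=ef,
                     basis=design.meta.get("basis"))


# ---------------------------------------------------------------------------
# DIC basis selection
# ---------------------------------------------------------------------------

@dataclass
class BasisSelection:
    winner: BasisSpec
    table: pd.DataFrame
    fits: dict  # index -> FitResult


def select_basis(linked: LinkedDataset, candidates, spec: ModelSpec) -> BasisSelection:
    """Fit every candidate temperature basis and pick the DIC minimiser.

    Ties (exactly equal DIC) break toward fewer basis columns, then earlier
    declaration order. A hard failure in any candidate aborts selection with
    the failing spec named.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate bases")
    rows, fits = [], {}
    for i, cand in enumerate(candidates):
        cspec = spec.with_temperature(TemperatureBasis(cand))
        try:
            fr = fit(linked, cspec)
        except Exception as exc:
            raise RuntimeError(f"candidate {i} ({cand.kind}) failed: {exc}") from exc
        fits[i] = fr
        rows.append({"index": i, "kind": cand.kind, "degree": cand.degree,
                     "n_columns": len(fr.temperature_names),
                     "dbar": fr.dic["dbar"], "p_d": fr.dic["p_d"],
                     "dic": fr.dic["dic"]})
    table = pd.DataFrame(rows)
    order = table.sort_values(["dic", "n_columns", "index"],
                              kind="stable").iloc[0]
    winner_i = int(order["index"])
    return BasisSelection(winner=candidates[winner_i], table=table, fits=fits)
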