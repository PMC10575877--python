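"""Synthetic study data with known ground truth.

The restricted survey microdata cannot be redistributed, so every fit in this
package is exercised against a generator that reproduces the *statistical
structure* the spatiotemporal model assumes: a connected county adjacency
(rook lattice), monthly temperatures with a seasonal cycle and a north-south
spatial gradient affinely scaled to the study's observed span (about -14 to
31 degC), precipitation and PM2.5 linearly coupled to temperature, subjects
unevenly allocated to counties, and Gaussian MMSE-like scores built from the
model's own linear predictor with every parameter known.

Ground truth (:class:`SyntheticTruth`) carries the fixed effects, one of
three temperature-response forms (quadratic, piecewise linear, distributed
lag weights), and the random-effect scales. Structured random effects are
drawn exactly on their sum-to-zero subspaces, so a correctly specified fit
can recover the truth without identifiability slack.

Scores are left continuous by default: rounding/clamping to the 0-30 MMSE
range breaks the Gaussian model and is available only as a realism flag
(recorded in the truth echo).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (CountyGraph, DOMAINS, LinkedDataset, filter_records,
                         link_exposures, write_adjacency)
from .structure import icar_precision, rw1_precision, sample_constrained

__all__ = [
    "QuadraticResponse", "PiecewiseLinearResponse", "LagResponse",
    "SyntheticTruth", "SyntheticConfig", "gen_county_graph", "gen_exposures",
    "gen_records", "write_dataset", "generate_linked",
]

N_MOY = 12


# ---------------------------------------------------------------------------
# temperature-response truth forms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadraticResponse:
    """f(T) = curvature * (T - peak)^2; concave for curvature < 0."""

    peak: float = -7.0
    curvature: float = -0.003

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.curvature * (t - self.peak) ** 2

    def polynomial_coefficients(self):
        """(b1, b2) on raw columns (T, T^2); the constant is absorbed."""
        return (-2.0 * self.curvature * self.peak, self.curvature)


@dataclass(frozen=True)
class PiecewiseLinearResponse:
    """Continuous piecewise-linear response, zero at the first break.

    ``breaks`` has one more element than ``slopes``; the first/last slopes
    extend beyond the end breaks.
    """

    breaks: tuple
    slopes: tuple

    def __post_init__(self):
        if len(self.breaks) != len(self.slopes) + 1:
            raise ValueError("need len(breaks) == len(slopes) + 1")
        if any(b >= c for b, c in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        br = np.asarray(self.breaks, dtype=float)
        sl = np.asarray(self.slopes, dtype=float)
        out = np.zeros_like(t)
        # value at each break by cumulative slopes
        vals = np.concatenate([[0.0], np.cumsum(sl * np.diff(br))])
        seg = np.clip(np.searchsorted(br, t, side="right") - 1, 0, len(sl) - 1)
        out = vals[seg] + sl[seg] * (t - br[seg])
        return out


@dataclass(frozen=True)
class LagResponse:
    """Distributed-lag truth: sum_L weights[L] * T_{t -/+ L}."""

    weights: tuple = (-0.03, -0.02, 0.0, 0.0)
    direction: str = "lag"

    def __post_init__(self):
        if self.direction not in ("lag", "lead"):
            raise ValueError("direction must be 'lag' or 'lead'")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters a recovery test must recover."""

    alpha0: float = 24.0
    beta0_time: float = -0.005          # score per study month
    response: object = field(default_factory=QuadraticResponse)
    beta_precip: float = -0.004         # score per mm
    beta_pm25: float = -0.01            # score per ug/m3
    sd_county_structured: float = 0.5
    sd_county_iid: float = 0.3
    sd_county_slope: float = 0.005
    sd_month: float = 0.3
    sd_month_slope: float = 0.002
    sd_interaction: float = 0.15
    sd_interaction_slope: float = 0.0
    sd_nu: float = 0.2
    sd_epsilon: float = 3.0
    subgroup_multipliers: object = None  # e.g. {"gender": {"female": 2.0}}

    def __post_init__(self):
        for f in ("sd_county_structured", "sd_county_iid", "sd_county_slope",
                  "sd_month", "sd_month_slope", "sd_interaction",
                  "sd_interaction_slope", "sd_nu", "sd_epsilon"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["response"] = {"form": type(self.response).__name__,
                         **asdict(self.response)}
        return d


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset. ``seed`` is mandatory."""

    seed: int
    n_counties: int = 40
    grid_shape: tuple = (5, 8)
    n_months: int = 36                  # study span in months
    n_subjects: int = 2000
    start_year: int = 2008
    lag_buffer: int = 3                 # exposure months beyond the span, each side
    seasonal_amplitude: float = 16.0    # degC, peak-to-midline
    spatial_gradient: float = 3.0       # degC per lattice row
    temp_noise_sd: float = 2.0
    temp_range: tuple = (-14.0, 31.0)
    precip_intercept: float = 60.0      # mm
    precip_slope: float = 3.0           # mm per degC
    precip_noise_sd: float = 15.0
    pm25_intercept: float = 55.0        # ug/m3
    pm25_slope: float = -0.8            # ug/m3 per degC (winter pollution)
    pm25_noise_sd: float = 10.0
    county_concentration: float = 1.0   # Dirichlet concentration of allocation
    clamp_scores: bool = False
    domain_weights: tuple = (0.2, 0.15, 0.25, 0.2, 0.2)
    domain_noise_sd: float = 0.3
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)

    def __post_init__(self):
        if int(np.prod(self.grid_shape)) != self.n_counties:
            raise ValueError(
                f"grid shape {self.grid_shape} does not hold "
                f"{self.n_counties} counties")
        if self.n_months % 12 != 0:
            warnings.warn("n_months is not a multiple of 12; seasonal and "
                          "secular terms will be partially confounded")
        if abs(len(self.domain_weights) - len(DOMAINS)) > 0:
            raise ValueError(f"need {len(DOMAINS)} domain weights")
        if abs(sum(self.domain_weights) - 1.0) > 1e-9:
            raise ValueError("domain weights must sum to 1")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def gen_county_graph(config: SyntheticConfig) -> CountyGraph:
    """Rook-adjacency lattice of ``grid_shape``; connected, deterministic."""
    import networkx as nx
    rows, cols = config.grid_shape
    g = nx.grid_2d_graph(rows, cols)
    name = {rc: f"c{rc[0] * cols + rc[1]:03d}" for rc in g.nodes}
    ids = [name[(r, c)] for r in range(rows) for c in range(cols)]
    edges = [(name[a], name[b]) for a, b in g.edges]
    return CountyGraph.from_edges(ids, edges)


def _county_row(config: SyntheticConfig) -> np.ndarray:
    rows, cols = config.grid_shape
    return np.repeat(np.arange(rows), cols).astype(float)


def gen_exposures(config: SyntheticConfig, graph: CountyGraph) -> pd.DataFrame:
    """County-month exposure table covering the span plus the lag buffers.

    Temperature = spatial gradient + seasonal sinusoid (July peak) + noise,
    affinely rescaled so its empirical range equals ``temp_range``.
    Precipitation and PM2.5 are the configured linear functions of the final
    temperature plus Gaussian noise.
    """
    rng = _rng(config, 1)
    n_total = config.n_months + 2 * config.lag_buffer
    am0 = config.start_year * 12 - config.lag_buffer
    row = _county_row(config)
    recs = []
    raw = np.empty((graph.n, n_total))
    for j in range(n_total):
        am = am0 + j
        moy = am % 12 + 1
        season = -config.seasonal_amplitude * np.cos(2 * np.pi * (moy - 1) / N_MOY)
        raw[:, j] = config.spatial_gradient * row + season
    raw += rng.normal(0.0, config.temp_noise_sd, size=raw.shape)
    lo, hi = config.temp_range
    ptp = raw.max() - raw.min()
    if ptp == 0:
        temp = np.full_like(raw, 0.5 * (lo + hi))
    else:
        temp = lo + (raw - raw.min()) * (hi - lo) / ptp
    precip = (config.precip_intercept + config.precip_slope * temp
              + rng.normal(0.0, config.precip_noise_sd, size=temp.shape))
    pm25 = (config.pm25_intercept + config.pm25_slope * temp
            + rng.normal(0.0, config.pm25_noise_sd, size=temp.shape))
    for i, cid in enumerate(graph.county_ids):
        for j in range(n_total):
            am = am0 + j
            recs.append({"county_id": cid, "year": am // 12,
                         "month": am % 12 + 1,
                         "temperature_c": temp[i, j],
                         "precipitation_mm": precip[i, j],
                         "pm25_ugm3": pm25[i, j]})
    return pd.DataFrame(recs)


_COVARIATE_LEVELS = {
    "gender": (("female", "male"), (0.55, 0.45)),
    "residence": (("rural", "urban"), (0.6, 0.4)),
    "education": (("low", "medium", "high"), (0.55, 0.3, 0.15)),
    "income": (("low", "medium", "high"), (0.4, 0.4, 0.2)),
    "ethnicity": (("Han", "minority"), (0.92, 0.08)),
}


def _apportion(total: int, weights) -> np.ndarray:
    """Largest-remainder integer split of ``total`` by ``weights``."""
    w = np.asarray(weights, dtype=float)
    raw = w * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def gen_records(config: SyntheticConfig, graph: CountyGraph,
                exposures: pd.DataFrame):
    """Subject records from the model's own generative process.

    Returns ``(records, truth)`` where records is the CSV-dialect DataFrame
    the data_model readers consume and truth echoes the generating
    parameters (plus the clamp flag).
    """
    truth = config.truth
    rng = _rng(config, 2)
    n = config.n_subjects
    nc = graph.n

    # exposure lookup arrays indexed (county_pos, total-month index)
    exp = exposures.copy()
    exp["_am"] = exp["year"].astype(int) * 12 + exp["month"].astype(int) - 1
    am_min = int(exp["_am"].min())
    n_total = int(exp["_am"].max()) - am_min + 1
    pos = {c: i for i, c in enumerate(graph.county_ids)}
    T = np.full((nc, n_total), np.nan)
    P = np.full((nc, n_total), np.nan)
    M = np.full((nc, n_total), np.nan)
    ci = exp["county_id"].map(pos).to_numpy()
    ti = (exp["_am"] - am_min).to_numpy()
    T[ci, ti] = exp["temperature_c"]
    P[ci, ti] = exp["precipitation_mm"]
    M[ci, ti] = exp["pm25_ugm3"]

    # subjects: uneven county allocation, uniform exam month in the span
    weights = rng.dirichlet(np.full(nc, config.county_concentration))
    county = rng.choice(nc, size=n, p=weights)
    tindex = rng.integers(config.lag_buffer,
                          config.lag_buffer + config.n_months, size=n)
    time_c = tindex.astype(float) - (n_total - 1) / 2.0

    cov = {}
    for name, (levels, probs) in _COVARIATE_LEVELS.items():
        cov[name] = rng.choice(levels, size=n, p=probs)
    cov["age"] = np.clip(np.round(rng.normal(86.0, 8.0, size=n)), 65, 110).astype(int)

    # random effects, drawn exactly on their constrained subspaces
    comps = graph.components()
    groups = [np.array([pos[c] for c in comp]) for comp in comps]
    u_spat = sample_constrained(icar_precision(graph),
                                truth.sd_county_structured, rng, groups)
    u_iid = rng.normal(0.0, truth.sd_county_iid, nc)
    u_iid -= u_iid.mean() if truth.sd_county_iid > 0 else 0.0
    u_cslope = rng.normal(0.0, truth.sd_county_slope, nc)
    u_cslope -= u_cslope.mean() if truth.sd_county_slope > 0 else 0.0
    u_month = sample_constrained(rw1_precision(N_MOY, cyclic=True),
                                 truth.sd_month, rng)
    u_mslope = sample_constrained(rw1_precision(N_MOY, cyclic=True),
                                  truth.sd_month_slope, rng)
    u_inter = rng.normal(0.0, truth.sd_interaction, nc * N_MOY)
    u_inter -= u_inter.mean() if truth.sd_interaction > 0 else 0.0
    u_islope = rng.normal(0.0, truth.sd_interaction_slope, nc * N_MOY)
    u_islope -= u_islope.mean() if truth.sd_interaction_slope > 0 else 0.0
    u_nu = sample_constrained(rw1_precision(max(n_total, 2)), truth.sd_nu, rng)

    temp_now = T[county, tindex]
    moy = (am_min + tindex) % 12  # 0-based month of year
    resp = truth.response
    if isinstance(resp, LagResponse):
        contrib = np.zeros(n)
        sign = -1 if resp.direction == "lag" else 1
        for L, w in enumerate(resp.weights):
            contrib += w * T[county, tindex + sign * L]
    else:
        contrib = resp(temp_now)
    if truth.subgroup_multipliers:
        mult = np.ones(n)
        for var, table in truth.subgroup_multipliers.items():
            vals = pd.Series(cov[var]).map(lambda v: table.get(str(v), 1.0))
            mult *= vals.to_numpy(dtype=float)
        contrib = contrib * mult

    eta = (truth.alpha0 + truth.beta0_time * time_c + contrib
           + u_spat[county] + u_iid[county] + u_cslope[county] * time_c
           + u_month[moy] + u_mslope[moy] * time_c
           + u_inter[county * N_MOY + moy]
           + u_islope[county * N_MOY + moy] * time_c
           + u_nu[tindex]
           + truth.beta_precip * P[county, tindex]
           + truth.beta_pm25 * M[county, tindex])
    score = eta + rng.normal(0.0, truth.sd_epsilon, n)

    w = np.asarray(config.domain_weights)
    e = rng.normal(0.0, config.domain_noise_sd, (n, len(w)))
    e -= e.mean(axis=1, keepdims=True)
    domains = score[:, None] * w[None, :] + e
    if config.clamp_scores:
        score = np.clip(np.round(score), 0, 30).astype(int)
        domains = np.vstack([_apportion(int(s), w) for s in score])
    else:
        domains[:, -1] = score - domains[:, :-1].sum(axis=1)

    am = am_min + tindex
    records = pd.DataFrame({
        "subject_id": [f"s{i:06d}" for i in range(n)],
        "county_id": [graph.county_ids[c] for c in county],
        "year": am // 12,
        "month": am % 12 + 1,
        "global_score": score,
        **{f"score_{d}": domains[:, j] for j, d in enumerate(DOMAINS)},
        **{k: cov[k] for k in ("gender", "age", "residence", "education",
                               "income", "ethnicity")},
    })
    echo = truth.to_dict()
    echo["clamp_scores"] = config.clamp_scores
    echo["seed"] = config.seed
    return records, echo


def write_dataset(config: SyntheticConfig, out_dir) -> dict:
    """Generate and write records.csv, exposures.csv, adjacency.txt,
    truth.json under ``out_dir``; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = gen_county_graph(config)
    exposures = gen_exposures(config, graph)
    records, echo = gen_records(config, graph, exposures)
    paths = {
        "records": out / "records.csv",
        "exposures": out / "exposures.csv",
        "adjacency": out / "adjacency.txt",
        "truth": out / "truth.json",
    }
    records.to_csv(paths["records"], index=False)
    exposures.to_csv(paths["exposures"], index=False)
    write_adjacency(graph, paths["adjacency"])
    with open(paths["truth"], "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def generate_linked(config: SyntheticConfig, lag_window: int = 0,
                    lead_window: int = 0):
    """Generate, filter and link in one call (the test-suite workhorse)."""
    graph = gen_county_graph(config)
    exposures = gen_exposures(config, graph)
    records, echo = gen_records(config, graph, exposures)
    kept, _ = filter_records(records)
    linked = link_exposures(kept, exposures, graph, lag_window=lag_window,
                            lead_window=lead_window)
    return linked, config.truth, echo
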