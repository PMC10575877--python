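"""Domain types and data handling for the temperature–cognition study.

The unit of analysis is one MMSE examination of one older adult, located in a
county and a calendar month. Records are carried as :class:`pandas.DataFrame`
objects with a fixed column vocabulary; small dataclasses wrap the pieces that
need structure beyond a table (the county adjacency graph, the linked dataset).

Conventions
-----------
* Calendar time is a ``(year, month)`` pair; internally months are mapped to an
  absolute month number ``year * 12 + (month - 1)`` and, within a study span,
  to a gapless non-negative "study month index".
* The MMSE instrument here has 24 items partitioned into five domains and a
  global score of 0–30. The per-item point values of the survey instrument are
  not public; the shipped default weighting (six 2-point items in the
  attention–calculation domain, all other items 1 point) is a declared
  stand-in convention, configurable via :class:`MMSEConfig`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "COVARIATE_COLUMNS",
    "MMSEConfig",
    "CountyGraph",
    "LinkedDataset",
    "score_mmse",
    "filter_records",
    "link_exposures",
    "quartile_summary",
    "read_records_csv",
    "read_exposures_csv",
    "read_adjacency",
    "write_adjacency",
]

#: The five MMSE sub-domains, in reporting order.
DOMAINS = ("general", "reaction", "attention", "memory", "language")

#: Sociodemographic covariates every valid record must carry.
COVARIATE_COLUMNS = ("gender", "age", "residence", "education", "income", "ethnicity")

#: Score column names: global plus one per domain.
SCORE_COLUMNS = ("global_score",) + tuple(f"score_{d}" for d in DOMAINS)

N_ITEMS = 24
MAX_GLOBAL = 30


@dataclass(frozen=True)
class MMSEConfig:
    """Item weights and item→domain partition for the 24-item instrument.

    The default assigns items 0–5 to *general* (1 pt), 6–9 to *reaction*
    (1 pt), 10–15 to *attention* (2 pt each — the six double-weight items),
    16–19 to *memory* (1 pt) and 20–23 to *language* (1 pt), totalling 30.
    """

    weights: tuple = tuple([1] * 10 + [2] * 6 + [1] * 8)
    partition: tuple = tuple(
        ["general"] * 6 + ["reaction"] * 4 + ["attention"] * 6
        + ["memory"] * 4 + ["language"] * 4
    )

    def validate(self) -> None:
        if len(self.weights) != N_ITEMS or len(self.partition) != N_ITEMS:
            raise ValueError(f"weights and partition must have length {N_ITEMS}")
        if any(w <= 0 or int(w) != w for w in self.weights):
            raise ValueError("item weights must be positive integers")
        if sum(self.weights) != MAX_GLOBAL:
            raise ValueError(f"item weights must sum to {MAX_GLOBAL}, got {sum(self.weights)}")
        unknown = set(self.partition) - set(DOMAINS)
        if unknown:
            raise ValueError(f"items assigned to unknown domains: {sorted(unknown)}")


def score_mmse(item_responses, config: MMSEConfig | None = None):
    """Score one 24-item response vector.

    Parameters
    ----------
    item_responses
        Length-24 vector of 0/1 correctness indicators (non-negative integers;
        values are clipped to {0, 1} meaning incorrect/correct).
    config
        Weight/partition convention; defaults to the shipped stand-in.

    Returns
    -------
    (domain_scores, global_score)
        ``domain_scores`` is a length-5 integer array in :data:`DOMAINS`
        order; ``global_score`` is their sum, in [0, 30].
    """
    config = config or MMSEConfig()
    config.validate()
    resp = np.asarray(item_responses)
    if resp.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} item responses, got shape {resp.shape}")
    if np.any(resp < 0):
        raise ValueError("item responses must be non-negative")
    correct = (resp > 0).astype(int)
    weights = np.asarray(config.weights, dtype=int)
    domain_scores = np.zeros(len(DOMAINS), dtype=int)
    for i, dom in enumerate(config.partition):
        domain_scores[DOMAINS.index(dom)] += int(weights[i] * correct[i])
    return domain_scores, int(domain_scores.sum())


@dataclass(frozen=True)
class CountyGraph:
    """County identifiers plus a symmetric, self-loop-free adjacency."""

    county_ids: tuple
    edges: frozenset  # of frozenset pairs {a, b}

    @classmethod
    def from_edges(cls, county_ids, edge_pairs) -> "CountyGraph":
        ids = tuple(county_ids)
        known = set(ids)
        edges = set()
        for a, b in edge_pairs:
            if a == b:
                raise ValueError(f"self-loop on county {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown county")
            edges.add(frozenset((a, b)))
        return cls(ids, frozenset(edges))

    @property
    def n(self) -> int:
        return len(self.county_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.county_ids)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def components(self):
        """Connected components ("islands"), each a sorted tuple of ids."""
        return [tuple(sorted(c)) for c in nx.connected_components(self.to_networkx())]

    def degree(self) -> dict:
        g = self.to_networkx()
        return {c: g.degree(c) for c in self.county_ids}


@dataclass
class LinkedDataset:
    """Records annotated with their county-month exposures.

    ``df`` holds one row per kept record with score, covariate and exposure
    columns (``temperature_c``, ``precipitation_mm``, ``pm25_ugm3``; lagged
    months as ``temperature_c_lag{L}``, leads as ``temperature_c_lead{L}``)
    plus ``tindex``, the gapless study-month index derived from the exposure
    span. ``drop_log`` records every record removed during linkage.
    """

    df: pd.DataFrame
    graph: CountyGraph
    time_index: dict  # (year, month) -> int, gapless over exposure span
    drop_log: pd.DataFrame
    lag_window: int = 0
    lead_window: int = 0

    @property
    def n(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "LinkedDataset":
        """A new LinkedDataset restricted to ``mask`` (drop log not carried)."""
        return LinkedDataset(
            df=self.df.loc[mask].reset_index(drop=True),
            graph=self.graph,
            time_index=self.time_index,
            drop_log=self.drop_log.iloc[0:0],
            lag_window=self.lag_window,
            lead_window=self.lead_window,
        )


def _abs_month(year, month):
    return np.asarray(year, dtype=int) * 12 + (np.asarray(month, dtype=int) - 1)


def filter_records(records: pd.DataFrame,
                   require=("location", "covariates", "domains"),
                   dedupe_on: str = "subject_id"):
    """Apply the study's record-exclusion rules.

    Removes records with missing location, missing sociodemographic
    covariates, incomplete domain scores (fewer than all five), and duplicate
    subject ids (first occurrence kept, input order). Never raises on bad
    rows; every removal is logged with a reason.

    Returns ``(kept, exclusion_log)`` where the log has columns
    ``subject_id`` and ``reason``.
    """
    df = records.reset_index(drop=True)
    reasons = pd.Series([None] * len(df), dtype=object)

    def _missing(cols):
        present = [c for c in cols if c in df.columns]
        absent = [c for c in cols if c not in df.columns]
        m = pd.Series(False, index=df.index)
        if absent:  # a wholly absent column means every row lacks it
            m |= True
        for c in present:
            col = df[c]
            m |= col.isna()
            if col.dtype == object:
                m |= col.astype(str).str.strip().eq("")
        return m

    if "location" in require:
        m = _missing(["county_id"])
        reasons[m & reasons.isna()] = "missing location"
    if "covariates" in require:
        m = _missing(list(COVARIATE_COLUMNS))
        reasons[m & reasons.isna()] = "missing covariates"
    if "domains" in require:
        m = _missing([f"score_{d}" for d in DOMAINS])
        reasons[m & reasons.isna()] = "incomplete domains"
    if dedupe_on and dedupe_on in df.columns:
        ok = reasons.isna()
        dup = df.loc[ok, dedupe_on].duplicated(keep="first")
        reasons[dup[dup].index] = "duplicate id"

    excluded = ~reasons.isna()
    log = pd.DataFrame({
        "subject_id": df.loc[excluded, "subject_id"] if "subject_id" in df.columns
        else pd.Series(df.index[excluded].astype(str)),
        "reason": reasons[excluded],
    }).reset_index(drop=True)
    kept = df.loc[~excluded].reset_index(drop=True)
    return kept, log


def link_exposures(records: pd.DataFrame, exposures: pd.DataFrame,
                   graph: CountyGraph, lag_window: int = 0,
                   lead_window: int = 0) -> LinkedDataset:
    """Join each record to the exposure cell of its county and exam month.

    With ``lag_window=l`` each record additionally carries the temperatures of
    the ``l`` preceding months (``temperature_c_lag1`` …); ``lead_window``
    symmetrically for following months. Records whose window is not fully
    covered by the exposure table are dropped and logged.
    """
    if len(exposures) == 0:
        raise ValueError("empty exposure table")
    exp = exposures.copy()
    exp["_am"] = _abs_month(exp["year"], exp["month"])
    dup = exp.duplicated(subset=["county_id", "_am"])
    if dup.any():
        r = exp.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate exposure cell for county {r['county_id']} "
            f"{int(r['year'])}-{int(r['month'])}")
    lo = np.percentile(exp["temperature_c"], 0)
    hi = np.percentile(exp["temperature_c"], 100)
    if lo < -60 or hi > 60:
        raise ValueError(f"temperature outside plausible range [-60, 60]: [{lo}, {hi}]")

    cell = exp.set_index(["county_id", "_am"])  # fast lookup
    df = records.reset_index(drop=True).copy()
    df["_am"] = _abs_month(df["year"], df["month"])

    # gapless study-month index over the exposure span
    am_min, am_max = int(exp["_am"].min()), int(exp["_am"].max())
    time_index = {}
    for am in range(am_min, am_max + 1):
        time_index[(am // 12, am % 12 + 1)] = am - am_min

    offsets = [("", 0)]
    offsets += [(f"_lag{L}", -L) for L in range(1, lag_window + 1)]
    offsets += [(f"_lead{L}", +L) for L in range(1, lead_window + 1)]

    keep = np.ones(len(df), dtype=bool)
    drop_reason = {}
    cols = {f"temperature_c{suf}": np.full(len(df), np.nan) for suf, _ in offsets}
    cols["precipitation_mm"] = np.full(len(df), np.nan)
    cols["pm25_ugm3"] = np.full(len(df), np.nan)

    known = set(graph.county_ids)
    idx = cell.index
    for i, (cid, am) in enumerate(zip(df["county_id"], df["_am"])):
        if cid not in known:
            keep[i] = False
            drop_reason[i] = f"unknown county {cid}"
            continue
        if (cid, am) not in idx:
            keep[i] = False
            drop_reason[i] = f"no exposure for ({cid}, month {am})"
            continue
        row = cell.loc[(cid, am)]
        cols["precipitation_mm"][i] = row["precipitation_mm"]
        cols["pm25_ugm3"][i] = row["pm25_ugm3"]
        ok = True
        for suf, off in offsets:
            key = (cid, am + off)
            if key in idx:
                cols[f"temperature_c{suf}"][i] = cell.loc[key]["temperature_c"]
            else:
                ok = False
                which = "lag" if off < 0 else "lead"
                drop_reason[i] = f"incomplete {which} window"
                break
        if not ok:
            keep[i] = False

    for name, arr in cols.items():
        df[name] = arr
    df["tindex"] = df["_am"] - am_min

    drop_log = pd.DataFrame({
        "subject_id": [df.at[i, "subject_id"] if "subject_id" in df.columns else str(i)
                       for i in sorted(drop_reason)],
        "reason": [drop_reason[i] for i in sorted(drop_reason)],
    })
    out = df.loc[keep].drop(columns=["_am"]).reset_index(drop=True)
    return LinkedDataset(df=out, graph=graph, time_index=time_index,
                         drop_log=drop_log, lag_window=lag_window,
                         lead_window=lead_window)


def quartile_summary(linked: LinkedDataset, score_col: str = "global_score") -> pd.DataFrame:
    """Mean cognitive score by empirical temperature quartile.

    Quartile cut points come from the linked records' own temperature
    distribution; bins are left-closed/right-open except the last, which is
    closed. Empty bins are reported with ``n = 0``.
    """
    if linked.n < 4:
        raise ValueError("need at least 4 records for a quartile summary")
    t = linked.df["temperature_c"].to_numpy()
    s = linked.df[score_col].to_numpy()
    cuts = np.percentile(t, [25, 50, 75])
    labels = np.searchsorted(cuts, t, side="right")
    rows = []
    edges = [t.min(), *cuts, t.max()]
    for q in range(4):
        m = labels == q
        rows.append({
            "quartile": q + 1,
            "t_low": edges[q],
            "t_high": edges[q + 1],
            "mean_score": float(s[m].mean()) if m.any() else np.nan,
            "n": int(m.sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers / writers for the plain-text interchange formats
# ---------------------------------------------------------------------------

def read_records_csv(path) -> pd.DataFrame:
    """Read a subject-exam records CSV (one row per exam, empty cells = NA)."""
    return pd.read_csv(path, dtype={"subject_id": str, "county_id": str})


def read_exposures_csv(path) -> pd.DataFrame:
    """Read a county-month exposure CSV.

    Expects columns county_id, year, month, temperature_c, precipitation_mm,
    pm25_ugm3.
    """
    df = pd.read_csv(path, dtype={"county_id": str})
    needed = {"county_id", "year", "month", "temperature_c",
              "precipitation_mm", "pm25_ugm3"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"exposure table missing columns: {sorted(missing)}")
    return df


def read_adjacency(path) -> list:
    """Read a two-column edge list (whitespace- or comma-delimited)."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    edges = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"malformed adjacency line: {line!r}")
        edges.append((parts[0], parts[1]))
    return edges


def write_adjacency(graph: CountyGraph, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{e[0]} {e[1]}\n")
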