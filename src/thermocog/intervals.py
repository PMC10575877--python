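"""Piecewise interval effects: score change per 1 degC inside a temperature band.

Within each temperature interval the model is refit on the records whose
current-month temperature falls inside it, with the temperature term linear
and the full random-effect structure retained. The reported quantity is the
*decline per degree*, signed so that a positive value always means the score
worsens as temperature moves away from the reference:

* hot side (above the reference): decline = -beta, the score drop per +1 degC;
* cold side (below the reference): decline = +beta, the score drop per 1 degC
  decrease (a positive beta means the score falls as temperature falls).

Credible intervals are transformed draw-wise under the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import LinkedDataset
from .model import ModelSpec, TemperatureLinear, fit

__all__ = ["TemperatureInterval", "IntervalEffect", "default_intervals",
           "interval_effect", "interval_profile"]

DEFAULT_MIN_RECORDS = 50


@dataclass(frozen=True)
class TemperatureInterval:
    """Half-open [low, high) temperature band (topmost band closed)."""

    low: float
    high: float
    side: str  # "cold" (below reference) or "hot" (above)
    closed_top: bool = False

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError(f"interval low {self.low} must be < high {self.high}")
        if self.side not in ("cold", "hot"):
            raise ValueError("side must be 'cold' or 'hot'")

    def contains(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.closed_top:
            return (t >= self.low) & (t <= self.high)
        return (t >= self.low) & (t < self.high)

    def overlaps(self, other: "TemperatureInterval") -> bool:
        return self.low < other.high and other.low < self.high


def default_intervals(reference: float = -7.0,
                      t_min: float = -14.0, t_max: float = 31.0) -> list:
    """The study's five bands: cold [t_min, reference), then hot bands
    [reference, 5), [5, 15), [15, 25), [25, t_max]."""
    return [
        TemperatureInterval(t_min, reference, "cold"),
        TemperatureInterval(reference, 5.0, "hot"),
        TemperatureInterval(5.0, 15.0, "hot"),
        TemperatureInterval(15.0, 25.0, "hot"),
        TemperatureInterval(25.0, t_max, "hot", closed_top=True),
    ]


@dataclass
class IntervalEffect:
    """Per-degree score decline inside one temperature band."""

    interval: TemperatureInterval
    decline_per_degree: float
    ci_low: float
    ci_high: float
    n_records: int
    outcome: str
    fit_result: object = None

    def decline_draws(self) -> np.ndarray:
        sign = -1.0 if self.interval.side == "hot" else 1.0
        return sign * self.fit_result.temperature_draws()[0]


def interval_effect(linked: LinkedDataset, interval: TemperatureInterval,
                    spec: ModelSpec,
                    min_records: int = DEFAULT_MIN_RECORDS) -> IntervalEffect:
    """Linear temperature effect on the records inside ``interval``."""
    t = linked.df["temperature_c"].to_numpy(dtype=float)
    if interval.low > t.max() or interval.high < t.min():
        raise ValueError(
            f"interval [{interval.low}, {interval.high}) lies outside the "
            f"observed range [{t.min():.1f}, {t.max():.1f}]")
    mask = interval.contains(t)
    n_in = int(mask.sum())
    if n_in < min_records:
        raise ValueError(
            f"only {n_in} records inside [{interval.low}, {interval.high}); "
            f"minimum is {min_records}")
    sub = linked.subset(mask)
    ispec = replace(spec, temperature_term=TemperatureLinear())
    fr = fit(sub, ispec)
    beta = fr.temperature_draws()[0]
    sign = -1.0 if interval.side == "hot" else 1.0
    decline = sign * beta
    return IntervalEffect(
        interval=interval,
        decline_per_degree=float(decline.mean()),
        ci_low=float(np.quantile(decline, 0.025)),
        ci_high=float(np.quantile(decline, 0.975)),
        n_records=n_in,
        outcome=spec.outcome,
        fit_result=fr,
    )


def interval_profile(linked: LinkedDataset, intervals, spec: ModelSpec,
                     outcomes=("global_score",),
                     min_records: int = DEFAULT_MIN_RECORDS) -> pd.DataFrame:
    """One row per (interval, outcome); sparse or failing cells are flagged.

    Overlapping intervals are rejected up front. Rows that cannot be fit
    (too few records, degenerate design) appear with NaN estimates and the
    reason in the ``flag`` column rather than being dropped.
    """
    intervals = list(intervals)
    for i, a in enumerate(intervals):
        for b in intervals[i + 1:]:
            if a.overlaps(b):
                raise ValueError(
                    f"overlapping intervals [{a.low}, {a.high}) and "
                    f"[{b.low}, {b.high})")
    rows = []
    for itv in intervals:
        for oc in outcomes:
            ospec = replace(spec, outcome=oc)
            row = {"outcome": oc, "interval_low": itv.low,
                   "interval_high": itv.high, "side": itv.side,
                   "decline_per_degree": np.nan, "ci_low": np.nan,
                   "ci_high": np.nan, "n_records": 0, "flag": ""}
            try:
                eff = interval_effect(linked, itv, ospec, min_records)
                row.update(decline_per_degree=eff.decline_per_degree,
                           ci_low=eff.ci_low, ci_high=eff.ci_high,
                           n_records=eff.n_records)
            except ValueError as exc:
                row["flag"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
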