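"""Displacement (distributed lag and lead) effects of monthly temperature.

The current-month temperature and the temperatures of up to ``l_max``
preceding (lag) or following (lead) months enter the model jointly; the
coefficients beta^0..beta^l are their per-degree score effects. The *overall
effect* is the draw-wise sum of the coefficients over a chosen offset set —
by default {0, 1} (current plus previous month, the summary the study settles
on after finding offsets beyond L-1 insignificant); the full 0..l_max sum
remains available. Summing draws, not intervals, so the overall CI reflects
the posterior correlation between offsets.

Regime restriction: the fit is restricted to records whose *current-month*
temperature lies in the cold or hot interval; the lagged/led regressors are
not range-restricted. Declines are signed per the interval convention
(hot: -beta, cold: +beta).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import LinkedDataset
from .intervals import TemperatureInterval, DEFAULT_MIN_RECORDS
from .model import DistributedLag, ModelSpec, fit

__all__ = ["DisplacementEffect", "displacement_fit", "overall_effect",
           "DEFAULT_OVERALL_OFFSETS"]

#: Offsets summed in the default overall effect (current + previous month).
DEFAULT_OVERALL_OFFSETS = (0, 1)


@dataclass
class DisplacementEffect:
    """Joint per-offset temperature effects and their overall summary."""

    direction: str                 # "lag" or "lead"
    l_max: int
    interval: TemperatureInterval | None
    outcome: str
    beta_draws: np.ndarray         # (l_max + 1, n_draws), raw coefficients
    table: pd.DataFrame            # offset, beta, decline and CIs
    overall: dict                  # estimate, ci_low, ci_high, offsets
    n_records: int
    fit_result: object = None

    @property
    def sign(self) -> float:
        return 1.0 if (self.interval is not None and
                       self.interval.side == "cold") else -1.0

    def decline_draws(self, offsets) -> np.ndarray:
        offsets = sorted(set(int(o) for o in offsets))
        if not offsets:
            raise ValueError("empty offset set")
        bad = [o for o in offsets if o < 0 or o > self.l_max]
        if bad:
            raise ValueError(f"offsets {bad} outside fitted range 0..{self.l_max}")
        return self.sign * self.beta_draws[offsets].sum(axis=0)


def displacement_fit(linked: LinkedDataset,
                     interval: TemperatureInterval | None,
                     direction: str = "lag", l_max: int = 3,
                     spec: ModelSpec | None = None,
                     overall_offsets=DEFAULT_OVERALL_OFFSETS,
                     min_records: int = DEFAULT_MIN_RECORDS) -> DisplacementEffect:
    """Joint distributed lag (or lead) fit within a temperature regime.

    ``interval=None`` fits the whole temperature range. The linked data must
    carry the matching exposure window columns.
    """
    spec = spec or ModelSpec()
    if interval is not None:
        mask = interval.contains(linked.df["temperature_c"].to_numpy(dtype=float))
        n_in = int(mask.sum())
        if n_in < min_records:
            raise ValueError(
                f"only {n_in} records in the {interval.side} regime "
                f"[{interval.low}, {interval.high}); minimum is {min_records}")
        sub = linked.subset(mask)
    else:
        sub = linked
        n_in = sub.n
    dspec = replace(spec, temperature_term=DistributedLag(l_max=l_max,
                                                          direction=direction))
    fr = fit(sub, dspec)
    beta = fr.temperature_draws()          # (l_max + 1, n_draws)
    sign = 1.0 if (interval is not None and interval.side == "cold") else -1.0
    rows = []
    for L in range(l_max + 1):
        b = beta[L]
        d = sign * b
        rows.append({"offset": L, "beta": float(b.mean()),
                     "beta_lo": float(np.quantile(b, 0.025)),
                     "beta_hi": float(np.quantile(b, 0.975)),
                     "decline": float(d.mean()),
                     "decline_lo": float(np.quantile(d, 0.025)),
                     "decline_hi": float(np.quantile(d, 0.975))})
    eff = DisplacementEffect(
        direction=direction, l_max=l_max, interval=interval,
        outcome=spec.outcome, beta_draws=beta, table=pd.DataFrame(rows),
        overall={}, n_records=n_in, fit_result=fr)
    est, ci = overall_effect(eff, overall_offsets)
    eff.overall = {"estimate": est, "ci_low": ci[0], "ci_high": ci[1],
                   "offsets": tuple(sorted(set(int(o) for o in overall_offsets)))}
    return eff


def overall_effect(effect: DisplacementEffect, offsets=DEFAULT_OVERALL_OFFSETS):
    """Draw-wise sum of per-offset declines over ``offsets``.

    Returns ``(estimate, (ci_low, ci_high))``. Deterministic given the fit's
    draws.
    """
    d = effect.decline_draws(offsets)
    return float(d.mean()), (float(np.quantile(d, 0.025)),
                             float(np.quantile(d, 0.975)))
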