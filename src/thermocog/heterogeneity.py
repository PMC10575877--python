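"""Subgroup heterogeneity of the overall temperature effect, and the
sensitivity grid over confounder combinations.

Subgroup effects are overall displacement effects (current + previous month by
default) estimated within each level of a sociodemographic grouping, with the
full random-effect structure retained inside each subgroup fit. Two subgroups
are compared by the interval

    (Q1 - Q2) +/- 1.96 * sqrt(SE1 + SE2)        ["as_printed"]

with the indicator |Q1 - Q2| / sqrt(SE1 + SE2) declared significant at >= 2.
The unsquared sum of standard errors is the formula as published; it is not
scale-invariant (its units are mixed), so the conventional Wald form
sqrt(SE1^2 + SE2^2) is implemented alongside as rule "squared" and both are
reported — neither silently replaces the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LinkedDataset
from .displacement import (DEFAULT_OVERALL_OFFSETS, DisplacementEffect,
                           displacement_fit)
from .intervals import DEFAULT_MIN_RECORDS, TemperatureInterval
from .model import ModelSpec

__all__ = ["SubgroupEffect", "HeterogeneityResult", "default_bands",
           "subgroup_effects", "heterogeneity_test", "sensitivity_grid"]


#: Default level definitions for the grouping variables whose cut points the
#: survey instrument does not fix. Age bands follow the ">95 years" edge the
#: study singles out; education and income are coarse ordinal bands.
DEFAULT_BANDS = {
    "age": ((65, 80), (80, 95), (95, 200)),
    "education": ("low", "medium", "high"),
    "income": ("low", "medium", "high"),
}


def default_bands() -> dict:
    return {k: v for k, v in DEFAULT_BANDS.items()}


@dataclass
class SubgroupEffect:
    """Overall temperature effect within one subgroup level."""

    grouping: str
    level: str
    regime: str                    # "cold" or "hot"
    estimate: float                # Q hat (overall decline)
    se: float                      # posterior sd of the summed decline draws
    ci_low: float
    ci_high: float
    n_records: int
    displacement: DisplacementEffect | None = None


@dataclass
class HeterogeneityResult:
    """Pairwise between-subgroup comparison."""

    effect_1: SubgroupEffect
    effect_2: SubgroupEffect
    rule: str                      # "as_printed" or "squared"
    diff: float
    interval: tuple                # diff -/+ 1.96 * combined
    indicator: float
    significant: bool


def _level_series(df: pd.DataFrame, grouping: str, bands: dict) -> pd.Series:
    if grouping == "age":
        age = df["age"].astype(float)
        lab = pd.Series("", index=df.index, dtype=object)
        for lo, hi in bands.get("age", DEFAULT_BANDS["age"]):
            m = (age >= lo) & (age < hi)
            lab[m] = f"{lo}-{hi}" if hi < 200 else f">{lo}"
        return lab
    return df[grouping].astype(str)


def subgroup_effects(linked: LinkedDataset, grouping: str,
                     regime: TemperatureInterval, spec: ModelSpec,
                     bands: dict | None = None, direction: str = "lag",
                     l_max: int = 3, overall_offsets=DEFAULT_OVERALL_OFFSETS,
                     min_records: int = DEFAULT_MIN_RECORDS) -> list:
    """One overall displacement effect per level of ``grouping``.

    Levels that fail the minimum-record guard (or whose fit fails) are
    returned with NaN estimates and ``n_records`` filled, flagged via
    ``se = nan`` — skipped, never silently merged.
    """
    bands = bands or default_bands()
    levels = _level_series(linked.df, grouping, bands)
    out = []
    for lev in sorted(levels.unique()):
        mask = (levels == lev).to_numpy()
        n_lev = int(mask.sum())
        try:
            sub = linked.subset(mask)
            eff = displacement_fit(sub, regime, direction=direction,
                                   l_max=l_max, spec=spec,
                                   overall_offsets=overall_offsets,
                                   min_records=min_records)
            draws = eff.decline_draws(overall_offsets)
            out.append(SubgroupEffect(
                grouping=grouping, level=str(lev), regime=regime.side,
                estimate=float(draws.mean()), se=float(draws.std(ddof=1)),
                ci_low=float(np.quantile(draws, 0.025)),
                ci_high=float(np.quantile(draws, 0.975)),
                n_records=eff.n_records, displacement=eff))
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"subgroup {grouping}={lev} skipped: {exc}")
            out.append(SubgroupEffect(grouping=grouping, level=str(lev),
                                      regime=regime.side, estimate=np.nan,
                                      se=np.nan, ci_low=np.nan,
                                      ci_high=np.nan, n_records=n_lev))
    return out


def heterogeneity_test(e1: SubgroupEffect, e2: SubgroupEffect,
                       variance_rule: str = "as_printed") -> HeterogeneityResult:
    """Between-subgroup significance of the temperature-effect difference.

    Antisymmetric in argument order: the interval negates, the indicator and
    the significance verdict are unchanged.
    """
    if variance_rule not in ("as_printed", "squared"):
        raise ValueError("variance_rule must be 'as_printed' or 'squared'")
    if e1.regime != e2.regime:
        raise ValueError(f"mismatched regimes: {e1.regime} vs {e2.regime}")
    if not (e1.se > 0 and e2.se > 0):
        raise ValueError("subgroup standard errors must be positive")
    if variance_rule == "as_printed":
        warnings.warn(
            "the as_printed rule sqrt(SE1 + SE2) sums standard errors "
            "unsquared and is not scale-invariant; the 'squared' Wald rule "
            "is available", stacklevel=2)
        comb = np.sqrt(e1.se + e2.se)
    else:
        comb = np.sqrt(e1.se ** 2 + e2.se ** 2)
    diff = e1.estimate - e2.estimate
    indicator = abs(diff) / comb
    return HeterogeneityResult(
        effect_1=e1, effect_2=e2, rule=variance_rule, diff=float(diff),
        interval=(float(diff - 1.96 * comb), float(diff + 1.96 * comb)),
        indicator=float(indicator), significant=bool(indicator >= 2.0))


#: Confounder components togglable in the sensitivity grid, mapped to the
#: ModelSpec flags each one controls.
SENSITIVITY_COMPONENTS = {
    "county_effects": ("county_bym_intercept", "county_slope"),
    "month_effects": ("month_rw_intercept", "month_slope"),
    "interaction": ("interaction", "interaction_slope"),
    "precipitation": ("precipitation",),
    "pm25": ("pm25",),
}


def sensitivity_grid(linked: LinkedDataset, base_spec: ModelSpec, toggles,
                     cold: TemperatureInterval, hot: TemperatureInterval,
                     direction: str = "lag", l_max: int = 3,
                     overall_offsets=DEFAULT_OVERALL_OFFSETS,
                     min_records: int = DEFAULT_MIN_RECORDS) -> pd.DataFrame:
    """Overall cold/hot effects under varied confounder combinations.

    ``toggles`` is an iterable of subsets (iterables) of
    :data:`SENSITIVITY_COMPONENTS` keys naming the components *removed* from
    the full model in that row. The full model is always the first
    (reference) row. Per-row failures are flagged in ``status``; the rest of
    the grid is still produced.
    """
    from dataclasses import replace

    rows = []
    subsets = [()] + [tuple(t) for t in toggles]
    for sub_toggle in subsets:
        bad = set(sub_toggle) - set(SENSITIVITY_COMPONENTS)
        if bad:
            raise ValueError(f"unknown sensitivity components: {sorted(bad)}")
        spec = base_spec
        for comp in sub_toggle:
            for flag in SENSITIVITY_COMPONENTS[comp]:
                spec = replace(spec, **{flag: False})
        row = {"removed": "+".join(sub_toggle) if sub_toggle else "(full model)",
               "cold_overall": np.nan, "cold_lo": np.nan, "cold_hi": np.nan,
               "hot_overall": np.nan, "hot_lo": np.nan, "hot_hi": np.nan,
               "status": "ok"}
        for regime, prefix in ((cold, "cold"), (hot, "hot")):
            try:
                eff = displacement_fit(linked, regime, direction=direction,
                                       l_max=l_max, spec=spec,
                                       overall_offsets=overall_offsets,
                                       min_records=min_records)
                row[f"{prefix}_overall"] = eff.overall["estimate"]
                row[f"{prefix}_lo"] = eff.overall["ci_low"]
                row[f"{prefix}_hi"] = eff.overall["ci_high"]
            except (ValueError, RuntimeError) as exc:
                row["status"] = f"{prefix} failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
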