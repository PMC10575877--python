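"""Exposure-response curves: deviation of the score from a reference temperature.

The fitted nonlinear temperature contribution g(T) is identified only up to a
constant, so it is reported as a contrast against a reference temperature:
deviation(T) = g(T) - g(T_ref), computed draw-wise so the 95% band comes from
the posterior of the contrast itself and has exactly zero width at the
reference. The default global reference is -7 deg C; a per-outcome preset from
the study's results section ships alongside (the two presets disagree for the
global score, -7 vs -6, and name five values for six outcomes — both are kept
as published, unresolved).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import LinkedDataset, DOMAINS
from .model import FitResult, ModelSpec, TemperatureBasis, fit, select_basis

__all__ = ["ResponseCurve", "curve_from_fit", "find_peak_reference",
           "curves_all_outcomes", "OUTCOMES", "REFERENCE_PRESETS",
           "default_grid"]

#: The six outcome score columns: global plus the five sub-domains.
OUTCOMES = ("global_score",) + tuple(f"score_{d}" for d in DOMAINS)

#: Named reference-temperature presets (deg C). "methods" applies the stated
#: global reference to every outcome; "results" carries the per-outcome values
#: as printed — five values for six outcomes, the last left unresolved (None
#: falls back to the methods value).
REFERENCE_PRESETS = {
    "methods": {o: -7.0 for o in OUTCOMES},
    "results": {"global_score": -6.0, "score_general": -2.0,
                "score_reaction": -5.0, "score_attention": -3.0,
                "score_memory": -6.0, "score_language": None},
}


@dataclass
class ResponseCurve:
    """Deviation-from-reference curve with draw-wise 95% credible band."""

    grid: np.ndarray
    deviation: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference_temperature: float
    outcome: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature_c": self.grid,
                             "deviation": self.deviation,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def default_grid(linked: LinkedDataset, step: float = 0.5) -> np.ndarray:
    """Observed temperature min to max in ``step`` degC increments."""
    t = linked.df["temperature_c"]
    return np.arange(float(t.min()), float(t.max()) + step / 2, step)


def _contribution_draws(fr: FitResult, grid: np.ndarray) -> np.ndarray:
    if fr.basis is None:
        raise ValueError(
            "response curves need a basis temperature term; interval (linear) "
            "fits are summarised by interval_effect instead")
    B = fr.basis.evaluate(grid)
    return B @ fr.temperature_draws()


def curve_from_fit(fr: FitResult, reference: float, grid) -> ResponseCurve:
    """Deviation-from-reference curve from a basis-term fit.

    The reference must lie inside the fitted temperature range; it is inserted
    into the grid if absent so the exact zero at the reference is part of the
    curve.
    """
    tmin = float(fr.basis.temperatures.min()) if fr.basis is not None else None
    if fr.basis is None:
        _contribution_draws(fr, np.array([0.0]))  # raises with the right message
    tmax = float(fr.basis.temperatures.max())
    if not (tmin <= reference <= tmax):
        raise ValueError(f"reference {reference} degC outside the observed "
                         f"range [{tmin}, {tmax}]")
    grid = np.sort(np.unique(np.append(np.asarray(grid, dtype=float), reference)))
    G = _contribution_draws(fr, grid)
    # take the reference row out of the same matrix product so the
    # self-contrast is exactly zero in floating point
    ref_idx = int(np.searchsorted(grid, reference))
    dev = G - G[ref_idx][None, :]
    return ResponseCurve(
        grid=grid,
        deviation=dev.mean(axis=1),
        ci_low=np.quantile(dev, 0.025, axis=1),
        ci_high=np.quantile(dev, 0.975, axis=1),
        reference_temperature=float(reference),
        outcome=fr.spec.outcome,
    )


def find_peak_reference(fr: FitResult, grid) -> float:
    """Grid temperature maximising the posterior-mean contribution.

    Ties break toward the lowest temperature (first grid hit).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    grid = np.sort(grid)
    mean_contrib = _contribution_draws(fr, grid).mean(axis=1)
    return float(grid[int(np.argmax(mean_contrib))])


def curves_all_outcomes(linked: LinkedDataset, spec: ModelSpec,
                        outcomes=OUTCOMES, references=None,
                        candidates=None, grid=None) -> dict:
    """One response curve per outcome, sharing a single basis.

    If ``candidates`` is given, the basis is chosen once by DIC on the first
    outcome (the study's procedure: select on the global score, then apply the
    winner to every sub-domain); otherwise ``spec``'s own basis term is used.
    ``references`` maps outcome -> reference degC; missing entries fall back
    to the "methods" preset. Per-outcome failures are reported in the result
    (value None plus an "errors" entry) without aborting the rest.

    Returns ``{"curves": {outcome: ResponseCurve|None}, "errors": {...},
    "basis": BasisSpec, "dic_table": DataFrame|None}``.
    """
    outcomes = list(outcomes)
    refs = dict(references or {})
    if grid is None:
        grid = default_grid(linked)
    dic_table = None
    if candidates is not None:
        sel = select_basis(linked, candidates, replace(spec, outcome=outcomes[0]))
        basis_spec = sel.winner
        dic_table = sel.table
    elif isinstance(spec.temperature_term, TemperatureBasis):
        basis_spec = spec.temperature_term.spec
    else:
        raise ValueError("spec must carry a basis temperature term or "
                         "candidates must be provided")
    curves, errors = {}, {}
    for oc in outcomes:
        ref = refs.get(oc)
        if ref is None:
            ref = REFERENCE_PRESETS["methods"].get(oc, -7.0)
        try:
            ospec = replace(spec.with_temperature(TemperatureBasis(basis_spec)),
                            outcome=oc)
            fr = fit(linked, ospec)
            curves[oc] = curve_from_fit(fr, ref, grid)
        except Exception as exc:  # keep going; report per outcome
            curves[oc] = None
            errors[oc] = str(exc)
    return {"curves": curves, "errors": errors, "basis": basis_spec,
            "dic_table": dic_table}
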