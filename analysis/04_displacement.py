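"""Distributed lag and lead (displacement) effects of temperature.

For the cold regime (below the reference) and the hot regime (the hottest
band) the current month's temperature enters jointly with up to three
preceding (lag) or following (lead) months. The overall effect — the sum of
the current- and previous-month declines — is the study's headline summary.
Writes results/tables/displacement.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import thermocog as tc
from thermocog.displacement import displacement_fit
from thermocog.intervals import TemperatureInterval
from thermocog.model import InferenceConfig, ModelSpec

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "fit_curves", Path(__file__).parent / "02_fit_curves.py")
_fc = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_fc)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--reference", type=float, default=-7.0)
    args = ap.parse_args()

    linked = _fc.load_linked(args.out / "data", lag_window=3)
    t = linked.df["temperature_c"]
    cold = TemperatureInterval(float(t.min()), args.reference, "cold")
    hot = TemperatureInterval(25.0, float(t.max()), "hot", closed_top=True)
    spec = ModelSpec(interaction_slope=False,
                     inference=InferenceConfig(n_draws=400, seed=args.seed))

    rows = []
    for regime in (cold, hot):
        eff = displacement_fit(linked, regime, "lag", 3, spec)
        tab = eff.table.assign(regime=regime.side, direction="lag")
        rows.append(tab)
        o = eff.overall
        print(f"{regime.side} regime overall effect (offsets {o['offsets']}): "
              f"{o['estimate']:+.3f} score per 1 degC "
              f"(95% CI {o['ci_low']:+.3f} to {o['ci_high']:+.3f}, "
              f"n={eff.n_records})")
        rows.append(pd.DataFrame([{
            "offset": "overall", "regime": regime.side, "direction": "lag",
            "decline": o["estimate"], "decline_lo": o["ci_low"],
            "decline_hi": o["ci_high"]}]))

    lead_linked = tc.link_exposures(
        tc.filter_records(tc.read_records_csv(args.out / "data" / "records.csv"))[0],
        tc.read_exposures_csv(args.out / "data" / "exposures.csv"),
        linked.graph, lead_window=3)
    for regime in (cold, hot):
        eff = displacement_fit(lead_linked, regime, "lead", 3, spec)
        rows.append(eff.table.assign(regime=regime.side, direction="lead"))
        sig = [int(L) for L in range(1, 4)
               if not (eff.table.loc[L, "decline_lo"] < 0
                       < eff.table.loc[L, "decline_hi"])]
        print(f"{regime.side} lead offsets with CIs excluding zero: "
              f"{sig or 'none'}")

    out = pd.concat(rows, ignore_index=True)
    tables = args.out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    out.to_csv(tables / "displacement.csv", index=False)
    print(f"\nfull table: {tables / 'displacement.csv'}")


if __name__ == "__main__":
    main()
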