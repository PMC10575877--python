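"""Quantify the per-degree score decline inside each temperature interval.

The temperature range is divided into the study's five bands (one cold band
below the reference, four hot bands above it) and the model is refit with a
linear temperature term on the records inside each band. Writes
results/tables/interval_effects.csv.
"""

import argparse
from pathlib import Path

import thermocog as tc
from thermocog.intervals import default_intervals, interval_profile
from thermocog.model import InferenceConfig, ModelSpec
from thermocog.response import OUTCOMES

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

    linked = _fc.load_linked(args.out / "data")
    spec = ModelSpec(interaction_slope=False,
                     inference=InferenceConfig(n_draws=400, seed=args.seed))
    t = linked.df["temperature_c"]
    intervals = default_intervals(reference=args.reference,
                                  t_min=float(t.min()), t_max=float(t.max()))
    prof = interval_profile(linked, intervals, spec, outcomes=OUTCOMES)
    tables = args.out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    prof.to_csv(tables / "interval_effects.csv", index=False)

    g = prof[prof["outcome"] == "global_score"]
    print("global score, decline per 1 degC away from the reference:")
    for _, r in g.iterrows():
        if r["flag"]:
            print(f"  [{r.interval_low:6.1f}, {r.interval_high:6.1f}) "
                  f"{r.side:4s}  skipped: {r.flag}")
        else:
            print(f"  [{r.interval_low:6.1f}, {r.interval_high:6.1f}) "
                  f"{r.side:4s}  {r.decline_per_degree:+.3f} "
                  f"(95% CI {r.ci_low:+.3f} to {r.ci_high:+.3f}, "
                  f"n={int(r.n_records)})")
    print(f"\nfull table ({len(prof)} rows): "
          f"{tables / 'interval_effects.csv'}")


if __name__ == "__main__":
    main()
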