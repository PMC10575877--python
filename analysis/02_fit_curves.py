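"""Select the temperature-response basis by DIC and fit exposure-response
curves for the global score and the five sub-domain scores.

Reads results/data/ (from 01_simulate.py), writes the DIC comparison table
and one deviation-from-reference curve CSV per outcome under
results/curves/, and a plot of the global curve under results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

import thermocog as tc
from thermocog.basis import BasisSpec
from thermocog.model import InferenceConfig, ModelSpec
from thermocog.response import curves_all_outcomes, default_grid

CANDIDATES = [BasisSpec("polynomial", 3), BasisSpec("bspline", 3),
              BasisSpec("ncs3"), BasisSpec("ncs5")]


def load_linked(data_dir: Path, lag_window=0):
    recs = tc.read_records_csv(data_dir / "records.csv")
    exps = tc.read_exposures_csv(data_dir / "exposures.csv")
    edges = tc.read_adjacency(data_dir / "adjacency.txt")
    ids = sorted(set(recs["county_id"]) | {c for e in edges for c in e})
    graph = tc.CountyGraph.from_edges(ids, edges)
    kept, log = tc.filter_records(recs)
    return tc.link_exposures(kept, exps, graph, lag_window=lag_window)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    linked = load_linked(args.out / "data")
    spec = ModelSpec(interaction_slope=False,
                     inference=InferenceConfig(n_draws=400, seed=args.seed))
    out = curves_all_outcomes(linked, spec, candidates=CANDIDATES)

    cdir = args.out / "curves"
    cdir.mkdir(parents=True, exist_ok=True)
    out["dic_table"].to_csv(cdir / "dic_table.csv", index=False)
    print("DIC comparison (winner applied to all outcomes):")
    print(out["dic_table"].to_string(index=False,
                                     float_format=lambda v: f"{v:.1f}"))
    print(f"-> selected basis: {out['basis'].kind}")

    for oc, curve in out["curves"].items():
        if curve is None:
            print(f"{oc}: FAILED ({out['errors'][oc]})")
            continue
        curve.to_frame().to_csv(cdir / f"curve_{oc}.csv", index=False)
        lo = curve.deviation[0]
        hi = curve.deviation[-1]
        print(f"{oc}: deviation {lo:+.2f} at {curve.grid[0]:.1f} degC, "
              f"{hi:+.2f} at {curve.grid[-1]:.1f} degC "
              f"(ref {curve.reference_temperature} degC)")

    g = out["curves"]["global_score"]
    if g is not None:
        fdir = args.out / "figures"
        fdir.mkdir(parents=True, exist_ok=True)
        fig, ax = plt.subplots(figsize=(7, 4.5))
        ax.fill_between(g.grid, g.ci_low, g.ci_high, alpha=0.25,
                        label="95% credible band")
        ax.plot(g.grid, g.deviation, lw=2, label="posterior mean")
        ax2 = ax.twinx()
        ax2.hist(linked.df["temperature_c"], bins=40, alpha=0.2, color="gray")
        ax2.set_yticks([])
        ax.axvline(g.reference_temperature, ls=":", c="k")
        ax.set_xlabel("monthly mean temperature (degC)")
        ax.set_ylabel("change in global MMSE score vs reference")
        ax.legend()
        fig.tight_layout()
        fig.savefig(fdir / "curve_global.png", dpi=120)
        print(f"figure: {fdir / 'curve_global.png'}")


if __name__ == "__main__":
    main()
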