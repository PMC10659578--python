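#!/usr/bin/env python
"""Generate one seeded synthetic dataset per experiment fixture.

Bulky matrices go to scratch/datasets (regenerable from the logged seed);
a small inventory table is written to results/dataset_inventory.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from steapkin import fixtures
from steapkin.io_ import (write_bli, write_rapid_scan, write_timecourse,
                          write_titration)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    out = ROOT / "scratch" / "datasets"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, fx in fixtures.FIXTURES.items():
        if fx.kind == "rapid_scan":
            ds = fixtures.rapid_scan(name, seed=args.seed)
            write_rapid_scan(ds, out / f"{name}.csv")
            shape = f"{ds.time_s.size} x {ds.grid_nm.size}"
        elif fx.kind == "timecourse":
            tc = fixtures.timecourse(name, seed=args.seed)
            write_timecourse(tc, out / f"{name}.csv")
            shape = f"{tc.time_s.size} pts"
        elif fx.kind == "oxidation":
            n = 0
            for s_uM in fx.params["substrate_uM"]:
                tc = fixtures.oxidation_timecourse(name, s_uM, seed=args.seed)
                write_timecourse(tc, out / f"{name}_{s_uM:g}uM.csv")
                n += tc.time_s.size
            shape = f"{len(fx.params['substrate_uM'])} traces"
        elif fx.kind == "bli":
            series = fixtures.bli(seed=args.seed)
            write_bli(series, out / f"{name}.csv")
            shape = f"{series.analyte_uM.size} concentrations"
        else:
            table = fixtures.titration(name, seed=args.seed)
            write_titration(table, out / f"{name}.csv")
            shape = f"{table.substrate_uM.size} pts"
        rows.append({"fixture": name, "kind": fx.kind, "seed": args.seed,
                     "size": shape, "citation": fx.citation})
        print(f"{name:24s} {fx.kind:12s} {shape}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "dataset_inventory.csv", index=False)
    print(f"\nwrote {results / 'dataset_inventory.csv'}; datasets in {out}")


if __name__ == "__main__":
    main()
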