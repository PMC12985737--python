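#!/usr/bin/env python
"""Hotspot usage and within-hotspot reduction between the two populations.

Computes each population's hotspot usage (share of mapped crossovers per
hotspot span), writes usage and reduction tables under results/hotspots/,
and compares the recovered central-hotspot reduction with the 47.2%
suppression built into the generator in analysis/01.
"""

import argparse
from pathlib import Path

import pandas as pd

from xomap import landscape as ls
from xomap import xo_mapper
from xomap.xo_mapper import CallStatus

BUILT_IN_REDUCTION = 47.2  # share-space suppression of Coco built into the sim


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--xodir", type=Path, default=Path("results/xo"))
    parser.add_argument("--outdir", type=Path, default=Path("results/hotspots"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    hotspots = ls.read_hotspot_bed(args.simdir / "hotspots.bed")
    usages = {}
    for label in ("control", "suppressed"):
        ok = [
            c
            for c in xo_mapper.read_crossover_bed(args.xodir / f"xo_{label}.bed")
            if c.status is CallStatus.OK
        ]
        usage = ls.hotspot_usage(ok, hotspots)
        ls.write_usage_tsv(usage, args.outdir / f"usage_{label}.tsv")
        usages[label] = usage
        shares = ", ".join(f"{k} {v:.3f}" for k, v in usage.shares.items())
        print(f"{label} (n = {usage.n_calls} OK calls): {shares}, "
              f"background {usage.background:.3f}")

    rows = []
    for h in hotspots:
        red = ls.hotspot_reduction(usages["suppressed"], usages["control"], h.name)
        rows.append(dict(hotspot=h.name, reduction_pct=red))
        print(f"{h.name}: reduction {red:+.1f}%")
    pd.DataFrame(rows).to_csv(
        args.outdir / "reduction.tsv", sep="\t", index=False, float_format="%.4g"
    )

    coco = next(r["reduction_pct"] for r in rows if r["hotspot"] == "Coco")
    print(
        f"central hotspot reduction recovered: {coco:.1f}% "
        f"(built-in {BUILT_IN_REDUCTION}%); at n = 164 vs 243 a single pair "
        "of populations carries several points of binomial sampling error"
    )


if __name__ == "__main__":
    main()
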