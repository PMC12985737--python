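#!/usr/bin/env python
"""Build crossover landscapes for both populations.

From the crossover calls of analysis/03: per-population normalized
distributions over inter-marker bins, the sliding-window cM/Mb track
(1-kb window, 100-bp step) for the control population, and the
suppressed-minus-control differential track. Writes bedGraphs under
results/landscape/ and reports the mass-conservation checks.
"""

import argparse
from pathlib import Path

from xomap import landscape as ls
from xomap import xo_mapper
from xomap.xo_mapper import CallStatus

INTERVAL_CM = 0.33  # control interval genetic length used for the cM/Mb track


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--xodir", type=Path, default=Path("results/xo"))
    parser.add_argument("--outdir", type=Path, default=Path("results/landscape"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    snps = xo_mapper.read_snp_map_tsv(args.simdir / "snps.tsv")
    dists = {}
    for label in ("control", "suppressed"):
        ok = [
            c
            for c in xo_mapper.read_crossover_bed(args.xodir / f"xo_{label}.bed")
            if c.status is CallStatus.OK
        ]
        dist = ls.build_distribution(ok, snps.positions)
        ls.write_bedgraph(
            dist, args.outdir / f"distribution_{label}.bedgraph", chrom=snps.chrom
        )
        dists[label] = dist
        print(
            f"{label}: normalized distribution over {len(dist.values)} "
            f"inter-marker bins (sum = {dist.values.sum():.12f})"
        )
        if label == "control":
            track = ls.moving_average_cm_per_mb(
                ok, INTERVAL_CM, (snps.start, snps.end), window=1000, step=100
            )
            ls.write_bedgraph(
                track, args.outdir / "cm_per_mb_control.bedgraph", chrom=snps.chrom
            )
            print(
                f"control cM/Mb track: peak {track.values.max():.1f} cM/Mb, "
                f"integral {ls.track_integral_cm(track):.6f} cM "
                f"(supplied {INTERVAL_CM} cM)"
            )

    diff = ls.differential_track(dists["suppressed"], dists["control"])
    ls.write_bedgraph(diff, args.outdir / "difference.bedgraph", chrom=snps.chrom)
    print(
        f"differential track written (sum = {diff.values.sum():.2e}); "
        f"most negative bin at {diff.starts[diff.values.argmin()]}-"
        f"{diff.ends[diff.values.argmin()]} bp"
    )


if __name__ == "__main__":
    main()
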