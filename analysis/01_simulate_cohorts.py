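#!/usr/bin/env python
"""Simulate the study's input data with known ground truth.

Generates, under results/sim/:
  * seed-count tables for five wild-type-like crosses (r = 0.0033, i.e.
    0.33 cM) and five lncRNA-activation-like crosses (r = 0.0052,
    0.52 cM), ~4000 scored seeds per cross;
  * the 101-marker Col/Ler map over the 40-kb interval (TSV + VCF);
  * allele-depth tables at 1500x mean depth, 0.2% read error, for a
    control population (n = 243) and a population whose central hotspot
    carries a built-in 47.2% share suppression (n = 164), with truth
    sidecars;
  * the hotspot annotation BED (spans snapped to marker positions).
"""

import argparse
from pathlib import Path

from xomap import synthetic, xo_mapper
from xomap.landscape import HotspotAnnotation, write_hotspot_bed
from xomap.pipeline import stage_seed

R_WILD_TYPE = 0.0033
R_ACTIVATED = 0.0052
N_SEEDS_PER_CROSS = 6000
N_CROSSES = 8
N_CONTROL = 243
N_SAMPLE = 164
MEAN_DEPTH = 1500
ERROR_RATE = 0.002


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = parser.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    # seed-count tables
    for label, r in (("wild_type", R_WILD_TYPE), ("activated", R_ACTIVATED)):
        path = out / f"seed_counts_{label}.tsv"
        with open(path, "w") as fh:
            fh.write("cross_id\tn_green\tn_red\tn_total\n")
            for i in range(N_CROSSES):
                c, _ = synthetic.simulate_seed_counts(
                    r,
                    N_SEEDS_PER_CROSS,
                    rng_seed=stage_seed(args.seed, f"{label}:{i}"),
                    cross_id=f"{label}_{i + 1}",
                )
                fh.write(f"{c.cross_id}\t{c.n_green}\t{c.n_red}\t{c.n_total}\n")
        print(f"wrote {path} ({N_CROSSES} crosses at {100 * r:.2f} cM)")

    # marker map and hotspot model
    snps = synthetic.make_snp_map(40_000, 101, rng_seed=0)
    xo_mapper.write_snp_map_tsv(snps, out / "snps.tsv")
    xo_mapper.write_snp_map_vcf(snps, out / "snps.vcf")
    model = synthetic.chp_like_model(snps)
    suppressed = synthetic.suppress_hotspot(model, "Coco", 47.2)
    write_hotspot_bed(
        [HotspotAnnotation(c.name, c.start, c.end) for c in model.components],
        out / "hotspots.bed",
        chrom=snps.chrom,
    )
    print(f"wrote marker map ({len(snps)} markers) and hotspot annotations")

    # recombinant populations observed through sequencing noise
    for label, mdl, n in (
        ("control", model, N_CONTROL),
        ("suppressed", suppressed, N_SAMPLE),
    ):
        truth = synthetic.simulate_recombinants(
            n, mdl, rng_seed=stage_seed(args.seed, f"recs:{label}")
        )
        truth.to_json(out / f"truth_{label}.json")
        tables = synthetic.simulate_allele_depths(
            truth,
            snps,
            mean_depth=MEAN_DEPTH,
            error_rate=ERROR_RATE,
            rng_seed=stage_seed(args.seed, f"depths:{label}"),
        )
        xo_mapper.write_depth_tables(tables, out / f"depths_{label}.tsv")
        print(f"wrote depths_{label}.tsv ({n} recombinants at {MEAN_DEPTH}x)")


if __name__ == "__main__":
    main()
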