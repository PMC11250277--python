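#!/usr/bin/env python
"""Generate the synthetic inputs used by the downstream analyses.

Writes, under the output directory:
- ``tile.tiff`` + JSON sidecar — a 30-cell multiplex tile (20 disjoint cells,
  5 touching pairs) with tumor/immune phenotype channels and ground truth;
- ``ms_distributions.tsv`` — homopolymer read-length distributions spanning
  wild-type, boundary and clearly mutant instability levels;
- ``vaf_deterministic.tsv`` / ``vaf_sampled.tsv`` — neutral-tail VAF spectra
  at a known mutation rate.
"""

import argparse
from pathlib import Path

from msidyn.io import write_distribution_tsv, write_image, write_vaf_tsv
from msidyn.synth import (
    ImageSpec,
    MsSimSpec,
    TailSimSpec,
    gen_cell_image,
    gen_ms_reads,
    gen_neutral_vafs,
)

MARKER_PANEL = {
    "tumor_msh6_pos": {"dapi": 1.0, "panCK": 0.9, "MSH6": 0.9},
    "tumor_msh6_neg": {"dapi": 1.0, "panCK": 0.9},
    "cytotoxic_t": {"dapi": 1.0, "CD8": 0.8},
    "helper_t": {"dapi": 1.0, "CD4": 0.8},
    "b_cell": {"dapi": 1.0, "CD20": 0.8},
}

MS_SCENARIOS = [
    ("wild_type", {8: 1.0}, 0.02),
    ("boundary", {8: 0.95, 7: 0.05}, 0.0),
    ("mutant", {8: 0.55, 7: 0.45}, 0.02),
]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/synth"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = ImageSpec(n_cells=30, overlap_pairs=5, channel_spec=MARKER_PANEL,
                     seed=args.seed)
    channels, truth = gen_cell_image(spec)
    write_image(channels, args.out / "tile.tiff", um_per_px=spec.um_per_px,
                truth=truth)
    print(f"tile: {len(truth.ellipses)} cells, "
          f"{len(channels)} channels -> {args.out / 'tile.tiff'}")

    dists = []
    for i, (name, fracs, stutter) in enumerate(MS_SCENARIOS):
        d = gen_ms_reads(MsSimSpec(ref_length=8, allele_fractions=fracs,
                                   depth=400, stutter_rate=stutter,
                                   start=1000 * (i + 1), seed=args.seed + i))
        dists.append(d)
        print(f"ms[{name}]: counts {d.tumor_counts}")
    write_distribution_tsv(dists, args.out / "ms_distributions.tsv")

    for mode in ("deterministic", "sampled"):
        sp = gen_neutral_vafs(TailSimSpec(mu_true=100.0, mode=mode,
                                          depth=1000, seed=args.seed))
        write_vaf_tsv(sp, args.out / f"vaf_{mode}.tsv")
        print(f"vaf[{mode}]: {len(sp)} variants")


if __name__ == "__main__":
    main()
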