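#!/usr/bin/env python
"""Call homopolymer frameshifts and repeat-allele diversity on the synthetic
distributions from 01, and tabulate NMD-escape categories for a panel of
premature-termination contexts.

The caller requires at least 5% of reads off the reference length with at
least 50 reads present; diversity is the Shannon index over read-length
proportions.
"""

import argparse
from pathlib import Path

import pandas as pd

from msidyn.homopolymers import (
    PtcContext,
    call_frameshift,
    classify_nmd_escape,
    shannon_site,
)
from msidyn.io import read_distribution_tsv

PTC_PANEL = [
    ("first exon, 120 nt into CDS", PtcContext(1, 7, 120)),
    ("first exon, 350 nt into CDS", PtcContext(1, 7, 350)),
    ("middle exon", PtcContext(4, 7, 2000)),
    ("penultimate, 30 bp from last junction", PtcContext(6, 7, 2000, 30)),
    ("penultimate, 90 bp from last junction", PtcContext(6, 7, 2000, 90)),
    ("last exon", PtcContext(7, 7, 2000)),
]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dists", type=Path, default=Path("results/synth/ms_distributions.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/ms"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dists = read_distribution_tsv(args.dists)
    rows = []
    for d in dists:
        call = call_frameshift(d)
        div = shannon_site(d)
        rows.append(dict(site_id=d.site.site_id, status=call.status,
                         unstable_fraction=round(call.unstable_fraction, 4),
                         total_reads=call.total_reads,
                         shannon=round(div.shannon, 4),
                         n_lengths=div.n_lengths))
    calls = pd.DataFrame(rows)
    calls.to_csv(args.out / "frameshift_calls.tsv", sep="\t", index=False)
    print(calls.to_string(index=False))

    nmd = pd.DataFrame(
        [dict(context=name, escape=esc, category=cat)
         for name, ctx in PTC_PANEL
         for esc, cat in [classify_nmd_escape(ctx)]]
    )
    nmd.to_csv(args.out / "nmd_classification.tsv", sep="\t", index=False)
    print()
    print(nmd.to_string(index=False))


if __name__ == "__main__":
    main()
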