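#!/usr/bin/env python
"""Rank QTL by deletion density (average distance between deletions).

QTL length divided by the deletion score gives bases per deletion; the 30
densest QTL are reported.  Writes results/qtl_density.tsv and
results/qtl_top30.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnvpop import (
    complete_genotype_filter,
    qtl_deletion_density,
    read_cnv_table,
    read_qtl_table,
    top_qtl,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--top-k", type=int, default=30)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    callset, _ = complete_genotype_filter(
        read_cnv_table(args.data / "calls.tsv", args.data / "samples.tsv")
    )
    qtls = read_qtl_table(args.data / "qtls.tsv")
    dens = qtl_deletion_density(callset, qtls)
    ranked = top_qtl(dens, k=min(args.top_k, len(dens)))
    rank_of = {d.qtl_id: i + 1 for i, d in enumerate(ranked)}

    frame = pd.DataFrame(
        {
            "qtl_id": [d.qtl_id for d in dens],
            "trait": [d.trait for d in dens],
            "length": [d.length for d in dens],
            "n_cnvs": [d.n_cnvs for d in dens],
            "score": [d.score for d in dens],
            "avg_distance": [d.avg_distance for d in dens],
            "rank": [rank_of.get(d.qtl_id) for d in dens],
        }
    )
    frame.to_csv(args.out / "qtl_density.tsv", sep="\t", index=False)
    frame[frame["rank"].notna()].sort_values("rank").to_csv(
        args.out / "qtl_top30.tsv", sep="\t", index=False
    )

    ad = frame["avg_distance"]
    print(f"{len(dens)} of {len(qtls)} QTL overlap >= 1 CNV")
    if len(dens):
        print(
            f"average distance between deletions: min {ad.min():.2f}, "
            f"median {ad.median():.2f}, max {ad.max():.2f} bp"
        )
        print(
            f"top {len(ranked)} QTL span scores "
            f"{min(d.score for d in ranked)}..{max(d.score for d in ranked)}"
        )


if __name__ == "__main__":
    main()
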