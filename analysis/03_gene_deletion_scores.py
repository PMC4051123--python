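#!/usr/bin/env python
"""Score genes by population deletion burden and flag the extreme tail.

Each CNV-overlapping gene gets the sum of per-CNV deletion-carrier counts;
a normal fitted to the genome-wide scores gives upper-tail probabilities and
genes with p < 0.01 are the candidate set.  Writes results/gene_scores.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnvpop import (
    complete_genotype_filter,
    read_cnv_table,
    read_gene_annotation,
    score_genes,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.01)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    callset, _ = complete_genotype_filter(
        read_cnv_table(args.data / "calls.tsv", args.data / "samples.tsv")
    )
    genes = read_gene_annotation(args.data / "genes.tsv")
    scored, significant = score_genes(callset, genes, alpha=args.alpha)
    sig = {s.gene_id for s in significant}
    frame = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scored],
            "symbol": [s.symbol or "" for s in scored],
            "l": [s.l for s in scored],
            "score": [s.score for s in scored],
            "p_value": [s.p_value for s in scored],
            "significant": [s.gene_id in sig for s in scored],
        }
    )
    frame.to_csv(args.out / "gene_scores.tsv", sep="\t", index=False)

    ss = frame["score"]
    print(
        f"{len(scored)} of {len(genes)} genes overlap a CNV; scores: "
        f"min {ss.min()}, median {ss.median():.0f}, mean {ss.mean():.2f}, "
        f"max {ss.max()}"
    )
    print(f"{len(significant)} genes in the upper tail at p < {args.alpha}")
    if significant:
        top = significant[0]
        print(f"top gene: {top.gene_id} (score {top.score} over {top.l} CNVs)")


if __name__ == "__main__":
    main()
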