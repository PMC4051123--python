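#!/usr/bin/env python
"""Generate the study-scale synthetic inputs every later analysis consumes.

Emulates the two-breed design: 22 + 10 animals, 6,811 deleted CNVs on a
cattle-scale autosome set, plus gene and QTL tracks with planted overlaps
(150 genes and 70 QTL over isolated CNVs, the rest in CNV-free gaps).
Writes the genotype table, sample sheet, truth table, chromosome sizes and
feature tracks under results/data/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cnvpop import SimConfig, simulate_callset, simulate_features
from cnvpop.io import write_cnv_table, write_sample_sheet
from cnvpop.simulate import isolated_cnv_ids


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    callset, truth = simulate_callset(cfg)
    write_cnv_table(callset, args.out / "calls.tsv")
    write_sample_sheet(callset.samples, args.out / "samples.tsv")
    truth.frame.to_csv(args.out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(cfg.genome).to_csv(
        args.out / "chrom_sizes.tsv", sep="\t", index=False, header=False
    )

    rng = np.random.default_rng([args.seed % (2**31), 7])
    candidates = isolated_cnv_ids(callset, min_gap=60_000)
    picks = rng.choice(len(candidates), size=220, replace=False)
    gene_plan = {f"aGene{k:03d}": [candidates[i]] for k, i in enumerate(picks[:150])}
    qtl_plan = {f"aQtl{k:03d}": [candidates[i]] for k, i in enumerate(picks[150:])}
    genes, qtls, _ = simulate_features(
        callset, n_genes=400, n_qtl=120, gene_plan=gene_plan, qtl_plan=qtl_plan,
        seed=args.seed, genome=dict(cfg.genome),
    )
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.symbol or "") for g in genes],
        columns=["gene_id", "chrom", "start", "end", "symbol"],
    ).to_csv(args.out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(q.qtl_id, q.trait, q.chrom, q.start, q.end) for q in qtls],
        columns=["qtl_id", "trait", "chrom", "start", "end"],
    ).to_csv(args.out / "qtls.tsv", sep="\t", index=False)

    labels = truth.frame["label"].value_counts().to_dict()
    print(f"wrote {callset.n_cnvs} CNVs x {callset.n_samples} samples to {args.out}")
    print(f"planted classes: {labels}")
    print(f"feature tracks: {len(genes)} genes, {len(qtls)} QTL "
          f"({len(gene_plan)} / {len(qtl_plan)} with planted CNV overlap)")


if __name__ == "__main__":
    main()
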