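#!/usr/bin/env python
"""Call-set summary: counts, lengths, shared/one-breed/monomorphic classes.

Reads results/data/, applies the complete-genotype filter, and writes
results/summary.tsv plus a per-chromosome count table.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from cnvpop import complete_genotype_filter, read_cnv_table, summarize
from cnvpop.io import read_chrom_sizes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    raw = read_cnv_table(args.data / "calls.tsv", args.data / "samples.tsv")
    callset, n_removed = complete_genotype_filter(raw)
    sizes = read_chrom_sizes(args.data / "chrom_sizes.tsv")
    stats = summarize(callset, chrom_sizes=sizes)

    sd = dataclasses.asdict(stats)
    per_chrom = sd.pop("per_chromosome")
    pd.DataFrame([sd]).to_csv(args.out / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(per_chrom.items()), columns=["chrom", "n_cnvs"]).to_csv(
        args.out / "summary_per_chromosome.tsv", sep="\t", index=False
    )

    print(f"{raw.n_cnvs} CNVs read; {n_removed} dropped by the completeness filter")
    print(
        f"{stats.n_cnvs} CNVs, mean length {stats.mean_length:.1f} bp, "
        f"{stats.total_bases / 1e6:.2f} Mbp ({stats.pct_genome:.2f}% of genome)"
    )
    print(
        f"shared between breeds: {stats.n_shared} "
        f"({100 * stats.n_shared / stats.n_cnvs:.1f}%); "
        f"one-breed: {stats.n_one_breed}; zero-carrier: {stats.n_zero_carrier}; "
        f"monomorphic: {stats.n_monomorphic}"
    )


if __name__ == "__main__":
    main()
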