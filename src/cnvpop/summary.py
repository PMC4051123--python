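"""Call-set-level summary statistics.

Accounting definitions: a CNV is *shared* when at least one deletion allele
is observed in every breed; a *one-breed* CNV has deleted alleles in exactly
one breed; a *zero-carrier* CNV has none anywhere.  These three classes
partition the call set.  A CNV is *monomorphic* when all samples carry the
identical genotype (for called deletions this coincides with all-1/1 unless
the CNV is all-0/0, which is also reported as zero-carrier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import CallSet, CnvConfigError, LengthMode, require_complete


@dataclass(frozen=True)
class SummaryStats:
    n_cnvs: int
    mean_length: float
    total_bases: int
    n_shared: int
    n_one_breed: int
    n_zero_carrier: int
    n_monomorphic: int
    per_chromosome: Mapping[str, int]
    pct_genome: float | None = None


def summarize(
    callset: CallSet,
    chrom_sizes: Mapping[str, int] | None = None,
    length_mode: LengthMode = "inclusive",
) -> SummaryStats:
    """Summary statistics of a filtered call set.

    ``pct_genome`` is only computed when explicit chromosome sizes are
    supplied (every call-set chromosome must be present); no genome length
    is assumed.
    """
    require_complete(callset)
    lengths = callset.lengths(length_mode)
    total = int(lengths.sum())
    n = callset.n_cnvs

    cols = callset.breed_columns()
    allele_counts = np.stack(
        [callset.genotypes[:, jj].sum(axis=1) for jj in cols.values()]
    )  # breeds x cnvs
    breeds_with_del = (allele_counts > 0).sum(axis=0)
    n_shared = int((breeds_with_del == len(cols)).sum())
    n_one_breed = int((breeds_with_del == 1).sum()) if len(cols) > 1 else 0
    n_zero = int((breeds_with_del == 0).sum())

    mono = (callset.genotypes == callset.genotypes[:, [0]]).all(axis=1)
    # restrict to CNVs where the invariant genotype carries the deletion;
    # all-0/0 rows are the zero-carrier class, not called monomorphic deletions
    n_monomorphic = int((mono & (callset.genotypes[:, 0] > 0)).sum())

    per_chrom = callset.records.groupby("chrom", sort=True).size().to_dict()

    pct = None
    if chrom_sizes is not None:
        missing = set(callset.records["chrom"]) - set(chrom_sizes)
        if missing:
            raise CnvConfigError(
                f"chromosomes absent from size table: {sorted(missing)}"
            )
        pct = 100.0 * total / sum(chrom_sizes.values())

    return SummaryStats(
        n_cnvs=n,
        mean_length=total / n if n else float("nan"),
        total_bases=total,
        n_shared=n_shared,
        n_one_breed=n_one_breed,
        n_zero_carrier=n_zero,
        n_monomorphic=n_monomorphic,
        per_chromosome=per_chrom,
        pct_genome=pct,
    )
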