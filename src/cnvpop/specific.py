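"""Breed-specific CNV detection.

A CNV is a *putative* breed-specific call when deleted alleles are observed
in exactly one of the two breeds; it is *confirmed* when its deletion
frequency in that breed exceeds a minimum (0.1 by default, strict
inequality), which suppresses calls supported by a single rare allele.
Frequency defaults to the allele frequency (alleles / 2n, the same
definition as the selection scan); a carrier-fraction mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import CallSet, GeneSpan, require_complete, require_two_breeds
from .intervals import overlap_cnvs_to_features

FreqMode = Literal["allele", "carrier"]


@dataclass(frozen=True)
class BreedSpecificCall:
    cnv_id: str
    breed: str  # the breed carrying the deletion
    freq: float  # deletion frequency in that breed
    status: Literal["putative", "confirmed"] = "putative"


def putative_breed_specific(
    callset: CallSet, freq_mode: FreqMode = "allele"
) -> list[BreedSpecificCall]:
    """CNVs whose deleted alleles are confined to one breed.

    Specificity is judged on observed genotypes: >= 1 deletion allele in one
    breed and exactly 0 in the other.  CNVs with no carriers anywhere are
    not calls.
    """
    require_complete(callset)
    b1, b2 = require_two_breeds(callset)
    cols = callset.breed_columns()
    out = []
    for b_here, b_there in ((b1, b2), (b2, b1)):
        g_here = callset.genotypes[:, cols[b_here]]
        g_there = callset.genotypes[:, cols[b_there]]
        ac_here = g_here.sum(axis=1)
        ac_there = g_there.sum(axis=1)
        mask = (ac_here > 0) & (ac_there == 0)
        n_here = len(cols[b_here])
        if freq_mode == "allele":
            freqs = ac_here / (2 * n_here)
        else:
            freqs = (g_here >= 1).sum(axis=1) / n_here
        for i in np.flatnonzero(mask):
            out.append(
                BreedSpecificCall(
                    cnv_id=callset.cnv_ids[i], breed=b_here, freq=float(freqs[i])
                )
            )
    # restore call-set order across the two breed passes
    order = {c: i for i, c in enumerate(callset.cnv_ids)}
    out.sort(key=lambda c: order[c.cnv_id])
    return out


def confirm_breed_specific(
    putative: Sequence[BreedSpecificCall], min_freq: float = 0.1
) -> list[BreedSpecificCall]:
    """Retain calls with deletion frequency strictly above ``min_freq``."""
    return [
        replace(c, status="confirmed") for c in putative if c.freq > min_freq
    ]


def assign_genes(
    calls: Sequence[BreedSpecificCall],
    callset: CallSet,
    genes: Sequence[GeneSpan],
    flank: int = 0,
) -> pd.DataFrame:
    """Join calls to genes overlapped within ``flank`` bases of the CNV.

    Every call is reported; the gene field is empty when no gene lies within
    reach.  The default flank of 0 means direct overlap.
    """
    wanted = {c.cnv_id for c in calls}
    sub = callset.subset(np.array([c in wanted for c in callset.cnv_ids]))
    gene_map = overlap_cnvs_to_features(sub, list(genes), flank=flank)
    return pd.DataFrame(
        {
            "cnv_id": [c.cnv_id for c in calls],
            "breed": [c.breed for c in calls],
            "freq": [c.freq for c in calls],
            "status": [c.status for c in calls],
            "genes": [",".join(gene_map.get(c.cnv_id, [])) for c in calls],
        }
    )
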