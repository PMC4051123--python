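"""QTL deletion density: average distance between deletions.

QTL spans are long and wildly variable in length, so the raw deletion score
(carrier-count sum, as for genes) mostly tracks QTL length.  The density
statistic divides it out: ``avg_distance = QTL length / deletion score``,
in bases per deletion — the smaller, the denser the deletion burden.  QTL
are ranked ascending by this distance and the top k (default 30) reported;
no distributional significance model is applied to QTL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import CallSet, CnvConfigError, LengthMode, QtlSpan
from .genes import ScoreMode, carrier_counts
from .intervals import overlap_features

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QtlDensity:
    qtl_id: str
    trait: str
    length: int
    n_cnvs: int
    score: int
    avg_distance: float  # bases per deletion
    cnv_ids: tuple[str, ...]


def qtl_deletion_density(
    callset: CallSet,
    qtls: Sequence[QtlSpan],
    mode: ScoreMode = "carrier",
    length_mode: LengthMode = "inclusive",
) -> list[QtlDensity]:
    """Density for every QTL overlapping >= 1 CNV (others are excluded)."""
    counts = carrier_counts(callset, mode)
    count_of = dict(zip(callset.cnv_ids, counts))
    hit = overlap_features(callset, list(qtls))
    out = []
    for q in qtls:
        cnvs = hit.get(q.qtl_id)
        if not cnvs:
            continue
        score = int(sum(count_of[c] for c in cnvs))
        if score == 0:
            # a zero-carrier call set row; density undefined, skip
            continue
        length = q.length if length_mode == "inclusive" else q.end - q.start
        out.append(
            QtlDensity(
                qtl_id=q.qtl_id,
                trait=q.trait,
                length=length,
                n_cnvs=len(cnvs),
                score=score,
                avg_distance=length / score,
                cnv_ids=tuple(cnvs),
            )
        )
    return out


def top_qtl(densities: Sequence[QtlDensity], k: int = 30) -> list[QtlDensity]:
    """The k densest QTL (smallest average distance between deletions).

    Ties break toward the larger deletion score, then lexicographic qtl_id.
    """
    if k <= 0:
        raise CnvConfigError(f"top_qtl needs k >= 1, got {k}")
    if k > len(densities):
        log.warning("top_qtl: k=%d exceeds %d QTL; returning all", k, len(densities))
    ranked = sorted(densities, key=lambda d: (d.avg_distance, -d.score, d.qtl_id))
    return ranked[:k]
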