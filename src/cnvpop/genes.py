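"""Gene deletion scores and their tail significance.

Every gene that overlaps at least one CNV receives a *deletion score*: the
sum, over its overlapping CNVs, of the number of individuals carrying at
least one deleted allele at that CNV (the carrier count, 0..N for N
samples).  A normal distribution is fitted to the genome-wide score vector
and each gene's significance is the upper-tail probability of its score
under that fit; genes below the significance cutoff (default 0.01, the top
~1% of the score distribution) are flagged as candidate domestication genes.

The carrier-count reading of the per-CNV "deletion number" is forced by its
0..N range over N diploid individuals; an allele-dosage mode (range 0..2N)
is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import MISSING, CallSet, CnvConfigError, GeneSpan, require_complete
from .intervals import overlap_features

ScoreMode = Literal["carrier", "allele"]


@dataclass(frozen=True)
class GeneScore:
    """Deletion burden of one gene."""

    gene_id: str
    symbol: str | None
    l: int  # number of overlapping CNVs
    score: int
    cnv_ids: tuple[str, ...]
    p_value: float | None = None


def deletion_carrier_count(genotype_row: np.ndarray) -> int:
    """Number of individuals with >= 1 deleted allele at one CNV.

    Raises if the row still contains missing genotypes — carrier counts are
    defined on the complete-genotype call set only.
    """
    row = np.asarray(genotype_row)
    if (row == MISSING).any():
        raise CnvConfigError(
            "missing genotypes in row; run complete_genotype_filter first"
        )
    return int((row >= 1).sum())


def carrier_counts(callset: CallSet, mode: ScoreMode = "carrier") -> np.ndarray:
    """Per-CNV deletion counts for the whole call set.

    ``carrier``: individuals with >= 1 deleted allele (range 0..N).
    ``allele``: summed allele dosage (range 0..2N).
    """
    require_complete(callset)
    if mode == "carrier":
        return (callset.genotypes >= 1).sum(axis=1)
    if mode == "allele":
        return callset.genotypes.sum(axis=1, dtype=np.int64)
    raise CnvConfigError(f"unknown score mode {mode!r}")


def gene_deletion_scores(
    callset: CallSet,
    genes: Sequence[GeneSpan],
    mode: ScoreMode = "carrier",
) -> list[GeneScore]:
    """Score every gene overlapped by >= 1 CNV; p-values left unset.

    A CNV spanning k genes contributes its carrier count to all k scores.
    Output follows the order of ``genes`` (restricted to scored ones).
    """
    counts = carrier_counts(callset, mode)
    count_of = dict(zip(callset.cnv_ids, counts))
    hit = overlap_features(callset, list(genes))
    out = []
    for g in genes:
        cnvs = hit.get(g.gene_id)
        if not cnvs:
            continue
        out.append(
            GeneScore(
                gene_id=g.gene_id,
                symbol=g.symbol,
                l=len(cnvs),
                score=int(sum(count_of[c] for c in cnvs)),
                cnv_ids=tuple(cnvs),
            )
        )
    return out


def normal_tail_pvalues(scores: Sequence[float]) -> np.ndarray:
    """Upper-tail probabilities under a normal fitted to the score vector.

    The fit uses the sample mean and the n-1 sample standard deviation;
    p_i = 1 - Phi((score_i - mu) / sigma).  Requires >= 3 scores with
    nonzero spread.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise CnvConfigError(f"need >= 3 scores to fit a normal, got {x.size}")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise CnvConfigError("zero variance in scores; tail p-values undefined")
    return stats.norm.sf((x - mu) / sd)


def rank_tail_pvalues(scores: Sequence[float]) -> np.ndarray:
    """Rank-based upper-tail probabilities: p_i = #(score >= score_i) / n."""
    x = np.asarray(scores, dtype=float)
    n = x.size
    order = np.argsort(-x, kind="stable")
    ranked = x[order]
    # count of values >= each value, honoring ties
    counts = np.searchsorted(-ranked, -ranked, side="right")
    p = np.empty(n)
    p[order] = counts / n
    return p


def attach_pvalues(
    scores: Sequence[GeneScore], method: Literal["normal", "rank"] = "normal"
) -> list[GeneScore]:
    fn = normal_tail_pvalues if method == "normal" else rank_tail_pvalues
    ps = fn([s.score for s in scores])
    return [replace(s, p_value=float(p)) for s, p in zip(scores, ps)]


def select_significant_genes(
    scores: Sequence[GeneScore], alpha: float = 0.01
) -> list[GeneScore]:
    """Genes with tail p < alpha, by descending score then gene_id."""
    sig = [s for s in scores if s.p_value is not None and s.p_value < alpha]
    return sorted(sig, key=lambda s: (-s.score, s.gene_id))


def score_genes(
    callset: CallSet,
    genes: Sequence[GeneSpan],
    alpha: float = 0.01,
    mode: ScoreMode = "carrier",
) -> tuple[list[GeneScore], list[GeneScore]]:
    """Full gene stage: scores with p-values, plus the significant subset."""
    scored = attach_pvalues(gene_deletion_scores(callset, genes, mode))
    return scored, select_significant_genes(scored, alpha)
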