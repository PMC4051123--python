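"""Per-CNV selection scan between two breeds using Nei's F statistic.

For each CNV the deletion allele frequency p_j is computed per breed
(j = 1, 2) from genotype dosages over 2·n_j alleles.  With subpopulation
weights c_j = n_j / N, Nei's heterozygosity decomposition gives

    H_obs = sum_j c_j * 2 p_j q_j          (within-breed expected het.)
    H_exp = 2 p̄ q̄,  p̄ = sum_j c_j p_j     (pooled expected het.)
    F     = (H_exp - H_obs) / H_exp

which algebraically equals Var_c(p) / (p̄ q̄) and therefore lies in [0, 1]
whenever H_exp > 0.  Monomorphic CNVs (H_exp = 0) have undefined F and are
excluded from the significance pool rather than assigned p = 1, so they
cannot distort the fitted null.

Significance follows the genome-wide empirical-p recipe used for gene
deletion scores: fit a normal to the defined F vector and take upper-tail
probabilities, then Benjamini–Hochberg FDR adjustment (significant at
q <= alpha, default 0.01).  A within-sample rank alternative is provided
for sensitivity; note that rank p-values are uniform by construction, so
their BH-adjusted values are identically 1 and the rank+BH route is a
deliberately conservative diagnostic, not a discovery method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import (
    CallSet,
    CnvConfigError,
    GeneSpan,
    require_complete,
    require_two_breeds,
)
from .genes import normal_tail_pvalues, rank_tail_pvalues
from .intervals import overlap_cnvs_to_features

WeightMode = Literal["sample", "equal"]
PMethod = Literal["normal", "rank"]


@dataclass(frozen=True)
class BreedFreq:
    """Deletion allele frequency of one breed at one CNV."""

    breed: str
    n: int  # samples in breed
    c: float  # relative subpopulation size
    p: float  # deletion allele frequency

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class FstResult:
    cnv_id: str
    freqs: tuple[BreedFreq, ...]
    h_obs: float
    h_exp: float
    fst: float  # NaN when H_exp == 0
    p_value: float | None = None
    q_value: float | None = None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.fst)

    def significant(self, alpha: float = 0.01) -> bool:
        return self.q_value is not None and self.q_value <= alpha


def breed_weights(ns: Sequence[int], mode: WeightMode = "sample") -> np.ndarray:
    """Subpopulation weights c_j: sample-count proportions or equal."""
    ns = np.asarray(ns, dtype=float)
    if (ns <= 0).any():
        raise CnvConfigError("every breed needs >= 1 sample")
    if mode == "sample":
        return ns / ns.sum()
    if mode == "equal":
        return np.full(len(ns), 1.0 / len(ns))
    raise CnvConfigError(f"unknown weight mode {mode!r}")


def breed_allele_frequencies(
    callset: CallSet, weights: WeightMode = "sample"
) -> list[tuple[BreedFreq, ...]]:
    """Per-CNV deletion allele frequencies for each breed.

    p_j = (het + 2 * hom_del) / (2 n_j), i.e. dosage sum over 2 n_j alleles.
    """
    require_complete(callset)
    cols = callset.breed_columns()
    breeds = list(cols)
    ns = [len(cols[b]) for b in breeds]
    cs = breed_weights(ns, weights)
    per_breed_p = [
        callset.genotypes[:, cols[b]].sum(axis=1) / (2 * n)
        for b, n in zip(breeds, ns)
    ]
    out = []
    for i in range(callset.n_cnvs):
        out.append(
            tuple(
                BreedFreq(breed=b, n=n, c=float(c), p=float(ps[i]))
                for b, n, c, ps in zip(breeds, ns, cs, per_breed_p)
            )
        )
    return out


def nei_fst(
    freqs: Sequence[BreedFreq], pbar_weighted: bool = True
) -> tuple[float, float, float]:
    """(H_obs, H_exp, F) from per-breed frequencies.

    ``pbar_weighted=False`` uses the unweighted mean frequency in H_exp
    (sensitivity option); the weighted default keeps F within [0, 1].
    """
    c = np.array([f.c for f in freqs])
    p = np.array([f.p for f in freqs])
    if not np.isclose(c.sum(), 1.0):
        raise CnvConfigError(f"breed weights sum to {c.sum()}, expected 1")
    h_obs = float(np.sum(c * 2 * p * (1 - p)))
    pbar = float(np.sum(c * p)) if pbar_weighted else float(p.mean())
    h_exp = 2 * pbar * (1 - pbar)
    if h_exp == 0:
        return h_obs, h_exp, float("nan")
    return h_obs, h_exp, (h_exp - h_obs) / h_exp


def fst_scan(
    callset: CallSet,
    weights: WeightMode = "sample",
    pbar_weighted: bool = True,
) -> list[FstResult]:
    """One FstResult per CNV; p/q values filled by :func:`fst_significance`."""
    require_two_breeds(callset)
    freqs = breed_allele_frequencies(callset, weights)
    out = []
    for cnv_id, fr in zip(callset.cnv_ids, freqs):
        h_obs, h_exp, f = nei_fst(fr, pbar_weighted)
        out.append(FstResult(cnv_id=cnv_id, freqs=fr, h_obs=h_obs, h_exp=h_exp, fst=f))
    return out


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fst_significance(
    results: Sequence[FstResult],
    method: PMethod = "normal",
    alpha: float = 0.01,
) -> list[FstResult]:
    """Attach empirical p and BH q to every defined-F result.

    ``normal``: fit mean/sd to the defined F values and take upper-tail
    normal probabilities (the same procedure as gene deletion scores).
    ``rank``: p_i = #(F >= F_i) / #defined.  Undefined-F results keep
    p = q = None and can never be significant.
    """
    defined = [r for r in results if r.defined]
    if len(defined) < 3:
        raise CnvConfigError(f"need >= 3 defined F values, got {len(defined)}")
    fvals = [r.fst for r in defined]
    if method == "normal":
        ps = normal_tail_pvalues(fvals)
    elif method == "rank":
        ps = rank_tail_pvalues(fvals)
    else:
        raise CnvConfigError(f"unknown significance method {method!r}")
    qs = benjamini_hochberg(ps)
    adjusted = iter(zip(ps, qs))
    out = []
    for r in results:
        if r.defined:
            p, q = next(adjusted)
            out.append(replace(r, p_value=float(p), q_value=float(q)))
        else:
            out.append(r)
    return out


def results_to_frame(callset: CallSet, results: Sequence[FstResult]) -> pd.DataFrame:
    """Flat per-CNV table of the scan (coordinates, frequencies, F, p, q)."""
    rec = callset.records.set_index("cnv_id")
    rows = []
    for r in results:
        row: dict = {
            "cnv_id": r.cnv_id,
            "chrom": rec.at[r.cnv_id, "chrom"],
            "start": rec.at[r.cnv_id, "start"],
            "end": rec.at[r.cnv_id, "end"],
        }
        for f in r.freqs:
            row[f"p_{f.breed}"] = f.p
        row.update(
            h_obs=r.h_obs, h_exp=r.h_exp, fst=r.fst, p_value=r.p_value,
            q_value=r.q_value,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_selected(
    results: Sequence[FstResult],
    callset: CallSet,
    genes: Sequence[GeneSpan] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Report the significant set with gene overlaps and per-breed tallies."""
    sig = [r for r in results if r.significant(alpha)]
    gene_map: Mapping[str, list[str]] = (
        overlap_cnvs_to_features(callset, list(genes)) if genes else {}
    )
    cols = callset.breed_columns()
    idx_of = {c: i for i, c in enumerate(callset.cnv_ids)}
    rec = callset.records.set_index("cnv_id")
    rows = []
    for r in sorted(sig, key=lambda r: -r.fst):
        i = idx_of[r.cnv_id]
        row: dict = {
            "cnv_id": r.cnv_id,
            "chrom": rec.at[r.cnv_id, "chrom"],
            "start": rec.at[r.cnv_id, "start"],
            "end": rec.at[r.cnv_id, "end"],
            "fst": r.fst,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "genes": ",".join(gene_map.get(r.cnv_id, [])),
        }
        for b, jj in cols.items():
            g = callset.genotypes[i, jj]
            row[f"{b}_het"] = int((g == 1).sum())
            row[f"{b}_hom_del"] = int((g == 2).sum())
            row[f"{b}_carriers"] = int((g >= 1).sum())
        rows.append(row)
    return pd.DataFrame(rows)
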