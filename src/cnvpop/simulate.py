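"""Synthetic two-breed deletion call sets with known ground truth.

The generator emulates the study design the pipeline targets: two breeds of
22 and 10 resequenced animals, several thousand deleted CNVs on a
cattle-scale autosome set, genotypes drawn per breed under Hardy–Weinberg
equilibrium from each CNV's true deletion allele frequency (dosage ~
Binomial(2, p), i.e. probabilities q², 2pq, p²).  Ground truth per CNV —
its class and true per-breed frequencies — is emitted alongside for
recovery tests.

CNV classes
-----------
background
    One frequency per CNV, shared by both breeds, drawn from a Beta
    distribution (default Beta(0.5, 2.0): a rare-skewed deletion
    site-frequency spectrum, mean 0.2, with essentially no mass at
    fixation).
differentiated
    A planted between-breed frequency gap of ``delta`` (selection-scan
    positives).
specific_b1 / specific_b2
    Deletion frequency 0 in the other breed; the present-breed frequency is
    drawn from U(0.02, 0.6) so the 0.1 confirmation threshold is exercised
    on both sides.
monomorphic
    Fixed double deletion in every sample.

One global seed drives a named pseudo-random stream per sub-task
(frequencies, intervals, genotypes, missingness, features), so e.g. adding
CNVs does not perturb feature placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    CallSet,
    CnvConfigError,
    GeneSpan,
    QtlSpan,
    Sample,
)

#: cattle-scale synthetic autosome set: 29 chromosomes of 85 Mb (~2.47 Gb)
DEFAULT_GENOME: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", 85_000_000) for i in range(1, 30)
)

_STREAMS = {"freqs": 0, "intervals": 1, "genotypes": 2, "missing": 3, "features": 4}

LABELS = ("background", "differentiated", "specific_b1", "specific_b2", "monomorphic")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic call set.

    Defaults reproduce the emulated design: 22 + 10 animals, ~6,800 deleted
    CNVs with mean length 2,732 bp, a shared-Beta background frequency
    spectrum, and small planted fractions of differentiated, breed-specific
    and monomorphic CNVs in roughly the proportions the real call set shows.
    """

    n_breed1: int = 22
    n_breed2: int = 10
    breed1: str = "Hanwoo"
    breed2: str = "Holstein"
    n_cnvs: int = 6811
    bg_beta_a: float = 0.5
    bg_beta_b: float = 2.0
    #: fix every background CNV's shared frequency instead of Beta sampling
    bg_fixed_p: float | None = None
    frac_differentiated: float = 0.015
    delta: float = 0.6
    frac_specific_b1: float = 0.115
    frac_specific_b2: float = 0.033
    frac_monomorphic: float = 0.0003
    missing_rate: float = 0.0
    mean_length: float = 2732.2
    length_sigma: float = 0.75
    min_length: int = 100
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.frac_differentiated,
            self.frac_specific_b1,
            self.frac_specific_b2,
            self.frac_monomorphic,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise CnvConfigError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise CnvConfigError(f"class fractions sum to {sum(fracs):.3f} > 1")
        if self.bg_fixed_p is not None and not 0 <= self.bg_fixed_p <= 1:
            raise CnvConfigError("bg_fixed_p must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise CnvConfigError("missing_rate must lie in [0, 1]")
        if not 0 <= self.delta <= 1:
            raise CnvConfigError("delta must lie in [0, 1]")
        if self.n_cnvs < 1 or self.n_breed1 < 1 or self.n_breed2 < 1:
            raise CnvConfigError("n_cnvs and breed sizes must be >= 1")

    def class_counts(self) -> dict[str, int]:
        n = self.n_cnvs
        counts = {
            "differentiated": int(round(self.frac_differentiated * n)),
            "specific_b1": int(round(self.frac_specific_b1 * n)),
            "specific_b2": int(round(self.frac_specific_b2 * n)),
            "monomorphic": int(round(self.frac_monomorphic * n)),
        }
        planted = sum(counts.values())
        if planted > n:
            raise CnvConfigError(
                f"planted classes need {planted} CNVs but n_cnvs={n}"
            )
        counts["background"] = n - planted
        return counts


@dataclass
class SimTruth:
    """Per-CNV ground truth: class label and true breed frequencies."""

    frame: pd.DataFrame  # columns: cnv_id, label, p1, p2
    breed1: str
    breed2: str

    def of_label(self, label: str) -> list[str]:
        return self.frame.loc[self.frame["label"] == label, "cnv_id"].tolist()


def _draw_frequencies(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels and true (p1, p2) for every CNV, in random genome-wide order."""
    counts = config.class_counts()
    labels = np.concatenate(
        [np.repeat(lab, counts[lab]) for lab in LABELS if counts[lab]]
    )
    rng.shuffle(labels)
    n = config.n_cnvs
    p1 = np.empty(n)
    p2 = np.empty(n)
    for i, lab in enumerate(labels):
        if lab == "background":
            if config.bg_fixed_p is not None:
                p = config.bg_fixed_p
            else:
                p = rng.beta(config.bg_beta_a, config.bg_beta_b)
            p1[i] = p2[i] = p
        elif lab == "differentiated":
            lo = rng.uniform(0, 1 - config.delta)
            hi = lo + config.delta
            if rng.random() < 0.5:
                p1[i], p2[i] = hi, lo
            else:
                p1[i], p2[i] = lo, hi
        elif lab == "specific_b1":
            p1[i], p2[i] = rng.uniform(0.02, 0.6), 0.0
        elif lab == "specific_b2":
            p1[i], p2[i] = 0.0, rng.uniform(0.02, 0.6)
        else:  # monomorphic
            p1[i] = p2[i] = 1.0
    return labels, p1, p2


def _place_intervals(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    chroms = [c for c, _ in config.genome]
    sizes = np.array([s for _, s in config.genome], dtype=float)
    lengths = rng.lognormal(
        mean=np.log(config.mean_length) - config.length_sigma**2 / 2,
        sigma=config.length_sigma,
        size=config.n_cnvs,
    )
    lengths = np.maximum(lengths.astype(np.int64), config.min_length)
    which = rng.choice(len(chroms), size=config.n_cnvs, p=sizes / sizes.sum())
    lengths = np.minimum(lengths, sizes[which].astype(np.int64))
    starts = (rng.random(config.n_cnvs) * (sizes[which] - lengths + 1)).astype(
        np.int64
    ) + 1
    return pd.DataFrame(
        {
            "chrom": [chroms[k] for k in which],
            "start": starts,
            "end": starts + lengths - 1,
            "_chrom_order": which,
        }
    )


def simulate_callset(config: SimConfig | None = None) -> tuple[CallSet, SimTruth]:
    """Generate a call set and its ground truth; bit-reproducible per seed."""
    config = config or SimConfig()
    config.validate()

    labels, p1, p2 = _draw_frequencies(config, _rng(config.seed, "freqs"))
    rec = _place_intervals(config, _rng(config.seed, "intervals"))
    rec["label"], rec["p1"], rec["p2"] = labels, p1, p2
    rec = rec.sort_values(["_chrom_order", "start"], kind="stable").reset_index(
        drop=True
    )
    rec["cnv_id"] = [f"simCNV{i + 1:05d}" for i in range(len(rec))]

    g_rng = _rng(config.seed, "genotypes")
    n1, n2 = config.n_breed1, config.n_breed2
    geno = np.empty((config.n_cnvs, n1 + n2), dtype=np.int8)
    geno[:, :n1] = g_rng.binomial(2, rec["p1"].to_numpy()[:, None], (config.n_cnvs, n1))
    geno[:, n1:] = g_rng.binomial(2, rec["p2"].to_numpy()[:, None], (config.n_cnvs, n2))

    if config.missing_rate > 0:
        m_rng = _rng(config.seed, "missing")
        mask = m_rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    samples = [Sample(f"{config.breed1}{i + 1:02d}", config.breed1) for i in range(n1)]
    samples += [Sample(f"{config.breed2}{i + 1:02d}", config.breed2) for i in range(n2)]

    callset = CallSet(rec[["cnv_id", "chrom", "start", "end"]], samples, geno)
    truth = SimTruth(
        frame=rec[["cnv_id", "label", "p1", "p2"]].reset_index(drop=True),
        breed1=config.breed1,
        breed2=config.breed2,
    )
    return callset, truth


# -- feature tracks ----------------------------------------------------


def _cnv_arrays(callset: CallSet) -> dict[str, list[tuple[int, int, str]]]:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for row in callset.records.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append((row.start, row.end, row.cnv_id))
    for v in by_chrom.values():
        v.sort()
    return by_chrom


def _free_gaps(
    callset: CallSet, genome: Mapping[str, int]
) -> list[tuple[str, int, int]]:
    """Maximal CNV-free intervals (1-based inclusive) on each chromosome."""
    by_chrom = _cnv_arrays(callset)
    gaps = []
    for chrom, size in genome.items():
        pos = 1
        for start, end, _ in by_chrom.get(chrom, []):
            if start > pos:
                gaps.append((chrom, pos, start - 1))
            pos = max(pos, end + 1)
        if pos <= size:
            gaps.append((chrom, pos, size))
    return gaps


def _planned_span(
    callset: CallSet,
    cnv_ids: Sequence[str],
    rng: np.random.Generator,
    genome: Mapping[str, int],
) -> tuple[str, int, int]:
    """An interval overlapping exactly the planned CNVs and no others."""
    rec = callset.records.set_index("cnv_id")
    missing = [c for c in cnv_ids if c not in rec.index]
    if missing:
        raise CnvConfigError(f"overlap plan references unknown CNVs: {missing}")
    sub = rec.loc[list(cnv_ids)]
    chroms = sub["chrom"].unique()
    if len(chroms) != 1:
        raise CnvConfigError(
            f"planned CNVs {list(cnv_ids)} span chromosomes {list(chroms)}; "
            "a single feature cannot overlap them all"
        )
    chrom = chroms[0]
    span_start, span_end = int(sub["start"].min()), int(sub["end"].max())
    others = [
        (s, e)
        for s, e, cid in _cnv_arrays(callset)[chrom]
        if cid not in set(cnv_ids)
    ]
    for s, e in others:
        if s <= span_end and span_start <= e:
            raise CnvConfigError(
                f"plan unsatisfiable: an unplanned CNV ({chrom}:{s}-{e}) lies "
                f"inside the span of {list(cnv_ids)}"
            )
    left_bound = max([e for s, e in others if e < span_start], default=0)
    right_bound = min([s for s, e in others if s > span_end], default=genome[chrom] + 1)
    left_margin = span_start - left_bound - 1
    right_margin = right_bound - span_end - 1
    start = span_start - int(rng.integers(0, left_margin + 1))
    end = span_end + int(rng.integers(0, right_margin + 1))
    return chrom, max(1, start), min(genome[chrom], end)


def _place_in_gap(
    gaps: list[tuple[str, int, int]],
    length: int,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    fitting = [(c, s, e) for c, s, e in gaps if e - s + 1 >= length]
    if not fitting:
        raise CnvConfigError(
            f"no CNV-free gap of {length} bp left on the configured genome"
        )
    weights = np.array([e - s + 1 for _, s, e in fitting], dtype=float)
    c, s, e = fitting[rng.choice(len(fitting), p=weights / weights.sum())]
    start = int(rng.integers(s, e - length + 2))
    return c, start, start + length - 1


_QTL_TRAITS = ("milk yield", "carcass weight", "marbling", "fertility", "stature")


def simulate_features(
    callset: CallSet,
    n_genes: int = 0,
    n_qtl: int = 0,
    gene_plan: Mapping[str, Sequence[str]] | None = None,
    qtl_plan: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    genome: Mapping[str, int] | None = None,
    gene_length: tuple[int, int] = (5_000, 50_000),
    qtl_length: tuple[int, int] = (100_000, 1_000_000),
) -> tuple[list[GeneSpan], list[QtlSpan], dict[str, dict[str, list[str]]]]:
    """Gene and QTL tracks with controlled CNV overlap.

    Features named in a plan overlap exactly their planned CNVs and no
    others (error if unsatisfiable); the remaining features (up to
    ``n_genes`` / ``n_qtl``) are placed in CNV-free gaps.  Returns the
    realized truth map ``{"genes": {...}, "qtls": {...}}`` including empty
    lists for non-overlapping features.
    """
    gene_plan = dict(gene_plan or {})
    qtl_plan = dict(qtl_plan or {})
    if genome is None:
        genome = {
            c: int(max(e, 85_000_000))
            for c, e in callset.records.groupby("chrom")["end"].max().items()
        }
        for c, _ in DEFAULT_GENOME:
            genome.setdefault(c, 85_000_000)
    rng = _rng(seed, "features")
    gaps = _free_gaps(callset, genome)

    genes: list[GeneSpan] = []
    qtls: list[QtlSpan] = []
    truth: dict[str, dict[str, list[str]]] = {"genes": {}, "qtls": {}}

    for fid, cnvs in gene_plan.items():
        chrom, start, end = _planned_span(callset, cnvs, rng, genome)
        genes.append(GeneSpan(fid, chrom, start, end))
        truth["genes"][fid] = list(cnvs)
    for fid, cnvs in qtl_plan.items():
        chrom, start, end = _planned_span(callset, cnvs, rng, genome)
        qtls.append(QtlSpan(fid, "planted", chrom, start, end))
        truth["qtls"][fid] = list(cnvs)

    for i in range(max(0, n_genes - len(gene_plan))):
        length = int(rng.integers(gene_length[0], gene_length[1] + 1))
        chrom, start, end = _place_in_gap(gaps, length, rng)
        fid = f"simGENE{i + 1:05d}"
        genes.append(GeneSpan(fid, chrom, start, end, symbol=f"SG{i + 1}"))
        truth["genes"][fid] = []
    for i in range(max(0, n_qtl - len(qtl_plan))):
        length = int(rng.integers(qtl_length[0], qtl_length[1] + 1))
        chrom, start, end = _place_in_gap(gaps, length, rng)
        fid = f"simQTL{i + 1:05d}"
        trait = _QTL_TRAITS[int(rng.integers(0, len(_QTL_TRAITS)))]
        qtls.append(QtlSpan(fid, trait, chrom, start, end))
        truth["qtls"][fid] = []

    genes.sort(key=lambda g: (g.chrom, g.start))
    qtls.sort(key=lambda q: (q.chrom, q.start))
    return genes, qtls, truth


def isolated_cnv_ids(callset: CallSet, min_gap: int = 100_000) -> list[str]:
    """CNVs at least ``min_gap`` bases from their nearest neighbour.

    Feature plans built from isolated CNVs are always satisfiable: the
    planted span (plus its random extension) cannot reach another CNV.
    """
    out = []
    for chrom, ivs in _cnv_arrays(callset).items():
        for k, (start, end, cid) in enumerate(ivs):
            left_ok = k == 0 or start - ivs[k - 1][1] > min_gap
            right_ok = k == len(ivs) - 1 or ivs[k + 1][0] - end > min_gap
            if left_ok and right_ok:
                out.append(cid)
    order = {c: i for i, c in enumerate(callset.cnv_ids)}
    out.sort(key=order.__getitem__)
    return out


def realized_frequencies(callset: CallSet) -> pd.DataFrame:
    """Observed per-breed deletion allele frequencies (for truth recovery)."""
    from .fst import breed_allele_frequencies

    freqs = breed_allele_frequencies(callset)
    rows = [
        {"cnv_id": cid, **{f"p_{f.breed}": f.p for f in fr}}
        for cid, fr in zip(callset.cnv_ids, freqs)
    ]
    return pd.DataFrame(rows)
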