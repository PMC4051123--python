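"""Core containers for two-breed deletion-CNV call sets.

A call set couples an ordered table of CNV intervals with a genotype matrix
(one row per CNV, one column per sample) and a sample -> breed map.  Deletion
genotypes are stored as allele dosages: 0 (no deleted allele, ``0/0``),
1 (single deletion, ``0/1``), 2 (double deletion, ``1/1``), or -1 for a
missing call (``./.``).  Coordinates are 1-based inclusive throughout the
package; BED I/O converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: genotype string <-> allele dosage
GT_TO_DOSAGE: Mapping[str, int] = {"0/0": 0, "0/1": 1, "1/1": 2, "./.": MISSING}
DOSAGE_TO_GT: Mapping[int, str] = {v: k for k, v in GT_TO_DOSAGE.items()}

RECORD_COLUMNS = ("cnv_id", "chrom", "start", "end")

LengthMode = Literal["inclusive", "span"]


class CnvFormatError(ValueError):
    """An input table violates the expected layout or encoding."""


class CnvConfigError(ValueError):
    """An operation was invoked with an invalid or infeasible configuration."""


@dataclass(frozen=True)
class Sample:
    """One sequenced individual with its breed label."""

    sample_id: str
    breed: str


@dataclass(frozen=True)
class GeneSpan:
    """A gene locus as a 1-based inclusive interval."""

    gene_id: str
    chrom: str
    start: int
    end: int
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CnvFormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QtlSpan:
    """A quantitative-trait locus as a 1-based inclusive interval."""

    qtl_id: str
    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CnvFormatError(
                f"QTL {self.qtl_id}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_lengths(
    start: np.ndarray, end: np.ndarray, mode: LengthMode = "inclusive"
) -> np.ndarray:
    """Interval lengths under the configured convention.

    ``inclusive`` counts both endpoints (end - start + 1, the 1-based
    inclusive convention); ``span`` is the raw coordinate difference.
    """
    if mode == "inclusive":
        return np.asarray(end) - np.asarray(start) + 1
    if mode == "span":
        return np.asarray(end) - np.asarray(start)
    raise CnvConfigError(f"unknown length mode {mode!r}")


class CallSet:
    """CNV intervals plus an N-sample deletion genotype matrix.

    Parameters
    ----------
    records
        DataFrame with columns ``cnv_id, chrom, start, end`` (1-based
        inclusive), one row per CNV, in call order.
    samples
        Ordered samples; one per genotype column.
    genotypes
        Integer dosage matrix of shape ``(n_cnvs, n_samples)`` with values
        in {0, 1, 2, -1}.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        samples: Sequence[Sample],
        genotypes: np.ndarray,
    ) -> None:
        records = records.reset_index(drop=True)
        missing_cols = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing_cols:
            raise CnvFormatError(f"records table lacks columns: {missing_cols}")
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 2 or genotypes.shape != (len(records), len(samples)):
            raise CnvFormatError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(records)} CNVs x {len(samples)} samples"
            )
        bad = ~np.isin(genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CnvFormatError(
                f"invalid dosage {genotypes[i, j]} at CNV row {i}, sample column {j}"
            )
        dup = records["cnv_id"].duplicated()
        if dup.any():
            raise CnvFormatError(
                f"duplicate cnv_id {records.loc[dup.idxmax(), 'cnv_id']!r}"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise CnvFormatError("duplicate sample_id in sample list")
        if (records["end"] < records["start"]).any():
            row = records[records["end"] < records["start"]].iloc[0]
            raise CnvFormatError(f"CNV {row['cnv_id']}: end < start")
        self.records = records[list(RECORD_COLUMNS)].astype(
            {"cnv_id": str, "chrom": str, "start": np.int64, "end": np.int64}
        )
        self.samples = list(samples)
        self.genotypes = genotypes

    # -- basic shape ---------------------------------------------------
    @property
    def n_cnvs(self) -> int:
        return len(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def cnv_ids(self) -> list[str]:
        return self.records["cnv_id"].tolist()

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def breeds(self) -> list[str]:
        """Distinct breed labels in first-seen sample order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.breed, None)
        return list(seen)

    def breed_columns(self) -> dict[str, np.ndarray]:
        """Column indices of the genotype matrix for each breed."""
        return {
            b: np.array(
                [i for i, s in enumerate(self.samples) if s.breed == b], dtype=int
            )
            for b in self.breeds
        }

    def lengths(self, mode: LengthMode = "inclusive") -> np.ndarray:
        return interval_lengths(
            self.records["start"].to_numpy(), self.records["end"].to_numpy(), mode
        )

    @property
    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    # -- derived views -------------------------------------------------
    def subset(self, mask: np.ndarray | Sequence[bool]) -> "CallSet":
        """New CallSet keeping rows where ``mask`` is True, order preserved."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cnvs,):
            raise CnvConfigError(
                f"mask length {mask.shape} does not match {self.n_cnvs} CNVs"
            )
        return CallSet(
            self.records.loc[mask].reset_index(drop=True),
            self.samples,
            self.genotypes[mask],
        )

    def genotype_frame(self) -> pd.DataFrame:
        """Records plus genotype strings, the on-disk table layout."""
        gt = pd.DataFrame(
            np.vectorize(DOSAGE_TO_GT.get)(self.genotypes),
            columns=self.sample_ids,
        )
        return pd.concat([self.records.reset_index(drop=True), gt], axis=1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CallSet({self.n_cnvs} CNVs, {self.n_samples} samples, "
            f"breeds={self.breeds})"
        )


def concat_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Concatenate two call sets over the same ordered sample list."""
    if a.samples != b.samples:
        raise CnvConfigError("call sets have different sample lists")
    return CallSet(
        pd.concat([a.records, b.records], ignore_index=True),
        a.samples,
        np.vstack([a.genotypes, b.genotypes]),
    )


def require_two_breeds(callset: CallSet) -> tuple[str, str]:
    """Return the two breed labels or raise for any other breed count."""
    breeds = callset.breeds
    if len(breeds) != 2:
        raise CnvConfigError(
            f"stage requires exactly 2 breeds, found {len(breeds)}: {breeds}"
        )
    return breeds[0], breeds[1]


def require_complete(callset: CallSet) -> None:
    if callset.has_missing:
        raise CnvConfigError(
            "call set contains missing genotypes; run complete_genotype_filter first"
        )
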