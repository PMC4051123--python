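"""Readers and writers for every tabular and track format the pipeline touches.

All tables are delimited text with a header; the delimiter is auto-detected
between tab and comma.  Genotype tables follow the layout
``cnv_id, chrom, start, end, <one column per sample>`` with genotype strings
``0/0``, ``0/1``, ``1/1`` or ``./.``.  Gene/QTL annotations are TSVs in
1-based inclusive coordinates; BED files are 0-based half-open and converted
on the way in and out.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    GT_TO_DOSAGE,
    MISSING,
    CallSet,
    CnvFormatError,
    GeneSpan,
    QtlSpan,
    Sample,
)

log = logging.getLogger(__name__)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    # single-column or whitespace table; tab is the documented default
    return "\t"


def read_sample_sheet(path: str | Path) -> list[Sample]:
    """Read a two-column sample sheet (sample_id, breed)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    try:
        i_id, i_breed = cols.index("sample_id"), cols.index("breed")
    except ValueError as exc:
        raise CnvFormatError(
            f"{path}: sample sheet needs 'sample_id' and 'breed' columns, "
            f"found {list(df.columns)}"
        ) from exc
    samples = [
        Sample(str(r.iloc[i_id]), str(r.iloc[i_breed])) for _, r in df.iterrows()
    ]
    if len({s.sample_id for s in samples}) != len(samples):
        raise CnvFormatError(f"{path}: duplicate sample_id in sample sheet")
    return samples


def read_cnv_table(
    path: str | Path, sample_sheet: str | Path | Sequence[Sample]
) -> CallSet:
    """Parse a CNV genotype table into a CallSet.

    The first four columns are CNV id, chromosome, start, end (1-based
    inclusive); every remaining column is a sample and must be assigned a
    breed by the sample sheet.  Genotype strings are parsed strictly: only
    ``0/0``, ``0/1``, ``1/1`` and ``./.`` are accepted.
    """
    path = Path(path)
    if isinstance(sample_sheet, (str, Path)):
        samples = read_sample_sheet(sample_sheet)
    else:
        samples = list(sample_sheet)
    breed_of = {s.sample_id: s.breed for s in samples}

    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if df.shape[1] < 5:
        raise CnvFormatError(
            f"{path}: expected >= 5 columns (cnv_id, chrom, start, end, "
            f"samples...), found {df.shape[1]}"
        )
    id_col, chrom_col, start_col, end_col = df.columns[:4]
    sample_cols = list(df.columns[4:])
    unassigned = [c for c in sample_cols if c not in breed_of]
    if unassigned:
        raise CnvFormatError(
            f"{path}: genotype columns without a breed assignment: {unassigned}"
        )

    records = pd.DataFrame(
        {
            "cnv_id": df[id_col].astype(str),
            "chrom": df[chrom_col].astype(str),
        }
    )
    for name, col in (("start", start_col), ("end", end_col)):
        try:
            records[name] = df[col].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise CnvFormatError(f"{path}: non-integer {name} in column {col!r}") from exc

    geno = np.empty((len(df), len(sample_cols)), dtype=np.int8)
    for j, col in enumerate(sample_cols):
        mapped = df[col].str.strip().map(GT_TO_DOSAGE)
        if mapped.isna().any():
            i = int(mapped.isna().idxmax())
            raise CnvFormatError(
                f"{path}: unparseable genotype {df[col].iloc[i]!r} for CNV "
                f"{records['cnv_id'].iloc[i]!r}, sample {col!r}"
            )
        geno[:, j] = mapped.to_numpy(dtype=np.int8)

    ordered = [Sample(c, breed_of[c]) for c in sample_cols]
    return CallSet(records, ordered, geno)


def write_cnv_table(callset: CallSet, path: str | Path) -> None:
    """Write a CallSet back to the genotype-table layout (round-trips)."""
    callset.genotype_frame().to_csv(path, sep="\t", index=False)


def write_sample_sheet(samples: Sequence[Sample], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples], "breed": [s.breed for s in samples]}
    ).to_csv(path, sep="\t", index=False)


class FilterResult(NamedTuple):
    callset: CallSet
    n_removed: int


def complete_genotype_filter(callset: CallSet) -> FilterResult:
    """Drop every CNV with at least one missing genotype.

    Mirrors the call-set completeness rule: a CNV is kept only when all
    individuals received a called genotype.  Order is preserved and the
    operation is idempotent.
    """
    keep = ~(callset.genotypes == MISSING).any(axis=1)
    n_removed = int((~keep).sum())
    log.info(
        "complete_genotype_filter: retained %d of %d CNVs (%d removed)",
        int(keep.sum()),
        callset.n_cnvs,
        n_removed,
    )
    return FilterResult(callset.subset(keep), n_removed)


# -- annotations -------------------------------------------------------


def _read_bed_spans(path: Path) -> list[tuple[str, str, int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise CnvFormatError(f"{path}:{lineno}: BED line with < 3 fields")
            chrom = parts[0]
            try:
                start0, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise CnvFormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            # BED is 0-based half-open; internal convention is 1-based inclusive
            rows.append((name, chrom, start0 + 1, end))
    return rows


def read_gene_annotation(path: str | Path) -> list[GeneSpan]:
    """Read a gene annotation (TSV or BED) into sorted GeneSpans.

    TSV columns: gene_id, chrom, start, end, optional symbol (1-based
    inclusive).  A ``.bed`` extension switches to BED parsing with the usual
    0-based half-open to 1-based inclusive conversion.  Duplicated gene ids
    are rejected.
    """
    path = Path(path)
    genes: list[GeneSpan] = []
    if path.suffix.lower() == ".bed":
        for name, chrom, start, end in _read_bed_spans(path):
            genes.append(GeneSpan(name, chrom, start, end))
    else:
        df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
        if df.shape[1] < 4:
            raise CnvFormatError(
                f"{path}: gene table needs >= 4 columns (gene_id, chrom, start, end)"
            )
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            try:
                start, end = int(row[2]), int(row[3])
            except (TypeError, ValueError) as exc:
                raise CnvFormatError(f"{path}: line {lineno}: bad coordinates") from exc
            symbol = str(row[4]) if len(row) > 4 and pd.notna(row[4]) else None
            genes.append(GeneSpan(str(row[0]), str(row[1]), start, end, symbol))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise CnvFormatError(f"{path}: duplicate gene_id {dup!r}")
    genes.sort(key=lambda g: (g.chrom, g.start))
    if not genes:
        log.warning("%s: no gene records read", path)
    return genes


def read_qtl_table(path: str | Path) -> list[QtlSpan]:
    """Read a QTL table (qtl_id, trait, chrom, start, end; 1-based inclusive)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if df.shape[1] < 5:
        raise CnvFormatError(
            f"{path}: QTL table needs >= 5 columns (qtl_id, trait, chrom, start, end)"
        )
    qtls: list[QtlSpan] = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        try:
            start, end = int(row[3]), int(row[4])
        except (TypeError, ValueError) as exc:
            raise CnvFormatError(f"{path}: line {lineno}: bad coordinates") from exc
        qtls.append(QtlSpan(str(row[0]), str(row[1]), str(row[2]), start, end))
    if not qtls:
        log.warning("%s: no QTL records read", path)
    return qtls


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-sizes table (chrom, length)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, header=None)
    if (df.iloc[0, 0] or "").lower() in {"chrom", "chromosome"}:
        df = df.iloc[1:]
    return {str(r[0]): int(r[1]) for r in df.itertuples(index=False)}


def write_bed(
    callset: CallSet,
    path: str | Path,
    labels: Mapping[str, str] | None = None,
) -> None:
    """Export the call set as a BED4 track (0-based half-open).

    The name column is the cnv_id, or ``labels[cnv_id]`` where provided —
    used for the deletion-map track with breed-specific colouring labels.
    """
    labels = labels or {}
    with open(path, "w") as fh:
        for row in callset.records.itertuples(index=False):
            name = labels.get(row.cnv_id, row.cnv_id)
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{name}\n")


def write_feature_bed(
    features: Iterable[GeneSpan | QtlSpan], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for f in features:
            name = f.gene_id if isinstance(f, GeneSpan) else f.qtl_id
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{name}\n")
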