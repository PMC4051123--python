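"""Shared genomic-interval overlap machinery (1-based inclusive intervals).

Overlap queries are served by per-chromosome interval trees; the brute-force
all-pairs definition (same chromosome and ``a.start <= b.end and
b.start <= a.end``) is what the trees must agree with and is kept in the
test suite as the oracle.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .core import CallSet, GeneSpan, QtlSpan

Feature = GeneSpan | QtlSpan


def feature_id(feature: Feature) -> str:
    return feature.gene_id if isinstance(feature, GeneSpan) else feature.qtl_id


def build_cnv_trees(callset: CallSet) -> dict[str, IntervalTree]:
    """One interval tree per chromosome; payload is the CNV row index."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, row in enumerate(callset.records.itertuples(index=False)):
        # half-open tree coordinates: [start, end + 1) covers 1-based inclusive
        trees[row.chrom].addi(row.start, row.end + 1, i)
    return trees


def overlap_features(
    callset: CallSet, features: Sequence[Feature], flank: int = 0
) -> dict[str, list[str]]:
    """Map each feature to the CNVs it intersects in >= 1 base.

    Features overlapping no CNV are omitted.  ``flank`` widens every CNV by
    that many bases on each side before testing (used by the breed-specific
    "nearby gene" rule).  CNV lists follow call-set order.
    """
    trees = build_cnv_trees(callset)
    ids = callset.cnv_ids
    out: dict[str, list[str]] = {}
    for feat in features:
        tree = trees.get(feat.chrom)
        if tree is None:
            continue
        hits = tree.overlap(feat.start - flank, feat.end + 1 + flank)
        if hits:
            rows = sorted(iv.data for iv in hits)
            out[feature_id(feat)] = [ids[i] for i in rows]
    return out


def overlap_cnvs_to_features(
    callset: CallSet, features: Sequence[Feature], flank: int = 0
) -> dict[str, list[str]]:
    """Inverse map: cnv_id -> overlapping feature ids (CNV widened by flank)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    order: dict[str, int] = {}
    for k, feat in enumerate(features):
        trees[feat.chrom].addi(feat.start, feat.end + 1, feature_id(feat))
        order[feature_id(feat)] = k
    out: dict[str, list[str]] = {}
    for row in callset.records.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = tree.overlap(row.start - flank, row.end + 1 + flank)
        if hits:
            out[row.cnv_id] = sorted((iv.data for iv in hits), key=order.__getitem__)
    return out
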