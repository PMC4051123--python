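import numpy as np
import pandas as pd
import pytest

from cnvpop import CallSet, Sample


def build_callset(rows, samples):
    """Build a CallSet from (cnv_id, chrom, start, end, dosages) tuples."""
    records = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in rows],
        columns=["cnv_id", "chrom", "start", "end"],
    )
    geno = np.array([r[4] for r in rows], dtype=np.int8)
    return CallSet(records, samples, geno)


def two_breed_samples(n1=4, n2=3, b1="Hanwoo", b2="Holstein"):
    return [Sample(f"{b1}{i}", b1) for i in range(n1)] + [
        Sample(f"{b2}{i}", b2) for i in range(n2)
    ]


def brute_force_overlaps(callset, features):
    """All-pairs interval-intersection scan: the overlap oracle."""
    out = {}
    for feat in features:
        fid = feat.gene_id if hasattr(feat, "gene_id") else feat.qtl_id
        hits = [
            row.cnv_id
            for row in callset.records.itertuples(index=False)
            if row.chrom == feat.chrom
            and row.start <= feat.end
            and feat.start <= row.end
        ]
        if hits:
            out[fid] = hits
    return out


def brute_force_bh(pvalues):
    """Independent BH step-up: q_(k) = cummin_{j>=k} (m/j) p_(j), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@pytest.fixture
def galk2_callset():
    """The two-CNV call set from the worked selection-scan example:
    one CNV with 13 hom + 9 het deletions in 22 Hanwoo and 3 het in 10
    Holstein, plus a fixed-difference CNV."""
    samples = two_breed_samples(22, 10)
    galk2 = [2] * 13 + [1] * 9 + [1] * 3 + [0] * 7
    fixed = [2] * 22 + [0] * 10
    return build_callset(
        [
            ("cnvGALK2", "chr10", 1000, 2000, galk2),
            ("cnvFIXED", "chr10", 5000, 6000, fixed),
        ],
        samples,
    )
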