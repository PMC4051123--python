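"""End-to-end pipeline: filter -> summarize -> gene scores -> QTL density ->
selection scan -> breed-specific calls, with a run manifest.

The config (YAML or JSON) names the input files and thresholds::

    cnv_table: calls.tsv          # required
    sample_sheet: samples.tsv     # required
    genes: genes.tsv              # optional; gene stage skipped if absent
    qtls: qtls.tsv                # optional; QTL stage skipped if absent
    chrom_sizes: sizes.tsv        # optional; enables percent-of-genome
    alpha: 0.01
    fst_method: normal            # or rank
    min_freq: 0.1
    flank: 0
    top_k: 30
    length_mode: inclusive        # or span
    out_dir: results/run

Outputs are TSVs with headers plus BED tracks, and ``manifest.json`` with
input checksums, parameters and record counts; identical inputs and config
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .core import CnvConfigError
from .fst import annotate_selected, fst_scan, fst_significance, results_to_frame
from .genes import score_genes
from .io import (
    complete_genotype_filter,
    read_chrom_sizes,
    read_cnv_table,
    read_gene_annotation,
    read_qtl_table,
    write_bed,
    write_cnv_table,
)
from .qtl import qtl_deletion_density, top_qtl
from .specific import assign_genes, confirm_breed_specific, putative_breed_specific
from .summary import summarize

log = logging.getLogger(__name__)

_DEFAULTS: dict[str, Any] = {
    "alpha": 0.01,
    "fst_method": "normal",
    "min_freq": 0.1,
    "flank": 0,
    "top_k": 30,
    "length_mode": "inclusive",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise CnvConfigError(f"{path}: config must be a mapping")
    merged = {**_DEFAULTS, **cfg}
    for key in ("cnv_table", "sample_sheet"):
        if key not in merged:
            raise CnvConfigError(f"config lacks required key {key!r}")
    return merged


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None) -> Path:
    """Execute every stage and write its outputs; returns the output dir."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = {**_DEFAULTS, **dict(config)}
    out = Path(out_dir or cfg.get("out_dir", "cnvpop_out"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "version": __version__,
        "parameters": {k: cfg[k] for k in _DEFAULTS},
        "inputs": {},
        "stages": {},
    }
    inputs = {
        k: Path(cfg[k])
        for k in ("cnv_table", "sample_sheet", "genes", "qtls", "chrom_sizes")
        if cfg.get(k)
    }
    for k, p in inputs.items():
        manifest["inputs"][k] = {"path": str(p), "sha256": _sha256(p)}

    def stage(name: str, **info: Any) -> None:
        manifest["stages"][name] = info
        log.info("stage %s: %s", name, info)

    # filter
    raw = read_cnv_table(inputs["cnv_table"], inputs["sample_sheet"])
    callset, n_removed = complete_genotype_filter(raw)
    write_cnv_table(callset, out / "filtered_calls.tsv")
    write_bed(callset, out / "cnvs.bed")
    stage("filter", n_input=raw.n_cnvs, n_retained=callset.n_cnvs, n_removed=n_removed)

    # summarize
    sizes = read_chrom_sizes(inputs["chrom_sizes"]) if "chrom_sizes" in inputs else None
    stats = summarize(callset, sizes, cfg["length_mode"])
    sd = dataclasses.asdict(stats)
    per_chrom = sd.pop("per_chromosome")
    pd.DataFrame([sd]).to_csv(out / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(per_chrom.items()), columns=["chrom", "n_cnvs"]).to_csv(
        out / "summary_per_chromosome.tsv", sep="\t", index=False
    )
    stage("summarize", n_cnvs=stats.n_cnvs, total_bases=stats.total_bases)

    genes = read_gene_annotation(inputs["genes"]) if "genes" in inputs else None

    # gene scores
    if genes is not None:
        scored, significant = score_genes(callset, genes, alpha=cfg["alpha"])
        sig_ids = {s.gene_id for s in significant}
        pd.DataFrame(
            {
                "gene_id": [s.gene_id for s in scored],
                "symbol": [s.symbol or "" for s in scored],
                "l": [s.l for s in scored],
                "score": [s.score for s in scored],
                "p_value": [s.p_value for s in scored],
                "significant": [s.gene_id in sig_ids for s in scored],
            }
        ).to_csv(out / "gene_scores.tsv", sep="\t", index=False)
        stage("gene_scores", n_scored=len(scored), n_significant=len(significant))
    else:
        stage("gene_scores", skipped="no gene annotation configured")

    # QTL density
    if "qtls" in inputs:
        qtls = read_qtl_table(inputs["qtls"])
        dens = qtl_deletion_density(callset, qtls, length_mode=cfg["length_mode"])
        ranked = top_qtl(dens, k=min(cfg["top_k"], len(dens))) if dens else []
        frame = pd.DataFrame(
            {
                "qtl_id": [d.qtl_id for d in dens],
                "trait": [d.trait for d in dens],
                "length": [d.length for d in dens],
                "n_cnvs": [d.n_cnvs for d in dens],
                "score": [d.score for d in dens],
                "avg_distance": [d.avg_distance for d in dens],
            }
        )
        frame.to_csv(out / "qtl_density.tsv", sep="\t", index=False)
        frame[frame["qtl_id"].isin([d.qtl_id for d in ranked])].assign(
            rank=lambda f: f["avg_distance"].rank(method="first").astype(int)
        ).sort_values("rank").to_csv(out / "qtl_top.tsv", sep="\t", index=False)
        stage("qtl_density", n_overlapping=len(dens), top_k=len(ranked))
    else:
        stage("qtl_density", skipped="no QTL table configured")

    # selection scan
    results = fst_significance(
        fst_scan(callset), method=cfg["fst_method"], alpha=cfg["alpha"]
    )
    results_to_frame(callset, results).to_csv(out / "fst.tsv", sep="\t", index=False)
    selected = annotate_selected(results, callset, genes, alpha=cfg["alpha"])
    selected.to_csv(out / "fst_significant.tsv", sep="\t", index=False)
    stage("fst", n_defined=sum(r.defined for r in results), n_significant=len(selected))

    # breed-specific calls
    putative = putative_breed_specific(callset)
    confirmed = confirm_breed_specific(putative, min_freq=cfg["min_freq"])
    table = assign_genes(confirmed, callset, genes or [], flank=cfg["flank"])
    table.to_csv(out / "breed_specific.tsv", sep="\t", index=False)
    labels = {c.cnv_id: f"{c.cnv_id}|{c.breed}" for c in confirmed}
    keep = [cid in labels for cid in callset.cnv_ids]
    if any(keep):
        import numpy as np

        write_bed(callset.subset(np.array(keep)), out / "breed_specific.bed", labels)
    stage(
        "breed_specific",
        n_putative=len(putative),
        n_confirmed=len(confirmed),
        per_breed={
            b: sum(c.breed == b for c in confirmed)
            for b in callset.breeds
        },
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
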