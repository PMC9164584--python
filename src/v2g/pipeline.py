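"""End-to-end convenience runs over an in-memory or on-disk dataset.

Thin composition of the stage modules: proxy expansion, per-cell-type
interaction merging, accessibility intersection, gene implication, the
implication matrix, heritability enrichment, the contacted-gene expression
comparison, and motif-disruption scanning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import (
    capture_design,
    expression_contact,
    heritability_ldsc,
    ld_proxies,
    motif_disruption,
    v2g_mapping,
)
from .synthetic_data import SimDataset


@dataclass
class V2GResult:
    records: list[v2g_mapping.V2GRecord]
    matrix: pd.DataFrame
    merged_by_cell: dict[str, list]


def run_v2g(dataset: SimDataset, r2_min: float = 0.8,
            min_score: float = 5.0) -> V2GResult:
    """Full variant-to-gene mapping over every cell type of a dataset."""
    chrom_len = dataset.config.chrom_length
    windows = [
        v2g_mapping.promoter_window(g, chrom_length=chrom_len)
        for g in dataset.genes
    ]
    proxy_sets = [
        ld_proxies.find_proxies(dataset.panel, s, r2_min=r2_min)
        for s in dataset.sentinels
    ]
    sentinel_of = {
        snp.snp_id: ps.sentinel.snp_id for ps in proxy_sets for snp, _ in ps
    }
    records: list[v2g_mapping.V2GRecord] = []
    merged_by_cell = {}
    for cell, ocrs in dataset.ocrs_by_cell.items():
        calls_1, calls_4 = dataset.ibeds_by_cell[cell]
        merged = capture_design.merge_interactions(calls_1, calls_4,
                                                   min_score=min_score)
        merged_by_cell[cell] = merged
        for ps in proxy_sets:
            accessible = v2g_mapping.accessible_proxies(ps, ocrs)
            records.extend(
                v2g_mapping.implicate(
                    accessible, windows, merged, cell, ocrs, sentinel_of
                )
            )
    records = sorted(set(records), key=lambda r: (
        r.sentinel_id, r.proxy_id, r.cell_type, r.gene_id, r.mode, r.ocr_id
    ))
    return V2GResult(
        records=records,
        matrix=v2g_mapping.implication_matrix(records),
        merged_by_cell=merged_by_cell,
    )


def score_v2g(result: V2GResult, dataset: SimDataset) -> tuple[float, float]:
    """(precision, recall) of recovered implications against planted truth,
    at the (sentinel, gene, cell type, mode) level."""
    found = {
        (r.sentinel_id, r.gene_id, r.cell_type, r.mode) for r in result.records
    }
    truth = dataset.ground_truth.planted_v2g
    if not found:
        return (1.0 if not truth else 0.0), (1.0 if not truth else 0.0)
    tp = len(found & truth)
    return tp / len(found), tp / len(truth)


def run_heritability(
    dataset: SimDataset,
    window_bp: int = 100_000,
    n_blocks: int = 20,
) -> heritability_ldsc.EnrichmentResult:
    scores = heritability_ldsc.ld_scores(
        dataset.panel, dataset.annotations, window_bp=window_bp
    )
    return heritability_ldsc.fit_partitioned(
        dataset.sumstats["chi2"].to_numpy(),
        dataset.sumstats["N"].to_numpy(),
        scores,
        dataset.annotations,
        n_jackknife_blocks=n_blocks,
    )


def run_expression_contact(
    dataset: SimDataset, result: V2GResult
) -> dict[str, expression_contact.RankSumResult]:
    """Per-cell-type contacted vs non-contacted expression comparison."""
    chrom_len = dataset.config.chrom_length
    windows = [
        v2g_mapping.promoter_window(g, chrom_length=chrom_len)
        for g in dataset.genes
    ]
    gene_ids = [g.gene_id for g in dataset.genes]
    out = {}
    for cell, ocrs in dataset.ocrs_by_cell.items():
        classification = expression_contact.classify_contacted(
            result.merged_by_cell[cell], ocrs, windows
        )
        tpm = dataset.tpm.loc[gene_ids, cell].to_dict()
        out[cell] = expression_contact.compare_contacted_expression(
            classification, tpm
        )
    return out


def run_motifs(
    dataset: SimDataset, result: V2GResult, min_tpm: float = 1.0
) -> list[motif_disruption.MotifHit]:
    """Motif scan over the distinct proxies implicated by V2G, filtered to
    TFs expressed (TPM > min_tpm) in at least one implicated cell type."""
    snp_by_id = {s.snp_id: s for s in dataset.panel.snps}
    cells_of_proxy: dict[str, set[str]] = {}
    for r in result.records:
        cells_of_proxy.setdefault(r.proxy_id, set()).add(r.cell_type)
    snps = [snp_by_id[p] for p in sorted(cells_of_proxy)]
    hits = motif_disruption.scan_snps(dataset.pwms, dataset.genome, snps)
    kept = []
    for h in hits:
        for cell in sorted(cells_of_proxy[h.snp_id]):
            if motif_disruption.filter_expressed([h], dataset.tpm, cell,
                                                 min_tpm=min_tpm):
                kept.append(h)
                break
    return kept
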