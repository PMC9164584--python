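"""Variant-to-gene mapping: accessible GWAS proxies to effector genes.

The core inference: a sentinel's high-LD proxies are intersected with a
cell type's open chromatin regions (OCRs); an accessible proxy implicates
gene g either because its OCR overlaps g's promoter window (-1500/+500 bp
of TSS, strand-aware) — "promoter" mode — or because the OCR overlaps the
other end of a significant capture interaction baited at g's promoter —
"PIR" mode (promoter-interacting region).  Per gene x cell type the calls
collapse to promoter / distal / both / none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .capture_design import Interaction
from .genomic_core import GeneModel, GenomicInterval, OcrSet, Snp, overlaps
from .ld_proxies import ProxySet

logger = logging.getLogger("v2g")

MODE_PROMOTER = "promoter"
MODE_PIR = "PIR"


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class V2GRecord:
    """One implication: (sentinel, proxy, OCR, gene, cell type, mode)."""

    sentinel_id: str
    proxy_id: str
    r2: float
    ocr_id: str
    gene_id: str
    cell_type: str
    mode: str
    interaction_score: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in (MODE_PROMOTER, MODE_PIR):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mode == MODE_PIR and self.interaction_score is None:
            raise ValueError("PIR-mode record requires an interaction score")


def promoter_window(
    gene: GeneModel,
    up: int = 1500,
    down: int = 500,
    chrom_length: int | None = None,
) -> PromoterWindow:
    """The -up/+down promoter span around the TSS, strand-aware.

    Plus strand: [TSS-up, TSS+down).  Minus strand: the window reflected
    through the TSS, [TSS-down+1, TSS+up+1), so that "upstream" always
    means 5' of the gene.  Clipped to [0, chrom_length); truncation is
    logged.
    """
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down + 1, gene.tss + up + 1
    clipped_start = max(0, start)
    clipped_end = end if chrom_length is None else min(end, chrom_length)
    if clipped_start != start or clipped_end != end:
        logger.info(
            "promoter window of %s truncated by chromosome bounds", gene.gene_id
        )
    return PromoterWindow(
        gene_id=gene.gene_id,
        interval=GenomicInterval(gene.chrom, clipped_start, clipped_end,
                                 strand=gene.strand),
    )


def accessible_proxies(
    proxy_set: ProxySet, ocrs: OcrSet
) -> list[tuple[Snp, float, str]]:
    """(proxy, r², ocr_id) for every proxy falling inside an OCR.

    SNP positions intersect as length-1 half-open intervals [pos, pos+1);
    a proxy sitting exactly at an OCR's (exclusive) end coordinate is
    outside.  One row per (proxy, OCR) pair.
    """
    out = []
    for snp, r2 in proxy_set:
        for ocr_id, iv in ocrs:
            if overlaps(snp.interval, iv):
                out.append((snp, r2, ocr_id))
    return out


def implicate(
    accessible: list[tuple[Snp, float, str]],
    windows: list[PromoterWindow],
    merged: list[Interaction],
    cell_type: str,
    ocrs: OcrSet,
    sentinel_of: dict[str, str],
) -> list[V2GRecord]:
    """Turn accessible proxies into per-gene implication records.

    ``merged`` must already be score-filtered (the dual-resolution merge);
    ``sentinel_of`` maps proxy id -> sentinel id.  One record per distinct
    (proxy, OCR, gene, mode, interaction); a single proxy may implicate
    several genes and both modes.
    """
    records: set[V2GRecord] = set()
    for snp, r2, ocr_id in accessible:
        ocr = ocrs.intervals[ocr_id]
        sentinel_id = sentinel_of[snp.snp_id]
        for win in windows:
            if overlaps(ocr, win.interval):
                records.add(
                    V2GRecord(
                        sentinel_id=sentinel_id,
                        proxy_id=snp.snp_id,
                        r2=r2,
                        ocr_id=ocr_id,
                        gene_id=win.gene_id,
                        cell_type=cell_type,
                        mode=MODE_PROMOTER,
                    )
                )
        for inter in merged:
            if not inter.bait_genes:
                logger.warning("interaction with empty bait_genes skipped")
                continue
            if overlaps(ocr, inter.other_end):
                for gene_id in inter.bait_genes:
                    records.add(
                        V2GRecord(
                            sentinel_id=sentinel_id,
                            proxy_id=snp.snp_id,
                            r2=r2,
                            ocr_id=ocr_id,
                            gene_id=gene_id,
                            cell_type=cell_type,
                            mode=MODE_PIR,
                            interaction_score=inter.score,
                        )
                    )
    return sorted(
        records,
        key=lambda r: (r.sentinel_id, r.proxy_id, r.gene_id, r.mode, r.ocr_id),
    )


def implication_matrix(records: list[V2GRecord]) -> pd.DataFrame:
    """Gene x cell-type matrix of {none, promoter, distal, both} calls."""
    genes = sorted({r.gene_id for r in records})
    cell_types = sorted({r.cell_type for r in records})
    mat = pd.DataFrame("none", index=genes, columns=cell_types)
    modes: dict[tuple[str, str], set[str]] = {}
    for r in records:
        modes.setdefault((r.gene_id, r.cell_type), set()).add(r.mode)
    for (g, c), m in modes.items():
        if m == {MODE_PROMOTER}:
            mat.loc[g, c] = "promoter"
        elif m == {MODE_PIR}:
            mat.loc[g, c] = "distal"
        else:
            mat.loc[g, c] = "both"
    mat.index.name = "gene_id"
    return mat


def write_v2g_table(records: list[V2GRecord], ocrs_by_cell: dict[str, OcrSet],
                    path) -> None:
    rows = []
    for r in records:
        ocr = ocrs_by_cell[r.cell_type].intervals[r.ocr_id]
        rows.append(
            (
                r.sentinel_id, r.proxy_id, f"{r.r2:.6g}", r.cell_type,
                str(ocr), r.gene_id, r.mode,
                "" if r.interaction_score is None else f"{r.interaction_score:.6g}",
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "sentinel", "proxy", "r2", "cell_type", "ocr", "gene", "mode",
            "interaction_score",
        ],
    ).to_csv(path, sep="\t", index=False)
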