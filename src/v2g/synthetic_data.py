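"""Internally consistent toy dataset with known ground truth for every stage.

The generator emits, from a single seeded configuration: a genome with
restriction sites at a controlled Poisson rate; gene models with
non-overlapping promoters; phased haplotypes with block-structured LD;
per-cell-type open chromatin (OCR BEDs) and CHiCAGO-style scored
interactions (1-fragment and 4-fragment ibeds) with planted
variant-to-gene implications; GWAS summary statistics with a planted
heritability enrichment; log-normal expression with a planted
contacted-gene fold difference; and sharply peaked PWMs with planted
allele-specific motif disruptions.  Ground truth for every planting is
returned (and written as a JSON sidecar) so downstream precision/recall
can be scored without re-deriving it.

LD is modeled by block copying, not a coalescent: within a block every
haplotype copies a founder state with a per-SNP flip probability chosen so
pairwise r-squared hits the configured target; across blocks haplotypes
are independent.  GWAS chi-square statistics are drawn block-by-block on
the true sample LD matrix, so E[chi2_j] = 1 + N * sum_c tau_c * l(j,c)
holds by construction — the identity the heritability stage recovers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import capture_design, motif_disruption, v2g_mapping
from .capture_design import BaitMap, FragmentMap, Interaction
from .genomic_core import (
    BASES,
    GeneModel,
    GenomicInterval,
    OcrSet,
    Pwm,
    Snp,
    write_bed,
    write_fasta,
    write_gene_models,
    write_ibed,
    write_jaspar,
)
from .heritability_ldsc import BASE_CATEGORY, AnnotationMatrix
from .ld_proxies import HaplotypePanel, write_phased_vcf

logger = logging.getLogger("v2g")

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the toy study, a pure function of which the dataset is.

    Defaults give two 500-kb chromosomes, 200 SNPs and 10 LD blocks per
    chromosome, 200 haplotypes, 60 genes, 3 cell types, 12 planted
    variant-to-gene implications, a 10-fold heritability enrichment in a
    category covering 10% of SNPs, and a 10-fold expression difference for
    contacted genes — small enough for the full pipeline to run in well
    under two minutes on one CPU.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gatc_rate: float = 4.0  # expected GATC sites per kb
    n_genes: int = 60
    n_haplotypes: int = 200
    n_snps_per_chrom: int = 200
    n_blocks: int = 20
    block_r2: float = 0.95
    maf_min: float = 0.05
    n_sentinels: int = 6
    n_cell_types: int = 3
    planted_enrichment: float = 10.0
    enriched_fraction: float = 0.10
    h2_total: float = 0.4
    gwas_n: float = 10_000.0
    contacted_fold: float = 10.0
    noncontacted_median_tpm: float = 1.2
    tpm_log_sd: float = 1.0
    zero_fraction: float = 0.15
    n_planted_v2g: int = 12
    n_decoy_ocrs_per_cell: int = 20
    n_decoy_interactions_per_cell: int = 10
    n_background_contacts_per_cell: int = 15
    ocr_width_mean: float = 575.0
    ocr_width_sd: float = 100.0
    ocr_width_min: int = 100
    n_pwms: int = 6
    pwm_width: int = 8
    n_motif_plants: int = 4

    def __post_init__(self) -> None:
        for name in (
            "genome_length", "n_chromosomes", "n_genes", "n_haplotypes",
            "n_snps_per_chrom", "n_blocks", "n_sentinels", "n_cell_types",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.block_r2 <= 1.0:
            raise ValueError("block_r2 must be in [0, 1]")
        if self.planted_enrichment <= 0:
            raise ValueError("planted_enrichment must be > 0")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid VCF output)")
        if self.gatc_rate < 0:
            raise ValueError("gatc_rate must be >= 0")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def cell_types(self) -> list[str]:
        return [f"cell{i}" for i in range(self.n_cell_types)]


@dataclass
class GroundTruth:
    """Machine-readable planted truth, sufficient to score every stage."""

    planted_v2g: set[tuple[str, str, str, str]] = field(default_factory=set)
    causal_categories: dict[str, float] = field(default_factory=dict)
    disrupted_motifs: set[tuple[str, str, str]] = field(default_factory=set)
    contacted_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_v2g": sorted(list(t) for t in self.planted_v2g),
            "causal_categories": self.causal_categories,
            "disrupted_motifs": sorted(list(t) for t in self.disrupted_motifs),
            "contacted_genes": self.contacted_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SimDataset:
    """Everything one simulation run produced, in memory."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    panel: HaplotypePanel
    sentinels: list[Snp]
    block_of_snp: np.ndarray
    rmap: FragmentMap
    baitmap: BaitMap
    ocrs_by_cell: dict[str, OcrSet]
    ibeds_by_cell: dict[str, tuple[list[Interaction], list[Interaction]]]
    annotations: AnnotationMatrix
    sumstats: pd.DataFrame
    tpm: pd.DataFrame
    pwms: list[Pwm]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASE_CODES[rng.integers(0, 4, size=length)]


def _find_all(seq: np.ndarray, motif: bytes) -> list[int]:
    s = seq.tobytes()
    hits, start = [], 0
    while True:
        i = s.find(motif, start)
        if i == -1:
            return hits
        hits.append(i)
        start = i + 1


def _scrub_motif(seq: np.ndarray, rng: np.random.Generator,
                 motif: bytes = b"GATC") -> None:
    """Mutate the sequence in place until it contains no motif occurrence."""
    for _ in range(1000):
        hits = _find_all(seq, motif)
        if not hits:
            return
        for h in hits:
            j = h + rng.integers(0, len(motif))
            old = seq[j]
            choices = _BASE_CODES[_BASE_CODES != old]
            seq[j] = rng.choice(choices)
    raise RuntimeError("could not scrub restriction sites from background")


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Background genome with Poisson-planted GATC sites, plus gene models.

    Background nucleotides are i.i.d. but scrubbed of accidental GATC
    occurrences, so the realized site count per chromosome is exactly the
    Poisson draw (planting GATC over a clean background cannot create a
    second overlapping occurrence).  TSSs are evenly spaced with jitter and
    alternating strands; promoters (2 kb) never overlap.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.chrom_length
    genome: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        seq = _random_seq(rng, L)
        _scrub_motif(seq, rng)
        n_sites = rng.poisson(config.gatc_rate * L / 1000.0)
        taken = np.zeros(L, dtype=bool)
        placed = 0
        for cand in rng.permutation(max(1, L - 4)):
            if placed >= n_sites:
                break
            lo, hi = max(0, cand - 3), min(L, cand + 4)
            if taken[lo:hi].any():
                continue
            seq[cand: cand + 4] = _BASE_CODES[[2, 0, 3, 1]]  # G A T C
            taken[lo:hi] = True
            placed += 1
        if placed < n_sites:
            raise ValueError("genome too short for requested gatc_rate")
        genome[chrom] = seq

    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    genes: list[GeneModel] = []
    gid = 0
    biotypes = ["protein_coding", "lincRNA", "antisense"]
    for ci, chrom in enumerate(config.chrom_names):
        n = int(per_chrom[ci])
        spacing = L / (n + 1)
        if spacing < 2101:
            raise ValueError(
                "genome too short to host n_genes with non-overlapping "
                "2-kb promoters"
            )
        for k in range(n):
            jitter = rng.integers(-int(spacing // 5), int(spacing // 5) + 1)
            tss = int((k + 1) * spacing) + int(jitter)
            tss = min(max(tss, 2000), L - 2001)
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:04d}",
                    gene_name=f"GENE{gid:04d}",
                    chrom=chrom,
                    strand="+" if gid % 2 == 0 else "-",
                    tss=tss,
                    biotype=biotypes[gid % len(biotypes)],
                )
            )
            gid += 1
    genes.sort(key=lambda g: (g.chrom, g.tss))
    for a, b in zip(genes, genes[1:]):
        if a.chrom == b.chrom and b.tss - a.tss < 2101:
            raise ValueError("gene placement produced overlapping promoters")
    return {c: s.tobytes().decode("ascii") for c, s in genome.items()}, genes


# ---------------------------------------------------------------------------
# haplotypes with block LD
# ---------------------------------------------------------------------------


def _block_spans(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """Contiguous per-chromosome spans, one per LD block (tiling)."""
    per_chrom = config.n_blocks // config.n_chromosomes
    if per_chrom * config.n_chromosomes != config.n_blocks:
        raise ValueError("n_blocks must be divisible by n_chromosomes")
    L = config.chrom_length
    spans = []
    for chrom in config.chrom_names:
        edges = np.linspace(0, L, per_chrom + 1).astype(int)
        spans.extend((chrom, int(a), int(b)) for a, b in zip(edges, edges[1:]))
    return spans


def _block_sizes(config: SimulationConfig) -> list[int]:
    """SNPs per block; sizes deliberately vary so per-block LD scores differ."""
    per_chrom = config.n_blocks // config.n_chromosomes
    sizes = []
    for _ in range(config.n_chromosomes):
        base = config.n_snps_per_chrom // per_chrom
        pattern = np.round(
            base * (0.6 + 0.8 * np.arange(per_chrom) / max(1, per_chrom - 1))
        ).astype(int)
        pattern[-1] += config.n_snps_per_chrom - int(pattern.sum())
        sizes.extend(int(x) for x in pattern)
    return sizes


def _draw_block_haplotypes(
    rng: np.random.Generator, n_hap: int, n_snp: int, block_r2: float,
    maf_min: float,
) -> np.ndarray:
    """Founder-copying block: columns share a founder state with flip noise.

    Flip probability eps solves E[r^2] = (1 - 2 eps)^4 = block_r2.
    """
    eps = (1.0 - block_r2 ** 0.25) / 2.0
    founder = rng.integers(0, 2, size=n_hap)
    cols = []
    for _ in range(n_snp):
        for _attempt in range(200):
            flips = rng.random(n_hap) < eps
            col = founder ^ flips
            maf = min(col.mean(), 1 - col.mean())
            if maf >= maf_min:
                cols.append(col.astype(np.int8))
                break
        else:
            raise RuntimeError("could not draw a block column at maf_min")
    return np.column_stack(cols)


def simulate_haplotypes(
    config: SimulationConfig,
    rng: np.random.Generator,
    required_positions: dict[int, list[tuple[int, str]]] | None = None,
    anchored_snps: dict[str, tuple[str, str]] | None = None,
    genome: dict[str, str] | None = None,
) -> tuple[HaplotypePanel, np.ndarray, dict[str, str]]:
    """Phased haplotype panel with block LD; returns (panel, block index
    per SNP, sentinel id per block-with-a-sentinel).

    ``required_positions`` forces named SNPs at fixed positions inside
    given blocks (used to plant proxies at promoters, distal fragments and
    motif sites); ``anchored_snps`` fixes (ref, alt) alleles for named
    SNPs.  Other SNPs take ref from the genome sequence when provided.
    MAF >= maf_min is enforced by resampling.
    """
    required_positions = required_positions or {}
    anchored_snps = anchored_snps or {}
    spans = _block_spans(config)
    sizes = _block_sizes(config)
    snps: list[Snp] = []
    block_of: list[int] = []
    columns: list[np.ndarray] = []
    snp_serial = 0
    for b, ((chrom, lo, hi), size) in enumerate(zip(spans, sizes)):
        req = required_positions.get(b, [])
        if len(req) > size:
            raise ValueError(f"block {b}: more required SNPs than block size")
        positions: list[tuple[int, str | None]] = [(p, name) for p, name in req]
        used = {p for p, _ in positions}
        margin = min(1000, (hi - lo) // 10)
        while len(positions) < size:
            p = int(rng.integers(lo + margin, hi - margin))
            if p not in used:
                used.add(p)
                positions.append((p, None))
        positions.sort(key=lambda t: t[0])
        mat = _draw_block_haplotypes(
            rng, config.n_haplotypes, size, config.block_r2, config.maf_min
        )
        for j, (pos, name) in enumerate(positions):
            snp_id = name if name else f"rs{snp_serial + 900000}"
            snp_serial += 1
            if snp_id in anchored_snps:
                ref, alt = anchored_snps[snp_id]
            else:
                ref = genome[chrom][pos] if genome else "A"
                alt = str(rng.choice([x for x in BASES if x != ref]))
            snps.append(Snp(snp_id=snp_id, chrom=chrom, pos=pos,
                            ref_allele=ref, alt_allele=alt))
            columns.append(mat[:, j])
            block_of.append(b)
    panel = HaplotypePanel(
        snps=snps, matrix=np.column_stack(columns), population_label="SIM"
    )
    return panel, np.array(block_of), {}


# ---------------------------------------------------------------------------
# GWAS summary statistics with planted enrichment
# ---------------------------------------------------------------------------


def per_snp_variances(
    annotations: AnnotationMatrix,
    enriched_category: str,
    planted_enrichment: float,
    h2_total: float,
) -> np.ndarray:
    """Per-SNP effect variances realizing the planted fold enrichment.

    SNPs in the enriched category carry E*h2/M each; the remainder share
    the leftover uniformly, which requires E * (M_1/M) <= 1.
    """
    ind = annotations.indicators[:, annotations.categories.index(enriched_category)]
    M = len(ind)
    M1 = int(ind.sum())
    if M1 == 0:
        raise ValueError(f"enriched category {enriched_category!r} is empty")
    frac = M1 / M
    if planted_enrichment * frac > 1 + 1e-12:
        raise ValueError(
            "planted_enrichment * category fraction exceeds 1: no valid "
            "variance allocation"
        )
    v_in = planted_enrichment * h2_total / M
    v_out = h2_total * max(0.0, 1 - planted_enrichment * frac) / max(1, M - M1)
    return np.where(ind == 1, v_in, v_out)


def _block_corr(X: np.ndarray) -> np.ndarray:
    """Sample correlation matrix, shrunk toward identity until PD."""
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    lam = 0.0
    while True:
        Rs = (1 - lam) * R + lam * np.eye(len(R))
        try:
            np.linalg.cholesky(Rs + 0.0)
            return Rs
        except np.linalg.LinAlgError:
            lam = 0.01 if lam == 0.0 else lam * 2
            logger.info("LD matrix not PD; shrinking with lambda=%g", lam)
            if lam > 1:
                return np.eye(len(R))


def simulate_gwas(
    panel: HaplotypePanel,
    block_of_snp: np.ndarray,
    annotations: AnnotationMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
    enriched_category: str = "enriched",
    tau_zero: bool = False,
) -> pd.DataFrame:
    """Draw chi-square association statistics block-by-block.

    Per block with sample LD matrix R: beta ~ N(0, diag(v)),
    z = sqrt(N) R beta + e with e ~ N(0, R), chi2 = z^2; hence
    E[chi2_j] = 1 + N sum_k R_jk^2 v_k.  ``tau_zero`` switches to the pure
    null (v = 0) regardless of the planted enrichment.
    """
    M = len(panel.snps)
    if tau_zero:
        v = np.zeros(M)
    else:
        v = per_snp_variances(
            annotations, enriched_category, config.planted_enrichment,
            config.h2_total,
        )
    N = config.gwas_n
    chi2 = np.empty(M)
    for b in np.unique(block_of_snp):
        idx = np.where(block_of_snp == b)[0]
        X = panel.matrix[:, idx].astype(float)
        R = _block_corr(X)
        Lc = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
        beta = rng.normal(0.0, np.sqrt(v[idx]))
        e = Lc @ rng.standard_normal(len(idx))
        z = np.sqrt(N) * (R @ beta) + e
        chi2[idx] = z ** 2
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in panel.snps],
            "chi2": chi2,
            "N": N,
        }
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: list[str],
    contacted: set[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Log-normal TPMs; contacted genes get ``contacted_fold`` the median.

    A ``zero_fraction`` of non-contacted genes sits at TPM 0, mirroring
    the silent tail of real expression tables.
    """
    mu0 = np.log(config.noncontacted_median_tpm)
    vals = {}
    for g in genes:
        if g in contacted:
            vals[g] = float(
                rng.lognormal(mu0 + np.log(config.contacted_fold),
                              config.tpm_log_sd)
            )
        elif rng.random() < config.zero_fraction:
            vals[g] = 0.0
        else:
            vals[g] = float(rng.lognormal(mu0, config.tpm_log_sd))
    return pd.Series(vals)


# ---------------------------------------------------------------------------
# the full landscape (orchestrator)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Plant:
    sentinel_block: int
    gene_id: str
    cell_type: str
    mode: str  # promoter | PIR


def _default_plant_plan(config: SimulationConfig) -> list[tuple[int, str, int]]:
    """(sentinel index, mode, cell index) triples; genes are bound later.

    The fixed pattern exercises promoter-only, PIR-only, both-mode, and
    multi-cell-type implications within ``n_planted_v2g`` tuples.
    """
    pattern = [
        (0, "promoter", 0), (0, "PIR", 0),
        (1, "promoter", 1),
        (2, "PIR", 2),
        (3, "promoter", 0), (3, "PIR", 1),
        (4, "PIR", 0), (4, "PIR", 1), (4, "PIR", 2),
        (5, "promoter", 2), (5, "PIR", 2), (5, "promoter", 1),
    ]
    plan = [pattern[i % len(pattern)] for i in range(config.n_planted_v2g)]
    return [
        (s % config.n_sentinels, mode, c % config.n_cell_types)
        for s, mode, c in plan
    ]


def _truncated_normal_width(config: SimulationConfig,
                            rng: np.random.Generator) -> int:
    # upper cap bounds how far an OCR can reach past its anchoring SNP,
    # which the placement-clearance checks below rely on
    cap = config.ocr_width_mean + 8 * config.ocr_width_sd
    while True:
        w = rng.normal(config.ocr_width_mean, config.ocr_width_sd)
        if config.ocr_width_min <= w <= cap:
            return int(round(w))


def simulate_all(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimDataset:
    """Generate the complete dataset; optionally write every file to outdir.

    Deterministic given ``config`` (seed included).  Planted LD is
    re-drawn until every planted proxy's sample r-squared with its
    sentinel clears the 0.8 threshold with margin, so the planted
    implications are recoverable by construction.
    """
    rng = np.random.default_rng(config.seed)
    genome_str, genes = simulate_genome(config, rng)
    genome = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
              for c, s in genome_str.items()}
    gene_by_id = {g.gene_id: g for g in genes}
    spans = _block_spans(config)
    L = config.chrom_length

    # --- choose sentinel blocks, spread over the genome
    stride = max(1, config.n_blocks // config.n_sentinels)
    sentinel_blocks = [(i * stride + 1) % config.n_blocks
                       for i in range(config.n_sentinels)]
    if len(set(sentinel_blocks)) < config.n_sentinels:
        sentinel_blocks = list(range(config.n_sentinels))

    windows_all = [
        v2g_mapping.promoter_window(g, chrom_length=L) for g in genes
    ]

    def far_from_windows(chrom: str, pos: int, clearance: int = 5000) -> bool:
        return all(
            not (w.interval.start - clearance <= pos < w.interval.end + clearance)
            for w in windows_all if w.interval.chrom == chrom
        )

    # --- bind genes to the plant plan and fix required SNP positions
    plan_triples = _default_plant_plan(config)
    plants: list[_Plant] = []
    required: dict[int, list[tuple[int, str]]] = {}
    required_pos_by_block: dict[int, list[int]] = {}
    promoter_proxy_of: dict[tuple[int, str], str] = {}
    distal_proxy_of: dict[tuple[int, str], str] = {}
    distal_pos_of: dict[tuple[int, str], int] = {}
    sentinel_gene: dict[int, str] = {}
    used_genes: set[str] = set()
    proxy_serial = 0

    def block_gene(b: int) -> str:
        chrom, lo, hi = spans[b]
        for g in genes:
            if (g.gene_id not in used_genes and g.chrom == chrom
                    and lo + 2500 <= g.tss <= hi - 2500):
                used_genes.add(g.gene_id)
                return g.gene_id
        raise RuntimeError(f"no free gene inside block {b}")

    def reserve(b: int, pos: int, name: str) -> None:
        required.setdefault(b, []).append((pos, name))
        required_pos_by_block.setdefault(b, []).append(pos)

    def clear_of_required(b: int, pos: int, min_dist: int = 2000) -> bool:
        return all(abs(pos - p) >= min_dist
                   for p in required_pos_by_block.get(b, []))

    for s_idx, mode, c_idx in plan_triples:
        b = sentinel_blocks[s_idx]
        if s_idx not in sentinel_gene:
            sentinel_gene[s_idx] = block_gene(b)
        gene_id = sentinel_gene[s_idx]
        g = gene_by_id[gene_id]
        cell = config.cell_types[c_idx]
        if mode == "promoter":
            key = (s_idx, gene_id)
            if key not in promoter_proxy_of:
                pos = g.tss - 100 if g.strand == "+" else g.tss + 100
                name = f"rsP{proxy_serial:04d}"
                proxy_serial += 1
                promoter_proxy_of[key] = name
                reserve(b, pos, name)
        else:
            key = (s_idx, gene_id)
            if key not in distal_proxy_of:
                chrom, lo, hi = spans[b]
                for _ in range(2000):
                    pos = int(rng.integers(lo + 1000, hi - 1000))
                    if far_from_windows(chrom, pos) and clear_of_required(b, pos):
                        break
                else:
                    raise RuntimeError(f"no distal position found in block {b}")
                name = f"rsD{proxy_serial:04d}"
                proxy_serial += 1
                distal_proxy_of[key] = name
                distal_pos_of[key] = pos
                reserve(b, pos, name)
        plants.append(_Plant(s_idx, gene_id, cell, mode))

    # sentinel SNPs themselves, placed away from every planted proxy
    sentinel_names: dict[int, str] = {}
    for s_idx in range(config.n_sentinels):
        b = sentinel_blocks[s_idx]
        chrom, lo, hi = spans[b]
        for _ in range(2000):
            pos = int(rng.integers(lo + 1000, hi - 1000))
            if clear_of_required(b, pos, min_dist=2500):
                break
        else:
            raise RuntimeError(f"no sentinel position found in block {b}")
        name = f"rsS{s_idx:02d}"
        sentinel_names[s_idx] = name
        reserve(b, pos, name)

    # --- motif plants: edit the genome at chosen planted proxies
    pwms = []
    for k in range(config.n_pwms):
        counts = np.full((config.pwm_width, 4), 1.0)
        consensus_idx = rng.integers(0, 4, size=config.pwm_width)
        counts[np.arange(config.pwm_width), consensus_idx] = 97.0
        pwms.append(Pwm(tf_name=f"TF{k:02d}", matrix=counts))

    proxy_pos: dict[str, tuple[str, int]] = {}
    for b, entries in required.items():
        chrom = spans[b][0]
        for pos, name in entries:
            proxy_pos[name] = (chrom, pos)

    plantable = sorted(set(promoter_proxy_of.values()) |
                       set(distal_proxy_of.values()))
    anchored: dict[str, tuple[str, str]] = {}
    disrupted: set[tuple[str, str, str]] = set()
    for k in range(min(config.n_motif_plants, len(plantable), config.n_pwms)):
        snp_name = plantable[k]
        pwm = pwms[k]
        chrom, pos = proxy_pos[snp_name]
        direction = "decrease" if k % 2 == 0 else "increase"
        offset = int(rng.integers(1, config.pwm_width - 1))
        consensus = pwm.consensus()
        cons_base = consensus[offset]
        other = [x for x in BASES if x != cons_base]
        if direction == "decrease":
            ref, alt = cons_base, str(rng.choice(other))
            window = consensus
        else:
            ref = str(rng.choice(other))
            alt = cons_base
            window = consensus[:offset] + ref + consensus[offset + 1:]
        start = pos - offset
        genome[chrom][start: start + config.pwm_width] = np.frombuffer(
            window.encode(), dtype=np.uint8
        )
        anchored[snp_name] = (ref, alt)
        disrupted.add((snp_name, pwm.tf_name, direction))

    genome_str = {c: s.tobytes().decode("ascii") for c, s in genome.items()}

    # --- haplotypes honoring the required positions
    panel, block_of_snp, _ = simulate_haplotypes(
        config, rng, required_positions=required, anchored_snps=anchored,
        genome=genome_str,
    )
    snp_index = {s.snp_id: j for j, s in enumerate(panel.snps)}

    # re-draw planted blocks until every planted proxy clears the LD bar
    from .ld_proxies import compute_r2

    for s_idx in range(config.n_sentinels):
        b = sentinel_blocks[s_idx]
        s_col = panel.matrix[:, snp_index[sentinel_names[s_idx]]]
        needed = [n for n in required_pos_names(required, b)
                  if n != sentinel_names[s_idx]]
        for _ in range(100):
            ok = all(
                compute_r2(s_col, panel.matrix[:, snp_index[n]]) > 0.85
                for n in needed
            )
            if ok:
                break
            idx = np.where(block_of_snp == b)[0]
            mat = _draw_block_haplotypes(
                rng, config.n_haplotypes, len(idx), config.block_r2,
                config.maf_min,
            )
            panel.matrix[:, idx] = mat
            s_col = panel.matrix[:, snp_index[sentinel_names[s_idx]]]
        else:
            raise RuntimeError(f"block {b}: planted LD never cleared r2 > 0.85")

    sentinels = [panel.snps[snp_index[sentinel_names[i]]]
                 for i in range(config.n_sentinels)]

    # --- digestion of the final genome
    rmap = capture_design.digest(genome_str)
    rmap4 = capture_design.concatenate_fragments(rmap, k=4)
    baitmap = capture_design.assign_baits(rmap, genes)
    bait_frag_of_gene: dict[str, int] = {}
    for frag_id, gset in baitmap.entries.items():
        for gid in gset:
            bait_frag_of_gene.setdefault(gid, frag_id)
    frag_by_id = {f.frag_id: f for f in rmap.fragments}

    snp_pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        snp_pos_by_chrom[chrom] = np.array(
            sorted(s.pos for s in panel.snps if s.chrom == chrom)
        )

    def interval_has_snp(chrom: str, start: int, end: int) -> bool:
        pos = snp_pos_by_chrom[chrom]
        i = np.searchsorted(pos, start)
        return i < len(pos) and pos[i] < end

    def ocr_around(chrom: str, pos: int) -> GenomicInterval:
        w = _truncated_normal_width(config, rng)
        start = max(0, pos - w // 2)
        return GenomicInterval(chrom, start, min(L, start + w))

    # --- per-cell-type regulatory landscape
    ocrs_by_cell: dict[str, OcrSet] = {}
    ibeds_by_cell: dict[str, tuple[list[Interaction], list[Interaction]]] = {}
    truth = GroundTruth(disrupted_motifs=disrupted)
    contacted_by_cell: dict[str, set[str]] = {c: set() for c in config.cell_types}
    significant_other_ends: dict[str, list[GenomicInterval]] = {
        c: [] for c in config.cell_types
    }

    plant_keys = sorted({(p.sentinel_block, p.gene_id, p.cell_type, p.mode)
                         for p in plants})
    for cell in config.cell_types:
        ocrs = OcrSet(cell_type=cell)
        calls_1: list[Interaction] = []
        calls_4: list[Interaction] = []
        cell_plants = [p for s, gid, c, m in plant_keys
                       for p in [_Plant(s, gid, c, m)] if c == cell]
        for i, p in enumerate(cell_plants):
            g = gene_by_id[p.gene_id]
            sent_id = sentinel_names[p.sentinel_block]
            truth.planted_v2g.add((sent_id, p.gene_id, cell, p.mode))
            contacted_by_cell[cell].add(p.gene_id)
            if p.mode == "promoter":
                proxy = promoter_proxy_of[(p.sentinel_block, p.gene_id)]
                chrom, pos = proxy_pos[proxy]
                ocrs.add(ocr_around(chrom, pos), f"{cell}_prom_{p.gene_id}")
            else:
                proxy = distal_proxy_of[(p.sentinel_block, p.gene_id)]
                chrom, pos = proxy_pos[proxy]
                ocrs.add(ocr_around(chrom, pos), f"{cell}_pir_{p.gene_id}")
                frag = rmap.fragment_at(chrom, pos)
                bait = frag_by_id[bait_frag_of_gene[p.gene_id]]
                score = float(rng.uniform(5.5, 15.0))
                if not (far_from_windows(chrom, frag.interval.start, 1000)
                        and far_from_windows(chrom, frag.interval.end, 1000)):
                    raise RuntimeError("distal fragment collides with a promoter")
                calls_1.append(Interaction(
                    bait=bait.interval, bait_genes=frozenset({p.gene_id}),
                    other_end=frag.interval, score=score, resolution="1frag",
                    n_reads=int(rng.integers(10, 200)),
                ))
                significant_other_ends[cell].append(frag.interval)
                if i % 2 == 0:
                    frag4 = next(
                        f for f in rmap4.by_chrom(chrom)
                        if f.interval.start <= pos < f.interval.end
                    )
                    if not (far_from_windows(chrom, frag4.interval.start, 1000)
                            and far_from_windows(chrom, frag4.interval.end, 1000)):
                        # rare long bin reaching a promoter: emit 1frag only
                        continue
                    calls_4.append(Interaction(
                        bait=bait.interval,
                        bait_genes=frozenset({p.gene_id}),
                        other_end=frag4.interval,
                        score=float(rng.uniform(5.5, 15.0)),
                        resolution="4frag",
                        n_reads=int(rng.integers(10, 200)),
                    ))
                    significant_other_ends[cell].append(frag4.interval)

        # background (non-GWAS) promoter contacts: contacted genes for the
        # expression comparison, invisible to V2G (their OCRs hold no SNP)
        free_genes = [g for g in genes if g.gene_id not in used_genes]
        picked = rng.choice(len(free_genes),
                            size=min(config.n_background_contacts_per_cell,
                                     len(free_genes)),
                            replace=False)
        for gi in picked:
            g = free_genes[int(gi)]
            for _ in range(2000):
                pos = int(rng.integers(5000, L - 5000))
                iv = ocr_around(g.chrom, pos)
                frag = rmap.fragment_at(g.chrom, pos)
                # the fragment keeps a full OCR-reach away from every SNP,
                # so no accessible proxy's OCR can touch this other end
                ocr_reach = int(config.ocr_width_mean
                                + 8 * config.ocr_width_sd) // 2 + 10
                if (far_from_windows(g.chrom, pos)
                        and far_from_windows(g.chrom, frag.interval.start, 1200)
                        and far_from_windows(g.chrom, frag.interval.end, 1200)
                        and not interval_has_snp(g.chrom, iv.start - 5, iv.end + 5)
                        and not interval_has_snp(
                            g.chrom,
                            frag.interval.start - ocr_reach,
                            frag.interval.end + ocr_reach)):
                    break
            else:
                raise RuntimeError("no background contact position found")
            ocrs.add(iv, f"{cell}_bg_{g.gene_id}")
            bait = frag_by_id[bait_frag_of_gene[g.gene_id]]
            calls_1.append(Interaction(
                bait=bait.interval, bait_genes=frozenset({g.gene_id}),
                other_end=frag.interval, score=float(rng.uniform(5.5, 15.0)),
                resolution="1frag", n_reads=int(rng.integers(10, 200)),
            ))
            significant_other_ends[cell].append(frag.interval)
            contacted_by_cell[cell].add(g.gene_id)

        # decoy OCRs: SNP-free, promoter-free, contact-free negatives
        for d in range(config.n_decoy_ocrs_per_cell):
            chrom = config.chrom_names[d % config.n_chromosomes]
            for _ in range(5000):
                pos = int(rng.integers(2000, L - 2000))
                iv = ocr_around(chrom, pos)
                if (far_from_windows(chrom, pos, clearance=2000)
                        and not interval_has_snp(chrom, iv.start - 5, iv.end + 5)
                        and all(not _touch(iv, oe)
                                for oe in significant_other_ends[cell])):
                    break
            else:
                raise RuntimeError("no decoy OCR position found")
            ocrs.add(iv, f"{cell}_decoy{d:03d}")

        # sub-threshold decoy interactions, incl. some from truly
        # accessible distal fragments to the wrong gene (score filter bait)
        other_gene_pool = [g.gene_id for g in genes]
        for d in range(config.n_decoy_interactions_per_cell):
            if d < len(cell_plants):
                p = cell_plants[d]
                key = (p.sentinel_block, p.gene_id)
                if p.mode == "PIR" and key in distal_pos_of:
                    chrom, pos = proxy_pos[distal_proxy_of[key]]
                    frag = rmap.fragment_at(chrom, pos)
                    wrong = next(gid for gid in other_gene_pool
                                 if gid != p.gene_id)
                    calls_1.append(Interaction(
                        bait=frag_by_id[bait_frag_of_gene[wrong]].interval,
                        bait_genes=frozenset({wrong}),
                        other_end=frag.interval,
                        score=float(rng.uniform(0.5, 4.9)),
                        resolution="1frag",
                        n_reads=int(rng.integers(1, 20)),
                    ))
                    continue
            gid = other_gene_pool[int(rng.integers(len(other_gene_pool)))]
            g = gene_by_id[gid]
            pos = int(rng.integers(2000, L - 2000))
            frag = rmap.fragment_at(g.chrom, pos)
            calls_1.append(Interaction(
                bait=frag_by_id[bait_frag_of_gene[gid]].interval,
                bait_genes=frozenset({gid}),
                other_end=frag.interval,
                score=float(rng.uniform(0.5, 4.9)),
                resolution="1frag",
                n_reads=int(rng.integers(1, 20)),
            ))

        ocrs_by_cell[cell] = ocrs
        ibeds_by_cell[cell] = (calls_1, calls_4)

    truth.contacted_genes = {
        c: sorted(s) for c, s in contacted_by_cell.items()
    }

    # --- annotations + GWAS
    M = len(panel.snps)
    n_enriched = max(1, round(config.enriched_fraction * M))
    enriched_idx = enriched_snp_indices(n_enriched, block_of_snp, rng)
    categories = [BASE_CATEGORY, "enriched"] + [
        f"{c}_ocr" for c in config.cell_types
    ]
    indicators = np.zeros((M, len(categories)))
    indicators[:, 0] = 1.0
    indicators[enriched_idx, 1] = 1.0
    for ci, cell in enumerate(config.cell_types, start=2):
        for j, s in enumerate(panel.snps):
            if any(iv.chrom == s.chrom and iv.start <= s.pos < iv.end
                   for _id, iv in ocrs_by_cell[cell]):
                indicators[j, ci] = 1.0
    annotations = AnnotationMatrix(
        snp_ids=[s.snp_id for s in panel.snps],
        categories=categories,
        indicators=indicators,
    )
    sumstats = simulate_gwas(panel, block_of_snp, annotations, config, rng)
    v = per_snp_variances(annotations, "enriched",
                          config.planted_enrichment, config.h2_total)
    truth.causal_categories = {
        "enriched": float(v[enriched_idx[0]]),
        BASE_CATEGORY: float(np.median(v)),
    }

    # --- expression (genes + TFs)
    tpm_cols = {}
    for cell in config.cell_types:
        series = simulate_expression(
            [g.gene_id for g in genes], contacted_by_cell[cell], config, rng
        )
        tf_rows = {}
        for k, pwm in enumerate(pwms):
            planted_tf = any(t[1] == pwm.tf_name for t in disrupted)
            tf_rows[pwm.tf_name] = (
                float(rng.uniform(5.0, 50.0)) if planted_tf
                else float(rng.uniform(0.0, 0.9))
            )
        tpm_cols[cell] = pd.concat([series, pd.Series(tf_rows)])
    tpm = pd.DataFrame(tpm_cols)
    tpm.index.name = "gene"

    dataset = SimDataset(
        config=config,
        genome=genome_str,
        genes=genes,
        panel=panel,
        sentinels=sentinels,
        block_of_snp=block_of_snp,
        rmap=rmap,
        baitmap=baitmap,
        ocrs_by_cell=ocrs_by_cell,
        ibeds_by_cell=ibeds_by_cell,
        annotations=annotations,
        sumstats=sumstats,
        tpm=tpm,
        pwms=pwms,
        ground_truth=truth,
    )
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def enriched_snp_indices(
    n_enriched: int, block_of_snp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Block-clustered choice of enriched-category SNPs.

    Regulatory annotations cluster along the genome, so the enriched
    category concentrates in a subset of LD blocks (~35% of a chosen
    block's SNPs) rather than spreading uniformly; blocks without any
    annotated SNP then anchor the regression's base coefficient and
    intercept, keeping the planted enrichment identifiable.
    """
    blocks = rng.permutation(np.unique(block_of_snp))
    chosen: list[int] = []
    for b in blocks:
        if len(chosen) >= n_enriched:
            break
        idx = np.where(block_of_snp == b)[0]
        take = min(max(1, round(0.35 * len(idx))), n_enriched - len(chosen))
        chosen.extend(rng.choice(idx, size=take, replace=False))
    return np.array(sorted(chosen))


def required_pos_names(required: dict[int, list[tuple[int, str]]],
                       block: int) -> list[str]:
    return [name for _pos, name in required.get(block, [])]


def far_enough(frag: GenomicInterval, windows, clearance: int = 0) -> bool:
    from .genomic_core import overlaps

    return all(not overlaps(frag, w.interval) for w in windows)


def _touch(a: GenomicInterval, b: GenomicInterval) -> bool:
    from .genomic_core import overlaps

    return overlaps(a, b)


def write_dataset(dataset: SimDataset, outdir: str | Path) -> None:
    """Emit every file of the dataset in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, outdir / "genome.fa")
    write_gene_models(dataset.genes, outdir / "genes.tsv")
    write_phased_vcf(dataset.panel, outdir / "panel.vcf")
    pd.DataFrame(
        [
            (s.snp_id, s.chrom, s.pos, s.ref_allele, s.alt_allele)
            for s in dataset.sentinels
        ],
        columns=["snp_id", "chrom", "pos", "ref", "alt"],
    ).to_csv(outdir / "sentinels.tsv", sep="\t", index=False)
    for cell, ocrs in dataset.ocrs_by_cell.items():
        write_bed(ocrs, outdir / f"ocr_{cell}.bed")
    for cell, (c1, c4) in dataset.ibeds_by_cell.items():
        write_ibed(c1, outdir / f"interactions_{cell}_1frag.ibed")
        write_ibed(c4, outdir / f"interactions_{cell}_4frag.ibed")
    dataset.sumstats.to_csv(outdir / "sumstats.tsv", sep="\t", index=False)
    dataset.tpm.to_csv(outdir / "tpm.tsv", sep="\t")
    write_jaspar(dataset.pwms, outdir / "pwms.jaspar")
    capture_design.write_rmap(dataset.rmap, outdir / "fragments.rmap")
    capture_design.write_baitmap(dataset.rmap, dataset.baitmap,
                                 outdir / "fragments.baitmap")
    annot = pd.DataFrame(
        dataset.annotations.indicators,
        columns=dataset.annotations.categories,
    )
    annot.insert(0, "snp_id", dataset.annotations.snp_ids)
    annot.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    dataset.ground_truth.to_json(outdir / "ground_truth.json")
    (outdir / "config.json").write_text(json.dumps(asdict(dataset.config), indent=2))
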