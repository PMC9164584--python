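"""Pairwise LD (r-squared) from phased haplotypes and sentinel proxy expansion.

A haplotype panel is a binary haplotype x SNP matrix (0 = ref, 1 = alt)
from a phased VCF, assumed already subset to the analysis population.
Sentinels are expanded into proxy sets at r-squared strictly above 0.8
within a 500 kb window each side, the convention of the LD-proxy lookups
this module replaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .genomic_core import Snp

logger = logging.getLogger("v2g")


class MonomorphicError(ValueError):
    """LD is undefined for a monomorphic column; callers skip the pair."""


@dataclass
class HaplotypePanel:
    """Phased haplotypes: ``matrix`` is (n_haplotypes, n_snps) in {0, 1}."""

    snps: list[Snp]
    matrix: np.ndarray
    population_label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.snps):
            raise ValueError("matrix columns must match SNP count")
        if self.matrix.shape[0] < 4:
            raise ValueError("need at least 4 haplotypes")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    def column(self, snp_id: str) -> np.ndarray:
        try:
            j = next(i for i, s in enumerate(self.snps) if s.snp_id == snp_id)
        except StopIteration:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None
        return self.matrix[:, j]


@dataclass
class ProxySet:
    """A sentinel with its high-LD proxies; the sentinel is element 0 at r²=1."""

    sentinel: Snp
    proxies: list[tuple[Snp, float]] = field(default_factory=list)
    window_bp: int = 500_000

    def __iter__(self):
        return iter(self.proxies)

    def __len__(self) -> int:
        return len(self.proxies)


def compute_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Haplotype-counting r² between two 0/1 allele columns.

    r² = D² / (p_A(1-p_A) p_B(1-p_B)) with D = p_AB - p_A p_B, all
    frequencies counted over haplotypes.  Equals the squared Pearson
    correlation of the two columns; allele-label flips leave it unchanged.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be equal-length 1-D arrays")
    if a.size < 4:
        raise ValueError("need at least 4 haplotypes")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicError("LD undefined for a monomorphic column")
    p_ab = float(np.mean((a == 1) & (b == 1)))
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(min(r2, 1.0))


def find_proxies(
    panel: HaplotypePanel,
    sentinel: Snp | str,
    r2_min: float = 0.8,
    window_bp: int = 500_000,
) -> ProxySet:
    """All panel SNPs within ``window_bp`` of the sentinel at r² > ``r2_min``.

    The threshold is strict (r² = 0.8 exactly is excluded).  The sentinel
    itself is always returned first, at r² = 1.  Proxies are sorted by
    descending r², ties broken by position.
    """
    sentinel_id = sentinel if isinstance(sentinel, str) else sentinel.snp_id
    try:
        s_idx = next(
            i for i, s in enumerate(panel.snps) if s.snp_id == sentinel_id
        )
    except StopIteration:
        raise KeyError(f"sentinel {sentinel_id!r} not found in panel") from None
    sent = panel.snps[s_idx]
    s_col = panel.matrix[:, s_idx]
    hits: list[tuple[Snp, float]] = []
    for j, snp in enumerate(panel.snps):
        if j == s_idx:
            continue
        if snp.chrom != sent.chrom or abs(snp.pos - sent.pos) > window_bp:
            continue
        try:
            r2 = compute_r2(s_col, panel.matrix[:, j])
        except MonomorphicError:
            continue
        if r2 > r2_min:
            hits.append((snp, r2))
    hits.sort(key=lambda t: (-t[1], t[0].pos))
    return ProxySet(
        sentinel=sent,
        proxies=[(sent, 1.0)] + hits,
        window_bp=window_bp,
    )


def read_phased_vcf(path, population_label: str = "") -> HaplotypePanel:
    """Load a phased VCF into a HaplotypePanel.

    VCF POS is 1-based and converted to the package's 0-based convention.
    Multi-allelic and non-SNP records are excluded with a logged count;
    unphased genotypes raise.
    """
    vcf = VCF(str(path))
    snps: list[Snp] = []
    columns: list[np.ndarray] = []
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_excluded += 1
            continue
        gts = np.array(var.genotypes)  # (n_samples, 3): a0, a1, phased
        if not gts[:, 2].all():
            raise ValueError(f"unphased genotype at {var.ID or var.POS}")
        hap = gts[:, :2].reshape(-1)
        snps.append(
            Snp(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=var.CHROM,
                pos=var.POS - 1,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
            )
        )
        columns.append(hap.astype(np.int8))
    if n_excluded:
        logger.info("excluded %d multi-allelic/non-SNP records", n_excluded)
    if not snps:
        raise ValueError(f"{path}: no biallelic SNPs found")
    return HaplotypePanel(
        snps=snps,
        matrix=np.column_stack(columns),
        population_label=population_label,
    )


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Emit the panel as a minimal phased VCF (pairs of haplotypes per sample)."""
    n_hap = panel.n_haplotypes
    if n_hap % 2:
        raise ValueError("need an even haplotype count for diploid VCF output")
    samples = [f"S{i:04d}" for i in range(n_hap // 2)]
    chroms = sorted({s.chrom for s in panel.snps})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        order = sorted(range(len(panel.snps)),
                       key=lambda j: (panel.snps[j].chrom, panel.snps[j].pos))
        for j in order:
            s = panel.snps[j]
            col = panel.matrix[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))
            )
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_proxy_table(proxy_sets: list[ProxySet], path) -> None:
    with open(path, "w") as fh:
        fh.write("sentinel_id\tproxy_id\tchrom\tpos\tref\talt\tr2\n")
        for ps in proxy_sets:
            for snp, r2 in ps:
                fh.write(
                    f"{ps.sentinel.snp_id}\t{snp.snp_id}\t{snp.chrom}\t"
                    f"{snp.pos}\t{snp.ref_allele}\t{snp.alt_allele}\t{r2:.6g}\n"
                )
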