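"""Simplified stratified LD-score regression at desk scale.

Per-annotation LD scores l(j,c) = sum_k r2~(j,k) a_kc are computed from a
haplotype panel with the finite-sample bias correction
r2~ = r2 - (1 - r2)/(n_hap - 2), over a fixed-bp window.  GWAS chi-square
statistics are regressed on N*l(j,c) with a free intercept and weights
1/max(1, l_base)^2; tau coefficients are turned into per-category
heritability shares and fold enrichments (heritability share / SNP share)
with delete-one-block jackknife 95% CIs and Benjamini-Hochberg FDR.

This is deliberately lighter than the genome-scale tool it mirrors: no
MAF-stratified baseline model, fixed-bp (not cM) windows, equal per-SNP
weighting inside categories, and 20 jackknife blocks by default (toy SNP
counts cannot support 200).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ld_proxies import HaplotypePanel

logger = logging.getLogger("v2g")

BASE_CATEGORY = "base"


@dataclass
class AnnotationMatrix:
    """SNP x category binary indicators; the base category is all ones."""

    snp_ids: list[str]
    categories: list[str]
    indicators: np.ndarray

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=float)
        if self.indicators.shape != (len(self.snp_ids), len(self.categories)):
            raise ValueError("indicator shape must be (n_snps, n_categories)")
        if BASE_CATEGORY not in self.categories:
            raise ValueError(f"must include the {BASE_CATEGORY!r} category")
        base = self.indicators[:, self.categories.index(BASE_CATEGORY)]
        if not (base == 1).all():
            raise ValueError("base category must be all ones")

    @property
    def snp_counts(self) -> np.ndarray:
        """M_c: number of SNPs per category."""
        return self.indicators.sum(axis=0)


@dataclass
class LdScoreTable:
    snp_ids: list[str]
    categories: list[str]
    scores: np.ndarray  # (n_snps, n_categories)
    window_bp: int


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # category, tau, h2_share, snp_share, enrichment, se, ci_lo, ci_hi, p, fdr
    intercept: float
    h2_total: float


def ld_scores(
    panel: HaplotypePanel,
    annotations: AnnotationMatrix,
    window_bp: int = 100_000,
) -> LdScoreTable:
    """Per-SNP, per-category LD scores with finite-sample bias correction.

    The self term is included (r2~(j,j) = 1).  Only pairs on the same
    chromosome within ``window_bp`` contribute.
    """
    if annotations.snp_ids != [s.snp_id for s in panel.snps]:
        raise ValueError("annotation SNPs must match panel SNPs in order")
    X = panel.matrix.astype(float)
    n_hap, n_snp = X.shape
    pos = np.array([s.pos for s in panel.snps])
    chroms = np.array([s.chrom for s in panel.snps])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if (sd == 0).any():
        raise ValueError("panel contains monomorphic SNPs")
    Z = Xc / sd
    scores = np.zeros((n_snp, len(annotations.categories)))
    for chrom in np.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        r = (Z[:, idx].T @ Z[:, idx]) / n_hap
        r2 = r ** 2
        r2_adj = r2 - (1.0 - r2) / (n_hap - 2)
        in_window = np.abs(pos[idx][:, None] - pos[idx][None, :]) <= window_bp
        r2_adj = np.where(in_window, r2_adj, 0.0)
        scores[idx] = r2_adj @ annotations.indicators[idx]
    return LdScoreTable(
        snp_ids=list(annotations.snp_ids),
        categories=list(annotations.categories),
        scores=scores,
        window_bp=window_bp,
    )


def _wls_tau(
    chi2: np.ndarray,
    N: np.ndarray,
    scores: np.ndarray,
    base_idx: int,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, float]:
    """Two-step weighted least squares of chi2 on N*l(j,c).

    Step 1 uses oversampling weights 1/max(1, l_base)^2; step 2 adds the
    heteroskedasticity factor 1/mu_j^2 with mu_j the step-1 fitted mean of
    chi2_j (its sampling variance grows as mu^2), the standard stratified
    LD-score regression weighting.  Returns (tau, intercept).
    """
    design = scores * N[:, None]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the collinear columns for the error message
        corr = np.corrcoef(design.T)
        dupes = [
            (i, j)
            for i in range(len(corr))
            for j in range(i + 1, len(corr))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear column pairs {dupes}")
    base_l = np.maximum(1.0, scores[:, base_idx])
    X = sm.add_constant(design) if fit_intercept else design
    fit1 = sm.WLS(chi2, X, weights=1.0 / base_l ** 2).fit()
    mu = np.maximum(1.0, X @ fit1.params)
    fit = sm.WLS(chi2, X, weights=1.0 / (base_l * mu ** 2)).fit()
    if fit_intercept:
        return fit.params[1:], float(fit.params[0])
    return fit.params, 1.0


def _enrichment_from_tau(
    tau: np.ndarray, indicators: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Per-category enrichment from tau: h2_j = sum_c tau_c a_jc summed over
    category members, divided by the category's SNP share."""
    h2_per_snp = indicators @ tau
    h2_total = float(h2_per_snp.sum())
    m_total = indicators.shape[0]
    h2_c = indicators.T @ h2_per_snp
    m_c = indicators.sum(axis=0)
    h2_share = h2_c / h2_total if h2_total != 0 else np.full_like(h2_c, np.nan)
    snp_share = m_c / m_total
    return h2_share / snp_share, h2_total, h2_share, snp_share


def fit_partitioned(
    chi2: np.ndarray,
    N: np.ndarray | float,
    ldscores: LdScoreTable,
    annotations: AnnotationMatrix,
    n_jackknife_blocks: int = 20,
    fit_intercept: bool = True,
) -> EnrichmentResult:
    """Estimate per-category tau, heritability enrichment, jackknife CIs, FDR.

    ``chi2`` must align with ``ldscores.snp_ids``.  Enrichment of category
    C is (h2(C)/h2_total) / (M_C/M) where h2(C) sums the model's per-SNP
    heritability over C's members; the base category therefore has
    enrichment identically 1.  Jackknife blocks are contiguous equal-count
    SNP blocks; p-values are two-sided normal for H0: enrichment = 1.
    """
    chi2 = np.asarray(chi2, dtype=float)
    if (chi2 < 0).any():
        raise ValueError("chi2 must be non-negative")
    n_snp = len(ldscores.snp_ids)
    N = np.full(n_snp, float(N)) if np.isscalar(N) else np.asarray(N, float)
    base_idx = ldscores.categories.index(BASE_CATEGORY)

    tau, intercept = _wls_tau(
        chi2, N, ldscores.scores, base_idx, fit_intercept
    )
    enrichment, h2_total, h2_share, snp_share = _enrichment_from_tau(
        tau, annotations.indicators
    )

    se, ci, pvals = jackknife(
        chi2, N, ldscores, annotations, n_blocks=n_jackknife_blocks,
        fit_intercept=fit_intercept,
    )
    fdr = bh_fdr(pvals)
    table = pd.DataFrame(
        {
            "category": ldscores.categories,
            "tau": tau,
            "h2_share": h2_share,
            "snp_share": snp_share,
            "enrichment": enrichment,
            "se": se,
            "ci_lo": ci[:, 0],
            "ci_hi": ci[:, 1],
            "p": pvals,
            "fdr": fdr,
        }
    )
    return EnrichmentResult(table=table, intercept=intercept, h2_total=h2_total)


def jackknife(
    chi2: np.ndarray,
    N: np.ndarray,
    ldscores: LdScoreTable,
    annotations: AnnotationMatrix,
    n_blocks: int = 20,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delete-one-block jackknife over the enrichment estimator.

    Blocks are contiguous equal-SNP-count spans in panel order (the panel
    is position-sorted per chromosome, so blocks are genomic).
    se = sqrt((B-1)/B * sum (theta_b - theta_bar)^2); ci95 = point +-
    1.96 se; two-sided normal p for H0: enrichment = 1.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    n_snp = len(chi2)
    base_idx = ldscores.categories.index(BASE_CATEGORY)
    bounds = np.linspace(0, n_snp, n_blocks + 1).astype(int)
    # merge empty blocks into their neighbor
    bounds = np.unique(bounds)
    B = len(bounds) - 1
    if B < n_blocks:
        logger.info("merged %d empty jackknife blocks", n_blocks - B)

    tau_full, _ = _wls_tau(chi2, N, ldscores.scores, base_idx, fit_intercept)
    theta_full, _, _, _ = _enrichment_from_tau(tau_full, annotations.indicators)

    thetas = np.empty((B, len(ldscores.categories)))
    for b in range(B):
        keep = np.ones(n_snp, bool)
        keep[bounds[b]: bounds[b + 1]] = False
        tau_b, _ = _wls_tau(
            chi2[keep], N[keep], ldscores.scores[keep], base_idx, fit_intercept
        )
        thetas[b], _, _, _ = _enrichment_from_tau(
            tau_b, annotations.indicators[keep]
        )
    theta_bar = thetas.mean(axis=0)
    se = np.sqrt((B - 1) / B * ((thetas - theta_bar) ** 2).sum(axis=0))
    ci = np.column_stack(
        (theta_full - 1.96 * se, theta_full + 1.96 * se)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (theta_full - 1.0) / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    pvals = np.where(se > 0, pvals, 1.0)
    return se, ci, pvals


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out
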