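"""Contacted vs non-contacted genes and the expression rank-sum comparison.

A gene is "contacted" in a cell type when at least one open chromatin
region overlaps either the other end of a significant capture interaction
baited at its promoter or the promoter window itself (a ``distal_only``
switch restricts to the former).  Expression (TPM) of contacted vs
non-contacted genes is compared with a two-sided Wilcoxon rank-sum test:
exact by full enumeration (tie-aware, via a midrank convolution) when the
combined sample size is at most 20, otherwise a tie-corrected normal
approximation with continuity correction.  Zeros in TPM are legitimate
values, not missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .capture_design import Interaction
from .genomic_core import OcrSet, overlaps
from .v2g_mapping import PromoterWindow

logger = logging.getLogger("v2g")

EXACT_CUTOFF = 20


@dataclass
class ContactClassification:
    """Gene-level and OCR-level contact splits for one cell type."""

    cell_type: str
    n_contacting_ocrs: dict[str, int]  # gene_id -> count
    ocr_contacting: dict[str, bool]  # ocr_id -> contacts any promoter

    def contacted(self, gene_id: str) -> bool:
        return self.n_contacting_ocrs.get(gene_id, 0) >= 1

    @property
    def contacted_genes(self) -> set[str]:
        return {g for g, n in self.n_contacting_ocrs.items() if n >= 1}

    @property
    def ocr_split(self) -> tuple[int, int]:
        """(contacting, non-contacting) OCR counts."""
        n_yes = sum(self.ocr_contacting.values())
        return n_yes, len(self.ocr_contacting) - n_yes


@dataclass
class RankSumResult:
    statistic: float  # rank-sum of group 1 (midranks)
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    medians: tuple[float, float]


def classify_contacted(
    merged: list[Interaction],
    ocrs: OcrSet,
    windows: list[PromoterWindow],
    distal_only: bool = False,
) -> ContactClassification:
    """Count, per gene, the OCRs contacting its promoter.

    An OCR contacts gene g when it overlaps the other end of a merged
    interaction with g among its bait genes, or (unless ``distal_only``)
    overlaps g's promoter window.  The OCR-level split marks each OCR as
    promoter-contacting or not, for the complementary landscape view.
    """
    n_contacting: dict[str, set[str]] = {w.gene_id: set() for w in windows}
    ocr_contacting: dict[str, bool] = {}
    for ocr_id, iv in ocrs:
        touches = False
        for inter in merged:
            if overlaps(iv, inter.other_end):
                for g in inter.bait_genes:
                    n_contacting.setdefault(g, set()).add(ocr_id)
                touches = True
        if not distal_only:
            for w in windows:
                if overlaps(iv, w.interval):
                    n_contacting[w.gene_id].add(ocr_id)
                    touches = True
        ocr_contacting[ocr_id] = touches
    return ContactClassification(
        cell_type=ocrs.cell_type,
        n_contacting_ocrs={g: len(s) for g, s in n_contacting.items()},
        ocr_contacting=ocr_contacting,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_two_sided_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Tie-aware exact two-sided p by enumeration of all C(n, n1) labelings.

    Implemented as a subset-sum convolution over doubled midranks (always
    integers), equivalent to full enumeration but polynomial: f[k][s]
    counts size-k subsets with doubled-rank-sum s.
    """
    d = np.rint(2 * ranks).astype(int)
    n = len(d)
    total = int(d.sum())
    # f[k][s]: number of size-k subsets of the first i items summing to s
    f = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    f[0, 0] = 1
    for v in d:
        for k in range(min(n1, n), 0, -1):
            f[k, v:] += f[k - 1, : total + 1 - v]
    counts = f[n1]
    mu = n1 * (n + 1) / 2.0  # null mean of the rank-sum (midranks preserve it)
    dev_obs = abs(w_obs - mu)
    sums = np.arange(total + 1) / 2.0
    extreme = np.abs(sums - mu) >= dev_obs - 1e-9
    return float(counts[extreme].sum() / comb(n, n1))


def _normal_approx_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(ranks)
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all pooled values identical
    dev = abs(w_obs - mu)
    z = max(0.0, dev - 0.5) / np.sqrt(var)
    return float(min(1.0, 2 * stats.norm.sf(z)))


def rank_sum_test(
    x, y, exact_cutoff: int = EXACT_CUTOFF
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Midranks handle ties.  With combined n <= ``exact_cutoff`` the p-value
    is exact over all C(n1+n2, n1) group labelings; beyond that a
    tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[: x.size].sum())
    if pooled.size <= exact_cutoff:
        p = _exact_two_sided_p(ranks, x.size, w_obs)
        method = "exact"
    else:
        p = _normal_approx_p(ranks, x.size, w_obs)
        method = "normal_approx"
    return RankSumResult(
        statistic=w_obs,
        p_two_sided=p,
        method=method,
        medians=(float(np.median(x)), float(np.median(y))),
    )


def compare_contacted_expression(
    classification: ContactClassification,
    tpm: dict[str, float],
) -> RankSumResult:
    """Rank-sum comparison of TPM between contacted and non-contacted genes."""
    contacted = [v for g, v in tpm.items() if classification.contacted(g)]
    non_contacted = [v for g, v in tpm.items() if not classification.contacted(g)]
    return rank_sum_test(contacted, non_contacted)
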