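"""Allele-specific PWM scanning at accessible proxies.

Every placement of a motif covering a SNP, on both strands, is scored for
the reference and alternate alleles with a min-max-normalized log-odds
score in [0, 1] (1 = consensus, 0 = anti-consensus).  The placement with
the best allele score is kept; a hit is reported when that best score
reaches the report threshold and the allele difference (delta) reaches the
weak threshold, and its direction (increase/decrease of binding affinity)
is the sign of delta.  Hits are finally filtered to transcription factors
expressed in the implicated cell type (TPM strictly above 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_core import BASES, Pwm, Snp, reverse_complement

logger = logging.getLogger("v2g")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

REPORT_THRESHOLD = 0.85
WEAK_THRESHOLD = 0.04
STRONG_THRESHOLD = 0.10


@dataclass(frozen=True)
class MotifHit:
    snp_id: str
    tf_name: str
    strand: str
    offset: int  # 0-based SNP position within the motif
    ref_score: float
    alt_score: float

    @property
    def delta(self) -> float:
        return self.alt_score - self.ref_score

    @property
    def direction(self) -> str:
        return "increase" if self.delta > 0 else "decrease"

    def strength(self, strong_threshold: float = STRONG_THRESHOLD) -> str:
        return "strong" if abs(self.delta) >= strong_threshold else "weak"


def relative_score(pwm: Pwm, window: str) -> float:
    """Min-max-normalized log-odds score of ``window`` against ``pwm``.

    raw = sum_i log2(p_i(base_i) / background(base_i)); the result is
    (raw - min_raw) / (max_raw - min_raw) over the per-position extrema of
    the same log-odds matrix, so the consensus scores exactly 1 and the
    anti-consensus exactly 0.  Windows containing N are undefined.
    """
    window = window.upper()
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != pwm width {pwm.width}"
        )
    lo = pwm.log_odds()
    try:
        idx = [_BASE_INDEX[b] for b in window]
    except KeyError as exc:
        raise ValueError(f"ambiguous base in window {window!r}") from exc
    raw = float(lo[np.arange(pwm.width), idx].sum())
    lo_min = float(lo.min(axis=1).sum())
    lo_max = float(lo.max(axis=1).sum())
    if lo_max == lo_min:
        return 1.0  # uninformative matrix: every window is "consensus"
    return (raw - lo_min) / (lo_max - lo_min)


def score_snp(
    pwm: Pwm,
    genome: dict[str, str],
    snp: Snp,
    report_threshold: float = REPORT_THRESHOLD,
    weak_threshold: float = WEAK_THRESHOLD,
) -> MotifHit | None:
    """Best allele-specific placement of ``pwm`` over ``snp``, if reportable.

    All width placements covering the SNP are enumerated on both strands
    (minus strand scores the reverse complement of the genomic window).
    The placement maximizing max(ref_score, alt_score) wins; ties break to
    the higher max score, then + strand, then smaller offset.  Returns
    None when no placement reaches ``report_threshold`` with
    |delta| >= ``weak_threshold``, or when no valid placement exists.
    """
    seq = genome[snp.chrom]
    if seq[snp.pos].upper() != snp.ref_allele:
        raise ValueError(
            f"reference allele mismatch for {snp.snp_id}: genome has "
            f"{seq[snp.pos]!r}, SNP says {snp.ref_allele!r}"
        )
    w = pwm.width
    candidates: list[tuple[tuple, MotifHit]] = []
    for start in range(snp.pos - w + 1, snp.pos + 1):
        if start < 0 or start + w > len(seq):
            continue  # placements truncated at contig ends
        ref_window = seq[start: start + w].upper()
        if any(b not in _BASE_INDEX for b in ref_window):
            continue  # N in window: placement skipped
        within = snp.pos - start
        alt_window = (
            ref_window[:within] + snp.alt_allele + ref_window[within + 1:]
        )
        for strand in ("+", "-"):
            if strand == "+":
                ref_s = relative_score(pwm, ref_window)
                alt_s = relative_score(pwm, alt_window)
                offset = within
            else:
                ref_s = relative_score(pwm, reverse_complement(ref_window))
                alt_s = relative_score(pwm, reverse_complement(alt_window))
                offset = w - 1 - within
            hit = MotifHit(
                snp_id=snp.snp_id,
                tf_name=pwm.tf_name,
                strand=strand,
                offset=offset,
                ref_score=ref_s,
                alt_score=alt_s,
            )
            # tie-break: higher max score, then + strand, then smaller offset
            candidates.append(
                ((-max(ref_s, alt_s), strand != "+", offset), hit)
            )
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[0])
    best = candidates[0][1]
    if max(best.ref_score, best.alt_score) < report_threshold:
        return None
    if abs(best.delta) < weak_threshold:
        return None
    return best


def scan_snps(
    pwms: list[Pwm],
    genome: dict[str, str],
    snps: list[Snp],
    report_threshold: float = REPORT_THRESHOLD,
    weak_threshold: float = WEAK_THRESHOLD,
) -> list[MotifHit]:
    """score_snp over every SNP x PWM, deterministically ordered."""
    hits = [
        h
        for snp in snps
        for pwm in pwms
        if (h := score_snp(pwm, genome, snp, report_threshold, weak_threshold))
    ]
    hits.sort(key=lambda h: (h.snp_id, h.tf_name, h.strand, h.offset))
    return hits


def filter_expressed(
    hits: list[MotifHit],
    expression: pd.DataFrame,
    cell_type: str,
    min_tpm: float = 1.0,
) -> list[MotifHit]:
    """Keep hits whose TF has TPM strictly above ``min_tpm`` in ``cell_type``.

    ``expression`` is indexed by gene/TF name with one column per cell
    type.  A TPM of exactly 1.0 is excluded; TFs absent from the table are
    dropped with a log message.
    """
    if cell_type not in expression.columns:
        raise KeyError(f"cell type {cell_type!r} not in expression table")
    kept = []
    for h in hits:
        if h.tf_name not in expression.index:
            logger.info("TF %s absent from expression table; hit dropped", h.tf_name)
            continue
        if float(expression.loc[h.tf_name, cell_type]) > min_tpm:
            kept.append(h)
    return kept


def write_motif_table(hits: list[MotifHit], path,
                      expressed_cell_types: dict | None = None) -> None:
    rows = [
        (
            h.snp_id, h.tf_name, h.strand, h.offset,
            f"{h.ref_score:.6f}", f"{h.alt_score:.6f}", f"{h.delta:+.6f}",
            h.direction, h.strength(),
            ";".join((expressed_cell_types or {}).get((h.snp_id, h.tf_name), [])),
        )
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=["snp", "tf", "strand", "offset", "ref_score", "alt_score",
                 "delta", "direction", "strength", "cell_types_expressed"],
    ).to_csv(path, sep="\t", index=False)
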