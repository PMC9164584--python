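"""Allele-specific PWM scanning and the TF expression filter."""

import numpy as np
import pandas as pd
import pytest

from v2g.genomic_core import BASES, Pwm, Snp, reverse_complement
from v2g.motif_disruption import (
    MotifHit,
    filter_expressed,
    relative_score,
    scan_snps,
    score_snp,
)


def random_pwm(rng, width=6, name="TF"):
    return Pwm(tf_name=name, matrix=rng.uniform(0.5, 50, size=(width, 4)))


def anti_consensus(pwm):
    lo = pwm.log_odds()
    return "".join(BASES[i] for i in np.argmin(lo, axis=1))


def consensus_of(pwm):
    lo = pwm.log_odds()
    return "".join(BASES[i] for i in np.argmax(lo, axis=1))


class TestRelativeScore:
    def test_consensus_scores_exactly_one_and_anti_zero(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng, width=int(rng.integers(4, 12)))
            assert relative_score(pwm, consensus_of(pwm)) == pytest.approx(1.0)
            assert relative_score(pwm, anti_consensus(pwm)) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_agrees_with_brute_force_log_odds(self, rng):
        for _ in range(100):
            width = int(rng.integers(4, 10))
            pwm = random_pwm(rng, width=width)
            window = "".join(rng.choice(list(BASES), size=width))
            probs = pwm.probabilities()
            raw = sum(
                np.log2(probs[i][BASES.index(b)] / 0.25)
                for i, b in enumerate(window)
            )
            lo = np.log2(probs / 0.25)
            lo_min = lo.min(axis=1).sum()
            lo_max = lo.max(axis=1).sum()
            expected = (raw - lo_min) / (lo_max - lo_min)
            assert relative_score(pwm, window) == pytest.approx(expected,
                                                                abs=1e-12)

    def test_n_in_window_is_rejected(self, rng):
        pwm = random_pwm(rng, width=4)
        with pytest.raises(ValueError):
            relative_score(pwm, "ACNT")


def brute_force_best(pwm, genome, snp):
    """Enumerate every (offset, strand) placement independently."""
    seq = genome[snp.chrom]
    w = pwm.width
    best = None
    for start in range(snp.pos - w + 1, snp.pos + 1):
        if start < 0 or start + w > len(seq):
            continue
        ref_win = seq[start: start + w]
        if any(b not in "ACGT" for b in ref_win):
            continue
        i = snp.pos - start
        alt_win = ref_win[:i] + snp.alt_allele + ref_win[i + 1:]
        for strand in ("+", "-"):
            if strand == "+":
                r = relative_score(pwm, ref_win)
                a = relative_score(pwm, alt_win)
                off = i
            else:
                r = relative_score(pwm, reverse_complement(ref_win))
                a = relative_score(pwm, reverse_complement(alt_win))
                off = w - 1 - i
            key = (-max(r, a), strand != "+", off)
            if best is None or key < best[0]:
                best = (key, r, a, strand, off)
    return best


class TestScoreSnp:
    def test_consensus_destruction_is_a_decrease(self, rng):
        pwm = Pwm(tf_name="T", matrix=np.array(
            [[97, 1, 1, 1]] * 4, dtype=float
        ))
        genome = {"chr1": "TTTTTAAAATTTTT"}
        snp = Snp("rs1", "chr1", 6, "A", "C")
        hit = score_snp(pwm, genome, snp)
        assert hit is not None
        assert hit.ref_score == pytest.approx(1.0)
        assert hit.alt_score < 1.0
        assert hit.direction == "decrease"

    def test_reference_mismatch_raises(self):
        pwm = Pwm(tf_name="T", matrix=np.ones((4, 4)))
        genome = {"chr1": "ACGTACGT"}
        with pytest.raises(ValueError, match="mismatch"):
            score_snp(pwm, genome, Snp("rs1", "chr1", 0, "G", "T"))

    def test_palindromic_pwm_ties_break_to_plus(self, rng):
        # A/T symmetric matrix, reverse-complement palindromic
        m = np.array([
            [40, 1, 1, 5], [5, 1, 1, 40], [40, 1, 1, 5], [5, 1, 1, 40],
        ], dtype=float)
        pwm = Pwm(tf_name="P", matrix=m)
        rc = pwm.reverse_complement()
        assert np.allclose(pwm.matrix, rc.matrix)
        genome = {"chr1": "GGGATATGGG"}
        hit = score_snp(pwm, genome, Snp("rs1", "chr1", 4, "T", "C"),
                        report_threshold=0.0, weak_threshold=0.0)
        assert hit.strand == "+"

    def test_matches_brute_force_enumeration(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=400))}
        for k in range(50):
            width = int(rng.integers(4, 11))
            pwm = random_pwm(rng, width=width, name=f"T{k}")
            pos = int(rng.integers(0, 400))
            ref = genome["chr1"][pos]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            snp = Snp(f"rs{k}", "chr1", pos, ref, alt)
            hit = score_snp(pwm, genome, snp, report_threshold=0.0,
                            weak_threshold=0.0)
            _, r, a, strand, off = brute_force_best(pwm, genome, snp)
            assert hit.ref_score == pytest.approx(r, abs=1e-12)
            assert hit.alt_score == pytest.approx(a, abs=1e-12)
            assert (hit.strand, hit.offset) == (strand, off)

    def test_strand_consistency_under_reverse_complement(self, rng):
        """Scoring the reverse-complemented genome with the
        reverse-complemented PWM reproduces the original scores."""
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=200))}
        L = 200
        for k in range(20):
            pwm = random_pwm(rng, width=6, name=f"T{k}")
            pos = int(rng.integers(10, 190))
            ref = genome["chr1"][pos]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            snp = Snp(f"rs{k}", "chr1", pos, ref, alt)
            hit = score_snp(pwm, genome, snp, report_threshold=0.0,
                            weak_threshold=0.0)
            genome_rc = {"chr1": reverse_complement(genome["chr1"])}
            snp_rc = Snp(
                f"rs{k}", "chr1", L - 1 - pos,
                reverse_complement(ref), reverse_complement(alt),
            )
            hit_rc = score_snp(pwm.reverse_complement(), genome_rc, snp_rc,
                               report_threshold=0.0, weak_threshold=0.0)
            assert hit_rc.ref_score == pytest.approx(hit.ref_score,
                                                     abs=1e-12)
            assert hit_rc.alt_score == pytest.approx(hit.alt_score,
                                                     abs=1e-12)

    def test_delta_antisymmetric_under_allele_swap(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=100))}
        pos = 50
        ref = genome["chr1"][pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        pwm = random_pwm(rng, width=7)
        hit = score_snp(pwm, genome, Snp("rs1", "chr1", pos, ref, alt),
                        report_threshold=0.0, weak_threshold=0.0)
        swapped_genome = {
            "chr1": genome["chr1"][:pos] + alt + genome["chr1"][pos + 1:]
        }
        hit_sw = score_snp(pwm, swapped_genome,
                           Snp("rs1", "chr1", pos, alt, ref),
                           report_threshold=0.0, weak_threshold=0.0)
        assert hit_sw.delta == pytest.approx(-hit.delta, abs=1e-12)

    def test_contig_end_truncates_placements(self, rng):
        pwm = random_pwm(rng, width=6)
        genome = {"chr1": "ACGTACGTAC"}
        snp = Snp("rs1", "chr1", 0, "A", "G")
        hit = score_snp(pwm, genome, snp, report_threshold=0.0,
                        weak_threshold=0.0)
        # only the start-anchored placement is valid
        _, r, a, strand, off = brute_force_best(pwm, genome, snp)
        assert hit is not None
        assert (hit.strand, hit.offset) == (strand, off)
        assert hit.offset in (0, pwm.width - 1)


class TestExpressionFilter:
    def _hits(self):
        return [
            MotifHit("rs1", "TF_A", "+", 0, 0.9, 0.5),
            MotifHit("rs1", "TF_B", "+", 0, 0.9, 0.5),
            MotifHit("rs1", "TF_C", "+", 0, 0.9, 0.5),
        ]

    def test_tpm_threshold_is_strict(self):
        expr = pd.DataFrame({"cellA": [1.0, 5.0, 0.2]},
                            index=["TF_A", "TF_B", "TF_C"])
        kept = filter_expressed(self._hits(), expr, "cellA", min_tpm=1.0)
        assert [h.tf_name for h in kept] == ["TF_B"]

    def test_missing_tf_is_dropped(self):
        expr = pd.DataFrame({"cellA": [5.0]}, index=["TF_A"])
        kept = filter_expressed(self._hits(), expr, "cellA")
        assert [h.tf_name for h in kept] == ["TF_A"]

    def test_empty_hits_stay_empty(self):
        expr = pd.DataFrame({"cellA": [5.0]}, index=["TF_A"])
        assert filter_expressed([], expr, "cellA") == []


class TestPlantedDisruptions:
    def test_all_planted_disruptions_recovered_with_direction(
        self, default_dataset
    ):
        ds = default_dataset
        snp_by_id = {s.snp_id: s for s in ds.panel.snps}
        planted_snps = sorted({t[0] for t in ds.ground_truth.disrupted_motifs})
        hits = scan_snps(ds.pwms, ds.genome,
                         [snp_by_id[s] for s in planted_snps])
        found = {(h.snp_id, h.tf_name, h.direction) for h in hits}
        assert ds.ground_truth.disrupted_motifs <= found
        planted_hits = [
            h for h in hits
            if (h.snp_id, h.tf_name, h.direction)
            in ds.ground_truth.disrupted_motifs
        ]
        assert all(h.strength() == "strong" for h in planted_hits)
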