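"""Restriction digestion, bait assignment, and the dual-resolution merge."""

import numpy as np
import pytest

from v2g.capture_design import (
    Interaction,
    assign_baits,
    concatenate_fragments,
    digest,
    merge_interactions,
)
from v2g.genomic_core import GeneModel, GenomicInterval, contains


def random_genome(rng, n_chroms=1, length=2000):
    return {
        f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n_chroms)
    }


class TestDigest:
    @pytest.mark.parametrize(
        "seq, fragments",
        [
            ("AAGATCAA", [(0, 2), (2, 8)]),
            ("GATCGATC", [(0, 4), (4, 8)]),  # leading zero-length dropped
            ("ACGTACGT", [(0, 8)]),  # no site: single fragment
        ],
    )
    def test_hand_enumerated_cuts(self, seq, fragments):
        rmap = digest({"chr1": seq})
        got = [(f.interval.start, f.interval.end) for f in rmap.fragments]
        assert got == fragments

    def test_ambiguous_bases_never_match(self):
        rmap = digest({"chr1": "AAGNTCAA"})
        assert len(rmap.fragments) == 1

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            digest({"chr1": ""})

    def test_fragments_reassemble_genome(self, rng):
        """Tiling invariant: concatenated fragment sequences reproduce the
        input byte-for-byte, on 100 random sequences."""
        for _ in range(100):
            genome = random_genome(rng, length=int(rng.integers(50, 800)))
            rmap = digest(genome)
            for chrom, seq in genome.items():
                frags = rmap.by_chrom(chrom)
                rebuilt = "".join(
                    seq[f.interval.start: f.interval.end] for f in frags
                )
                assert rebuilt == seq
                # no overlap, no gap
                bounds = [(f.interval.start, f.interval.end) for f in frags]
                assert bounds[0][0] == 0 and bounds[-1][1] == len(seq)
                assert all(a[1] == b[0] for a, b in zip(bounds, bounds[1:]))

    def test_median_fragment_length_tracks_site_density(self, rng):
        """GATC every ~256 bp on average gives ~250-bp median fragments."""
        seq = "".join(rng.choice(list("ACGT"), size=200_000))
        rmap = digest({"chr1": seq})
        widths = [f.interval.width for f in rmap.fragments]
        assert 120 < np.median(widths) < 400


class TestConcatenate:
    def test_nine_fragments_k4_gives_4_4_1(self):
        seq = "A" * 10 + ("GATC" + "A" * 6) * 8  # 9 fragments
        rmap = digest({"chr1": seq})
        assert len(rmap.fragments) == 9
        coarse = concatenate_fragments(rmap, k=4)
        sizes = [f.interval.width for f in coarse.fragments]
        assert len(sizes) == 3
        assert coarse.fragments[-1].interval.end == len(seq)

    def test_k1_is_identity(self, rng):
        rmap = digest(random_genome(rng, length=500))
        same = concatenate_fragments(rmap, k=1)
        assert [f.interval for f in same.fragments] == [
            f.interval for f in rmap.fragments
        ]

    def test_coarse_bins_tile_exactly_like_fine(self, rng):
        for _ in range(20):
            genome = random_genome(rng, length=int(rng.integers(100, 2000)))
            rmap = digest(genome)
            coarse = concatenate_fragments(rmap, k=4)
            for chrom, seq in genome.items():
                covered = np.zeros(len(seq), dtype=int)
                for f in coarse.by_chrom(chrom):
                    covered[f.interval.start: f.interval.end] += 1
                assert (covered == 1).all()


class TestAssignBaits:
    def _rmap_from_bounds(self, bounds, length):
        # synthetic fragment map built directly from cut positions
        seq_parts = []
        prev = 0
        genome = {"chr1": None}
        # construct a sequence whose GATC occurrences sit at the bounds
        s = list("A" * length)
        for b in bounds:
            s[b: b + 4] = list("GATC")
        genome["chr1"] = "".join(s)
        return digest(genome)

    def test_window_overlap_rule(self):
        rmap = self._rmap_from_bounds([900, 1200], 2000)
        got = [(f.interval.start, f.interval.end) for f in rmap.fragments]
        assert got == [(0, 900), (900, 1200), (1200, 2000)]
        gene = GeneModel("G1", "GENE1", "chr1", "+", 1000)
        baits = assign_baits(rmap, [gene])
        # clipped promoter window [0, 1500) overlaps all three fragments
        assert sorted(baits.entries) == [0, 1, 2]
        assert all(baits.entries[i] == {"G1"} for i in baits.entries)

    def test_shared_tss_genes_share_baits(self):
        rmap = self._rmap_from_bounds([900, 1200], 2000)
        genes = [
            GeneModel("G1", "A", "chr1", "+", 1000),
            GeneModel("G2", "B", "chr1", "+", 1000),
        ]
        baits = assign_baits(rmap, genes)
        assert all(v == {"G1", "G2"} for v in baits.entries.values())

    def test_unknown_chromosome_names_gene(self):
        rmap = self._rmap_from_bounds([900], 2000)
        with pytest.raises(ValueError, match="GX"):
            assign_baits(rmap, [GeneModel("GX", "X", "chrZ", "+", 100)])


def _brute_force_merge(ones, fours, min_score):
    """Independent oracle: explicit redundancy graph + exhaustive grouping."""
    recs = [r for r in ones + fours if r.score > min_score]
    # collapse exact duplicates first
    uniq = {}
    for r in recs:
        k = (r.bait, r.bait_genes, r.other_end, r.resolution)
        if k not in uniq or r.score > uniq[k].score:
            uniq[k] = r
    recs = list(uniq.values())
    n = len(recs)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            a, b = recs[i], recs[j]
            if (a.resolution == "1frag" and b.resolution == "4frag"
                    and (a.bait_genes & b.bait_genes)
                    and contains(b.other_end, a.other_end)):
                adj[i].add(j)
                adj[j].add(i)
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        groups.append([recs[k] for k in comp])
    out = set()
    for g in groups:
        finest = min(g, key=lambda r: (r.other_end.width, r.other_end.start))
        out.add((finest.other_end, max(r.score for r in g)))
    return out


class TestMergeInteractions:
    def _mk(self, start, width, genes, score, resolution, bait_start=0):
        return Interaction(
            bait=GenomicInterval("chr1", bait_start, bait_start + 100),
            bait_genes=frozenset(genes),
            other_end=GenomicInterval("chr1", start, start + width),
            score=score,
            resolution=resolution,
        )

    def test_exact_duplicates_keep_max_score(self):
        a = self._mk(1000, 250, {"G1"}, 5.5, "1frag")
        b = self._mk(1000, 250, {"G1"}, 7.2, "1frag")
        (merged,) = merge_interactions([a, b], [])
        assert merged.score == 7.2

    def test_score_exactly_five_is_dropped(self):
        a = self._mk(1000, 250, {"G1"}, 5.0, "1frag")
        assert merge_interactions([a], []) == []

    def test_nested_other_end_keeps_finest_coordinates_and_max_score(self):
        one = self._mk(1000, 250, {"G1"}, 6.0, "1frag")
        four = self._mk(800, 1000, {"G1"}, 9.0, "4frag")
        (merged,) = merge_interactions([one], [four])
        assert (merged.other_end.start, merged.other_end.end) == (1000, 1250)
        assert merged.score == 9.0
        assert merged.resolution == "1frag+4frag"

    def test_different_bait_genes_do_not_merge(self):
        one = self._mk(1000, 250, {"G1"}, 6.0, "1frag")
        four = self._mk(800, 1000, {"G2"}, 9.0, "4frag")
        assert len(merge_interactions([one], [four])) == 2

    def test_idempotent_and_matches_brute_force(self, rng):
        ones, fours = [], []
        for _ in range(120):
            start = int(rng.integers(0, 3000))
            ones.append(self._mk(
                start, 250, {f"G{int(rng.integers(5))}"},
                float(np.round(rng.uniform(0, 12), 2)), "1frag",
            ))
        for _ in range(80):
            start = int(rng.integers(0, 3000))
            fours.append(self._mk(
                start, 1000, {f"G{int(rng.integers(5))}"},
                float(np.round(rng.uniform(0, 12), 2)), "4frag",
            ))
        merged = merge_interactions(ones, fours)
        assert all(r.score > 5 for r in merged)
        got = {(r.other_end, r.score) for r in merged}
        assert got == _brute_force_merge(ones, fours, 5.0)
        # idempotence: feed the merged set back through
        again = merge_interactions(merged, [])
        assert {(r.other_end, r.score) for r in again} == got
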