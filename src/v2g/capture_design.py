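"""In-silico restriction capture design and interaction merging.

DpnII (GATC) digestion yields the fragment resolution of the capture assay:
fragments tile each chromosome exactly, cut at the 5' start of every
recognition-site occurrence.  Fragments containing gene promoters become
capture baits.  Interaction calls at 1-fragment and coarsened 4-fragment
resolution are merged, keeping only significant contacts (score strictly
above 5 by default) and collapsing redundant calls to the finest
coordinates with the maximum score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .genomic_core import GenomicInterval, GeneModel, contains, overlaps

logger = logging.getLogger("v2g")

DPNII_SITE = "GATC"


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment; ``frag_id`` is consecutive per chromosome."""

    frag_id: int
    interval: GenomicInterval


@dataclass
class FragmentMap:
    """Restriction fragments tiling a genome (the CHiCAGO ``rmap``)."""

    fragments: list[Fragment]
    chrom_lengths: dict[str, int]

    def by_chrom(self, chrom: str) -> list[Fragment]:
        return [f for f in self.fragments if f.interval.chrom == chrom]

    def fragment_at(self, chrom: str, pos: int) -> Fragment | None:
        """The fragment containing ``pos`` (0-based), or None."""
        for f in self.fragments:
            iv = f.interval
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return f
        return None


@dataclass
class BaitMap:
    """frag_id -> set of gene_ids whose promoter window the fragment overlaps."""

    entries: dict[int, set[str]] = field(default_factory=dict)

    def genes_for(self, frag_id: int) -> set[str]:
        return self.entries.get(frag_id, set())


@dataclass(frozen=True)
class Interaction:
    """A promoter-capture contact between a bait fragment and an other end.

    ``score`` is the CHiCAGO-like significance score (consumed, never
    computed, here); ``resolution`` tags the fragment binning of the call
    ("1frag", "4frag", or "1frag+4frag" after a merge).
    """

    bait: GenomicInterval
    bait_genes: frozenset[str]
    other_end: GenomicInterval
    score: float
    resolution: str = "1frag"
    n_reads: int = 0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")


def digest(genome: dict[str, str], site: str = DPNII_SITE) -> FragmentMap:
    """In-silico digest: cut at the 0-based start of every site occurrence.

    Overlapping occurrences are allowed; ambiguous bases (N) never match.
    Fragments are the half-open spans between consecutive cuts plus the
    leading and trailing spans; zero-length fragments are dropped, so the
    surviving fragments tile ``[0, L)`` exactly.
    """
    if not site:
        raise ValueError("site must be non-empty")
    site = site.upper()
    fragments: list[Fragment] = []
    chrom_lengths: dict[str, int] = {}
    frag_id = 0
    for chrom, seq in genome.items():
        if not seq:
            raise ValueError(f"empty sequence for {chrom}")
        seq = seq.upper()
        L = len(seq)
        chrom_lengths[chrom] = L
        cuts = []
        start = 0
        while True:
            hit = seq.find(site, start)
            if hit == -1:
                break
            cuts.append(hit)
            start = hit + 1  # allow overlapping occurrences
        bounds = [0] + cuts + [L]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                fragments.append(
                    Fragment(frag_id=frag_id, interval=GenomicInterval(chrom, a, b))
                )
                frag_id += 1
    return FragmentMap(fragments=fragments, chrom_lengths=chrom_lengths)


def concatenate_fragments(rmap: FragmentMap, k: int = 4) -> FragmentMap:
    """Merge runs of ``k`` consecutive fragments into coarse bins.

    Binning starts from the first fragment of each chromosome; a trailing
    remainder of fewer than ``k`` fragments forms a final shorter bin, so
    the tiling invariant is preserved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[Fragment] = []
    frag_id = 0
    for chrom in rmap.chrom_lengths:
        frags = rmap.by_chrom(chrom)
        for i in range(0, len(frags), k):
            run = frags[i : i + k]
            out.append(
                Fragment(
                    frag_id=frag_id,
                    interval=GenomicInterval(
                        chrom, run[0].interval.start, run[-1].interval.end
                    ),
                )
            )
            frag_id += 1
    return FragmentMap(fragments=out, chrom_lengths=dict(rmap.chrom_lengths))


def assign_baits(
    rmap: FragmentMap,
    genes: list[GeneModel],
    window_up: int = 1500,
    window_down: int = 500,
) -> BaitMap:
    """Bait every fragment overlapping a gene's promoter window.

    The window is the strand-aware -window_up/+window_down span around the
    TSS (see :func:`v2g.v2g_mapping.promoter_window`); one fragment may bait
    several genes.
    """
    from .v2g_mapping import promoter_window

    unknown = [g.gene_id for g in genes if g.chrom not in rmap.chrom_lengths]
    if unknown:
        raise ValueError(f"genes on undigested chromosomes: {unknown}")
    baitmap = BaitMap()
    for g in genes:
        win = promoter_window(
            g, up=window_up, down=window_down,
            chrom_length=rmap.chrom_lengths[g.chrom],
        )
        hit = False
        for frag in rmap.by_chrom(g.chrom):
            if overlaps(frag.interval, win.interval):
                baitmap.entries.setdefault(frag.frag_id, set()).add(g.gene_id)
                hit = True
        if not hit:
            raise RuntimeError(
                f"promoter window of {g.gene_id} overlaps no fragment "
                "(tiling violated)"
            )
    return baitmap


def _collapse_exact_duplicates(records: list[Interaction]) -> list[Interaction]:
    """Within one resolution, identical bait/other_end records keep max score."""
    best: dict[tuple, Interaction] = {}
    for r in records:
        key = (r.bait, r.bait_genes, r.other_end, r.resolution)
        if key not in best or r.score > best[key].score:
            best[key] = r
    return list(best.values())


def merge_interactions(
    calls_1frag: list[Interaction],
    calls_4frag: list[Interaction],
    min_score: float = 5.0,
) -> list[Interaction]:
    """Merge dual-resolution interaction calls into one significant set.

    1. Records with score <= ``min_score`` are dropped (strict ``> 5``:
       a score of exactly 5.0 is not significant).
    2. A 1-frag and a 4-frag record are redundant iff they share at least
       one bait gene and the 1-frag other end lies entirely within the
       4-frag other-end span.  Redundancy groups are connected components
       of that relation; each group keeps a single record with the maximum
       score over the group, the finest (smallest-span) member's
       coordinates, and a resolution tag recording both sources.
    3. Exact duplicates within a resolution collapse to the max score.
    """
    for r in list(calls_1frag) + list(calls_4frag):
        if not r.bait_genes:
            raise ValueError(f"interaction with undefined bait_genes: {r}")

    ones = _collapse_exact_duplicates(
        [r for r in calls_1frag if r.score > min_score]
    )
    fours = _collapse_exact_duplicates(
        [r for r in calls_4frag if r.score > min_score]
    )

    # union-find over the combined record list
    records = ones + fours
    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    n1 = len(ones)
    for i, one in enumerate(ones):
        for j, four in enumerate(fours, start=n1):
            if (one.bait_genes & four.bait_genes) and contains(
                four.other_end, one.other_end
            ):
                union(i, j)

    groups: dict[int, list[Interaction]] = {}
    for i, r in enumerate(records):
        groups.setdefault(find(i), []).append(r)

    merged: list[Interaction] = []
    for members in groups.values():
        finest = min(members, key=lambda r: (r.other_end.width, r.other_end.start))
        score = max(r.score for r in members)
        resolutions = sorted({r.resolution for r in members})
        genes = frozenset().union(*(r.bait_genes for r in members))
        merged.append(
            replace(
                finest,
                score=score,
                bait_genes=genes,
                resolution="+".join(resolutions),
            )
        )
    merged.sort(
        key=lambda r: (r.bait.chrom, r.bait.start, r.other_end.start, sorted(r.bait_genes))
    )
    return merged


# ---------------------------------------------------------------------------
# rmap / baitmap files (CHiCAGO convention)
# ---------------------------------------------------------------------------


def write_rmap(rmap: FragmentMap, path) -> None:
    with open(path, "w") as fh:
        for f in rmap.fragments:
            iv = f.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.frag_id}\n")


def write_baitmap(rmap: FragmentMap, baitmap: BaitMap, path) -> None:
    frag_by_id = {f.frag_id: f for f in rmap.fragments}
    with open(path, "w") as fh:
        for frag_id in sorted(baitmap.entries):
            iv = frag_by_id[frag_id].interval
            genes = ";".join(sorted(baitmap.entries[frag_id]))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{frag_id}\t{genes}\n")
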