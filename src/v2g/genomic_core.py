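"""Coordinate conventions, interval algebra, and file I/O.

Every genomic coordinate inside the package is 0-based half-open
(BED-native).  Formats that use 1-based coordinates (VCF) are converted
exactly once, at the I/O boundary.  Chromosome names are matched as exact
strings; no "chr"-prefix normalization is attempted, but helpers warn when
two inputs share zero chromosome names.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("v2g")

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is carried for promoter-window construction but ignored by
    :func:`overlaps`, matching the GenomicRanges ``ignore.strand`` default
    for overlap queries.
    """

    chrom: str
    start: int
    end: int
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; strand is ignored.

    True iff the two spans share a chromosome and at least one base:
    ``a.start < b.end and b.start < a.end``.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies entirely within ``outer`` (same chromosome)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class Snp:
    """A biallelic single-nucleotide variant; ``pos`` is 0-based."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for a in (self.ref_allele, self.alt_allele):
            if a not in BASES:
                raise ValueError(f"allele must be one of {BASES}, got {a!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def interval(self) -> GenomicInterval:
        """The SNP as a 1-bp half-open interval, for intersection."""
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)


@dataclass
class OcrSet:
    """Open chromatin regions for one cell type, with stable OCR ids."""

    cell_type: str
    intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    def add(self, interval: GenomicInterval, ocr_id: str | None = None) -> str:
        if interval.width <= 0:
            raise ValueError(f"zero-length OCR {interval}")
        if ocr_id is None:
            ocr_id = str(interval)
        if ocr_id in self.intervals:
            raise ValueError(f"duplicate OCR id {ocr_id!r}")
        self.intervals[ocr_id] = interval
        return ocr_id

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals.items())


@dataclass
class Pwm:
    """A position frequency matrix over A/C/G/T with JASPAR-style counts.

    ``matrix`` holds raw counts (or probabilities), shape (width, 4) in
    A,C,G,T order.  ``probabilities()`` normalizes each position to a
    probability vector after adding ``pseudocount`` split by ``background``
    (the common PWM convention: p = (c + pseudo*bg) / (N + pseudo)).
    """

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (width, 4)")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def probabilities(self) -> np.ndarray:
        """Column-stochastic (width, 4) matrix after pseudocount smoothing."""
        totals = self.matrix.sum(axis=1, keepdims=True)
        # degenerate all-zero column: fall back to background
        totals = np.where(totals == 0, 1.0, totals)
        probs = (self.matrix + self.pseudocount * self.background) / (
            totals + self.pseudocount
        )
        return probs / probs.sum(axis=1, keepdims=True)

    def log_odds(self) -> np.ndarray:
        """log2(p / background), shape (width, 4)."""
        return np.log2(self.probabilities() / self.background)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            tf_name=self.tf_name,
            matrix=self.matrix[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, cell_type: str = "") -> OcrSet:
    """Read a BED3/BED4 file into an :class:`OcrSet`.

    BED coordinates are already 0-based half-open and are preserved as-is.
    The 4th column, when present, becomes the OCR id; otherwise ids are
    ``chrom:start-end``.  Exact duplicate intervals are collapsed with a
    warning (the field's peak callers should not emit them, but input
    hygiene is not assumed).
    """
    ocrs = OcrSet(cell_type=cell_type)
    seen: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ParseError(
                    f"{path}:{lineno}: zero-length or inverted interval "
                    f"[{start}, {end})"
                )
            key = (chrom, start, end)
            if key in seen:
                logger.warning("%s:%d: duplicate interval %s collapsed", path, lineno, key)
                continue
            seen.add(key)
            ocr_id = fields[3] if len(fields) >= 4 and fields[3] else None
            ocrs.add(GenomicInterval(chrom, start, end), ocr_id)
    return ocrs


def write_bed(ocrs: OcrSet, path) -> None:
    with open(path, "w") as fh:
        for ocr_id, iv in ocrs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ocr_id}\n")


# ---------------------------------------------------------------------------
# ibed (CHiCAGO export dialect)
# ---------------------------------------------------------------------------

IBED_COLUMNS = [
    "bait_chr", "bait_start", "bait_end", "bait_name",
    "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_name",
    "N_reads", "score",
]


def read_ibed(path) -> list:
    """Read CHiCAGO-style .ibed records into a list of Interaction.

    The bait name carries semicolon-separated gene annotation(s).  The
    resolution tag is taken from an optional 11th ``resolution`` column and
    defaults to ``1frag``.
    """
    from .capture_design import Interaction  # local import to avoid a cycle

    out: list[Interaction] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "score" not in header:
            raise ParseError(f"{path}: missing score column in header")
        idx = {name: i for i, name in enumerate(header)}
        for col in IBED_COLUMNS:
            if col not in idx:
                raise ParseError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                score = float(fields[idx["score"]])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad score") from exc
            if score < 0:
                raise ParseError(f"{path}:{lineno}: negative score {score}")
            bait = GenomicInterval(
                fields[idx["bait_chr"]],
                int(fields[idx["bait_start"]]),
                int(fields[idx["bait_end"]]),
            )
            other = GenomicInterval(
                fields[idx["otherEnd_chr"]],
                int(fields[idx["otherEnd_start"]]),
                int(fields[idx["otherEnd_end"]]),
            )
            genes = frozenset(
                g for g in fields[idx["bait_name"]].split(";") if g and g != "."
            )
            resolution = (
                fields[idx["resolution"]] if "resolution" in idx else "1frag"
            )
            out.append(
                Interaction(
                    bait=bait,
                    bait_genes=genes,
                    other_end=other,
                    score=score,
                    resolution=resolution,
                    n_reads=int(fields[idx["N_reads"]]),
                )
            )
    return out


def write_ibed(interactions, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(IBED_COLUMNS + ["resolution"]) + "\n")
        for x in interactions:
            fh.write(
                "\t".join(
                    [
                        x.bait.chrom, str(x.bait.start), str(x.bait.end),
                        ";".join(sorted(x.bait_genes)) or ".",
                        x.other_end.chrom, str(x.other_end.start),
                        str(x.other_end.end), ".",
                        str(x.n_reads), repr(x.score), x.resolution,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------


def read_jaspar(path, pseudocount: float = 0.8) -> list[Pwm]:
    """Parse JASPAR text PFMs (``>ID NAME`` then four ``A [ ... ]`` rows)."""
    pwms: list[Pwm] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ParseError(f"{path}: expected '>' header at line {i + 1}")
        header = lines[i][1:].strip().split()
        name = header[-1] if header else f"pwm{len(pwms)}"
        rows = {}
        for j in range(4):
            if i + 1 + j >= len(lines):
                raise ParseError(f"{path}: truncated matrix for {name}")
            row = lines[i + 1 + j]
            base = row.strip()[0].upper()
            nums = row[row.index("[") + 1: row.rindex("]")].split() \
                if "[" in row else row.split()[1:]
            rows[base] = [float(x) for x in nums]
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1 or set(rows) != set(BASES):
            raise ParseError(f"{path}: rows of unequal width for {name}")
        matrix = np.array([[rows[b][k] for b in BASES] for k in range(widths.pop())])
        pwms.append(Pwm(tf_name=name, matrix=matrix, pseudocount=pseudocount))
        i += 5
    return pwms


def write_jaspar(pwms: list[Pwm], path) -> None:
    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    with open(path, "w") as fh:
        for k, pwm in enumerate(pwms):
            fh.write(f">M{k:04d} {pwm.tf_name}\n")
            for bi, base in enumerate(BASES):
                nums = " ".join(fmt(v) for v in pwm.matrix[:, bi])
                fh.write(f"{base} [ {nums} ]\n")


# ---------------------------------------------------------------------------
# FASTA, gene models, tables
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


GENE_COLUMNS = ["gene_id", "gene_name", "chrom", "strand", "tss", "biotype"]


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing gene-model columns {sorted(missing)}")
    return [
        GeneModel(
            gene_id=row.gene_id,
            gene_name=row.gene_name,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss),
            biotype=getattr(row, "biotype", "protein_coding"),
        )
        for row in df.itertuples(index=False)
    ]


def write_gene_models(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.gene_name, g.chrom, g.strand, g.tss, g.biotype)
            for g in genes
        ],
        columns=GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def check_shared_chromosomes(a, b, what: str = "inputs") -> None:
    """Warn when two chromosome-name collections are disjoint.

    Exact-string matching means a chr1/1 naming mismatch silently yields
    zero overlaps; this guard makes that loud without renaming anything.
    """
    a, b = set(a), set(b)
    if a and b and not (a & b):
        warnings.warn(
            f"{what} share zero chromosome names "
            f"({sorted(a)[:3]}... vs {sorted(b)[:3]}...)",
            stacklevel=2,
        )
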