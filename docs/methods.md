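# Methods

This note documents the models and estimators the package implements, the
parameters that matter, the synthetic-data generator's assumptions, and
the numerical choices made where the design was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED-native); 1-based
formats (VCF) are converted exactly once at parse time. Overlap queries
ignore strand, matching the common convention of genomic-ranges libraries;
strand is consumed only by promoter-window construction. Chromosome names
are matched as exact strings — no `chr` normalization — with a warning
when two inputs share no chromosome names, because silent renaming hides
data errors. The ibed dialect is the CHiCAGO export header
(`bait_chr … N_reads score`), with an optional trailing `resolution`
column used by this package's writer.

## Capture design

**Digestion.** DpnII cuts are placed at the 0-based start of every GATC
occurrence (overlapping occurrences allowed; `N` never matches). Any
consistent cut offset yields an equivalent fragment tiling; start-of-site
matches common in-silico four-cutter digests. Zero-length fragments are
dropped, so fragments partition each chromosome exactly — a property the
test suite checks by reassembling random genomes byte-for-byte.

**4-fragment concatenation** groups runs of four consecutive fragments per
chromosome from the first fragment; a short trailing bin preserves the
tiling.

**Bait assignment.** A fragment baits gene *g* iff it overlaps *g*'s
promoter window: −1500/+500 bp of the TSS on the plus strand, reflected
through the TSS on the minus strand ([TSS−499, TSS+1501)), clipped at
chromosome bounds (clipping is logged). Strand-aware reflection is the
natural reading of "upstream/downstream"; a `strand_aware=False` caller
can simply construct plus-strand windows for every gene.

**Merge.** Records at score ≤ 5 are dropped first (strictly greater than
5: 5.0 exactly is not significant). A 1-fragment and a 4-fragment call are
redundant iff they share a bait gene and the 1-fragment other end is
nested in the 4-fragment other end — nesting is the only relationship the
two resolutions can have by construction, since the coarse map is a
concatenation of the fine one. Redundancy groups are connected components
of that relation; the merged record takes the finest member's coordinates,
the group's maximum score, the union of bait genes, and a tag naming both
resolutions. The merge is idempotent and is tested against a brute-force
grouping oracle. Overlapping 4-fragment records with distinct bait
fragments for the same gene are *not* collapsed.

## LD proxies

r² is computed by haplotype counting, r² = D²/(p_A q_A p_B q_B) with
D = p_AB − p_A p_B, equal to the squared Pearson correlation of the 0/1
allele columns (used as an independent oracle in tests). Proxy expansion
keeps SNPs with r² strictly above 0.8 within ±500 kb of the sentinel
(500 kb is the common default of LD-proxy web services and is
configurable); the sentinel itself is always element 0 at r² = 1.
Monomorphic columns have undefined LD and are skipped; multi-allelic VCF
records are excluded at parse time with a logged count. The panel is
assumed pre-subset to the analysis population.

## Variant-to-gene mapping

SNPs intersect OCRs as 1-bp half-open intervals (indels are out of scope).
An accessible proxy implicates gene *g* in promoter mode when its OCR
overlaps *g*'s promoter window, and in PIR mode when the OCR overlaps the
other end of a merged significant interaction with *g* among its bait
genes; one proxy may implicate several genes and both modes, and the
sentinel participates like any proxy. The promoter-window OCR is not
required to be a baited fragment — only window overlap is required. Per
gene × cell type, records collapse to promoter / distal / both / none.
Sentinels whose proxies hit no OCR simply produce no records.

## Partitioned heritability

A deliberately simplified stratified LD-score regression, sized for a
desk-scale panel:

- **LD scores.** ℓ(j,c) = Σₖ r̃²(j,k)·a_kc over same-chromosome SNPs
  within a fixed window (default 100 kb — the toy genome has no
  centimorgan map), with the finite-sample bias correction
  r̃² = r² − (1−r²)/(n_hap−2) and the self term included.
- **Regression.** χ²_j on {N·ℓ(j,c)} with a free intercept (a flag can fix
  it at 1). The fit is two-step weighted least squares: step 1 uses
  oversampling weights 1/max(1, ℓ_base)²; step 2 multiplies in the
  heteroskedasticity factor 1/μ̂_j², with μ̂_j the step-1 fitted mean —
  the sampling variance of a χ² statistic grows as the square of its mean,
  and without this factor the handful of strongly associated SNPs drown
  the base coefficient, biasing enrichment toward 1. With the two-step
  weights the planted 10-fold enrichment is recovered essentially
  unbiased (jackknife CI coverage 20/20 in the replication experiment the
  acceptance script re-runs).
- **Enrichment.** Per-SNP heritability h²_j = Σ_c τ̂_c a_jc;
  h²(C) = Σ_{j∈C} h²_j; enrichment(C) = (h²(C)/h²_total)/(M_C/M). The
  base category (all SNPs) therefore has enrichment identically 1.
- **Uncertainty.** Delete-one-block jackknife over contiguous equal-count
  SNP blocks, default 20 (a 400-SNP panel cannot support the genome-scale
  default of 200 blocks); se = √((B−1)/B Σ(θ_b−θ̄)²), CI = point ± 1.96 se,
  two-sided normal p for H₀: enrichment = 1, Benjamini–Hochberg FDR across
  exactly the categories tested in one run. No MAF-stratified baseline
  model is fitted, and per-SNP weighting inside a category is equal.

## Expression vs contact

A gene is contacted when at least one OCR overlaps the other end of a
significant interaction baited at its promoter or overlaps the promoter
window itself (`distal_only` restricts to the former); the complementary
OCR-level split (promoter-contacting vs not) is also reported. TPM zeros
are legitimate values, not missing data. The two-sided Wilcoxon rank-sum
test uses midranks for ties; with combined n ≤ 20 the p-value is exact
over all C(n₁+n₂, n₁) labelings, computed by a subset-sum convolution
over doubled midranks (integer-exact and equivalent to full enumeration);
beyond that, a tie-corrected normal approximation with continuity
correction. The exact cutoff of 20 keeps enumeration cheap while covering
every group size where the normal approximation is still rough.

## Motif disruption

PWMs are JASPAR count matrices; probabilities add a pseudocount (default
0.8, split by the background, default uniform 0.25). The relative score of
a window is the min–max-normalized log₂-odds sum, so the consensus scores
exactly 1 and the anti-consensus exactly 0; relative scoring was chosen
over p-value scoring as the simpler, threshold-friendly convention.
`score_snp` enumerates every placement covering the SNP on both strands
(minus strand scores the reverse complement), keeps the placement
maximizing max(ref, alt) — ties break to the higher max, then the plus
strand, then the smaller offset — and reports a hit when that max reaches
the report threshold (0.85) with |Δ| ≥ the weak threshold (0.04);
|Δ| ≥ 0.10 is "strong". All three thresholds are exposed as flags.
Expressed-TF filtering is strictly TPM > 1 in the implicated cell type.

## The synthetic-data generator

The generator emulates the statistical structure of the study inputs, not
their biology, and every emitted byte is a pure function of the
`SimulationConfig` (seed included).

- **Genome** (default 2 × 500 kb): i.i.d. nucleotides scrubbed of
  accidental GATC, then GATC planted at Poisson-spaced positions (default
  4/kb, giving ~250 bp fragments, the resolution a four-cutter design
  targets). Planting over a scrubbed background cannot create overlapping
  occurrences, so the realized site count is exactly the Poisson draw.
  60 genes with alternating strands and jittered, non-overlapping 2-kb
  promoters.
- **Haplotypes** (default 200 haplotypes, 200 SNPs and 10 blocks per
  chromosome): within a block every haplotype copies a founder state with
  per-SNP flip probability ε solving (1−2ε)⁴ = target r² (default 0.95);
  across blocks, independent; MAF ≥ 0.05 by resampling. Block sizes
  deliberately vary (≈0.6–1.4× the mean) so per-block LD scores differ —
  constant block sizes make the base LD-score column collinear with the
  intercept. Planted blocks are re-drawn until each planted proxy's sample
  r² with its sentinel clears 0.85, so planted implications are
  recoverable by construction; a coalescent simulator would add realism
  the correctness tests do not need.
- **Regulatory landscape** (3 cell types): each of the 12 planted
  implications places an OCR (width ~N(575, 100), truncated; the observed
  scale of ATAC peaks) over a proxy — inside the target gene's promoter
  window for promoter mode, at a distal fragment plus a scored interaction
  (score U(5.5, 15)) to the gene's bait for PIR mode, with some
  interactions also emitted at 4-fragment resolution to exercise the
  merge. Negatives: ≥50 SNP-free decoy OCRs, sub-threshold interactions
  (U(0.5, 4.9)) including some from genuinely accessible fragments to
  wrong genes, and per-cell background promoter contacts whose OCRs
  contain no SNPs (they enlarge the contacted-gene set for the expression
  comparison without touching V2G). Placement keeps background fragments a
  full OCR-reach away from every SNP so negatives cannot leak into the
  record set.
- **GWAS** (default N = 10 000, h² = 0.4): per block with sample LD matrix
  R (shrunk toward identity if not positive definite, λ = 0.01, logged),
  β ~ N(0, diag(v)), z = √N·R·β + e with e ~ N(0, R), χ² = z² — so
  E[χ²_j] = 1 + N Σ_c τ_c ℓ(j,c) holds by construction, the exact identity
  the heritability stage recovers. The enriched category (10% of SNPs,
  10-fold) is planted block-clustered (~35% of a subset of blocks), the
  way regulatory annotations actually distribute; uniform placement would
  make the enriched LD-score column proportional to the base column and
  the enrichment unidentifiable.
- **Expression**: log-normal TPMs (σ = 1), non-contacted median 1.2,
  contacted genes shifted by the planted fold (default 10), 15% of
  non-contacted genes at TPM 0.
- **Motifs**: sharply peaked width-8 PWMs (counts 97/1/1/1 per position);
  planted disruptions write the consensus (or a one-base-off consensus)
  into the genome at chosen accessible proxies so that the reference or
  alternate allele completes it, giving |Δ| = 1/8 of the score range —
  a strong hit by construction. Planted TFs are expressed (TPM 5–50);
  decoys sit below 1.

**What passing tests do and do not show.** The generator has rectangular
LD blocks, no allele-frequency–dependent architecture, no centimorgan
map, and planted effects that are large relative to real GWAS; exact
precision/recall on it demonstrates the correctness of the interval
logic, the LD algebra, the merge semantics and the estimators — not the
biological error rate of the approach on real data, which depends on LD
panel quality, peak calling, and capture library design that are outside
this package's scope.

## Problem sizes

Defaults were chosen so the full pipeline (generation, mapping, merging,
heritability with jackknife, expression comparison, motif scan) completes
in seconds on one CPU: 1 Mb genome, 400 SNPs, 200 haplotypes, 60 genes,
3 cell types, 20 jackknife blocks, 20 replicates in the recovery
experiments. All are configurable upward.

## Known limitations

- The heritability module is not a drop-in for genome-scale stratified
  LD-score regression: no baseline-LD model, fixed-bp windows, equal
  per-SNP weights inside categories, 20 jackknife blocks.
- Indels, multi-allelic variants and strand-ambiguous alleles are out of
  scope throughout.
- The merge collapses across resolutions only; two overlapping same-
  resolution calls with different bait fragments are kept distinct.
- The exact rank-sum path is quadratic in the doubled-rank total and is
  capped at combined n = 20 by default.
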