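# v2g — chromatin-based variant-to-gene mapping

Most disease-associated GWAS variants are non-coding and act through
*cis*-regulatory elements, often at a distance from the genes they control.
`v2g` implements a chromatin-based variant-to-gene (V2G) mapping pipeline
for that setting, built around three data layers:

1. **LD proxy expansion** — each GWAS sentinel SNP is expanded into the set
   of panel SNPs with r² > 0.8 within ±500 kb, computed from phased
   haplotypes (r² = D²/(p_A q_A p_B q_B)).
2. **Open chromatin** — ATAC-seq open chromatin regions (OCRs) per cell
   type, consumed as BED.
3. **Promoter-capture chromatin contacts** — CHiCAGO-scored interactions
   from a DpnII (GATC) promoter-capture design, at 1-fragment and
   4-fragment resolution, merged into one significant set (score strictly
   > 5, redundant dual-resolution calls collapsed to the finest
   coordinates at the maximum score).

A proxy that falls inside an OCR implicates gene *g* in cell type *c*
either in **promoter** mode (the OCR overlaps *g*'s promoter window,
−1500/+500 bp of the TSS, strand-aware) or in **PIR** mode (the OCR
overlaps the other end of a significant interaction baited at *g*'s
promoter). Per gene × cell type the calls collapse to
promoter / distal / both / none.

Around the core mapping the package provides:

- **Partitioned heritability** — simplified stratified LD-score
  regression: per-annotation LD scores
  ℓ(j,c) = Σₖ r̃²(j,k)·a_kc with the finite-sample correction
  r̃² = r² − (1−r²)/(n−2), a two-step weighted regression of χ² on
  N·ℓ(j,c), fold enrichment = (h² share)/(SNP share), delete-one-block
  jackknife 95 % CIs and Benjamini–Hochberg FDR.
- **Expression vs contact** — genes with ≥1 OCR–promoter contact vs genes
  without, compared by a two-sided Wilcoxon rank-sum test (exact by
  tie-aware enumeration up to combined n = 20, tie-corrected normal
  approximation beyond).
- **Motif disruption** — allele-specific PWM scanning at accessible
  proxies: min–max-normalized log-odds scores over every offset × strand
  placement, gain/loss direction, and a strict TPM > 1 expressed-TF
  filter.
- **A synthetic-data generator** (`v2g.synthetic_data`) that emits a
  complete, internally consistent toy study — genome, genes, block-LD
  haplotypes, OCR BEDs, scored ibeds, GWAS summary statistics with a
  planted heritability enrichment, TPM tables, JASPAR PWMs — with
  machine-readable ground truth for every planted signal.

## Worked example

```python
from v2g import SimulationConfig, simulate_all
from v2g.pipeline import run_v2g, score_v2g, run_heritability

dataset = simulate_all(SimulationConfig(seed=1))
result = run_v2g(dataset)
print(score_v2g(result, dataset))
print(result.matrix)
fit = run_heritability(dataset)
print(fit.table[["category", "enrichment", "ci_lo", "ci_hi", "fdr"]])
```

prints

```
(1.0, 1.0)
            cell0     cell1   cell2
gene_id
G0003        both      none    none
G0012        none  promoter    none
G0021        none      none  distal
G0030    promoter    distal    none
G0039      distal    distal  distal
G0048        none  promoter    both

    category  enrichment       ci_lo       ci_hi      fdr
0       base    1.000000    1.000000    1.000000  0.75756
1   enriched   24.687142  -74.019562  123.393845  0.75756
2  cell0_ocr  -22.280401 -170.099067  125.538265  0.75756
3  cell1_ocr  -30.724509 -199.913959  138.464941  0.75756
4  cell2_ocr  -68.447339 -500.213419  363.318741  0.75756
```

i.e. all 12 planted implications are recovered with no false positives
(precision = recall = 1.0), and the gene × cell-type matrix reports the
planted modes — `promoter` for accessible proxies in promoter windows,
`distal` for proxies in promoter-interacting regions, `both` when a gene
is hit through both routes. The enrichment table always pins the base
category at 1 and here covers the planted 10-fold enrichment of the
`enriched` category; a single 400-SNP replicate is noisy, so the jackknife
CI is honest but wide (the acceptance script's 20-replicate median sits at
≈10 with ≥95 % CI coverage).

The same stages are available from the shell:

```bash
v2g simulate --seed 1 --outdir data/
v2g digest --fasta data/genome.fa --out data/fragments.rmap
v2g merge-ibed data/interactions_cell0_1frag.ibed \
               data/interactions_cell0_4frag.ibed --out merged.ibed
v2g proxies --vcf data/panel.vcf --sentinels data/sentinels.tsv --out proxies.tsv
v2g ldsc --sumstats data/sumstats.tsv --panel data/panel.vcf \
         --annot data/annotations.tsv --out enrichment.tsv
```

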