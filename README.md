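# digseg

Sex-biased gene-expression classification for staged gonadal RNA-seq designs
without replicates — the analysis layout of early fish gonadal transcriptome
studies, where one XX (genotypic female) and one XY (genotypic male) library
are sequenced at each of several developmental stages (days after hatching,
dah) and every gene must be sorted, per stage, into co-expressed,
differentially expressed, or sex-specifically expressed.

It is aimed at researchers who have per-gene mapped read counts for a
two-genotype × multi-stage design (typically 2 × 4 = 8 libraries) and want
the classical exact-test classification pipeline as a tested, scriptable
library rather than a one-off analysis.

## Method

**Quantification.** Expression is RPKM: for gene *g* with exonic length *L*
(nt) and mapped count *C* in a library of *N* total mapped reads,

```
RPKM = 1e9 · C / (N · L)
```

A gene is *expressed* in a library when it has at least one mapped read.

**Exact two-library test.** With one library per genotype there are no
replicates, so the count difference for each gene is assessed with the
Audic–Claverie exact statistic: conditional on observing *x* reads in a
library of *N₁* mapped reads, the count *y* in the second library (*N₂*)
follows

```
P(y|x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1+N₂/N₁)^(x+y+1) )
```

The two-sided p-value is `2·min(P(K≤y|x), P(K>y|x))` capped at 1 — a
construction that is exactly symmetric in the two libraries. Per stage,
p-values over all tested genes are adjusted by the Benjamini–Hochberg
step-up FDR.

**Five-type classification.** Per stage, with thresholds FDR ≤ 10⁻² and
|log₂(XX_RPKM/XY_RPKM)| ≥ 1:

| detection | criteria met | label |
|---|---|---|
| both genotypes | both | XX-DIG / XY-DIG (by ratio sign) |
| both genotypes | not both | COG |
| one genotype | FDR (ratio is ±∞) | XX-SEG / XY-SEG |
| one genotype | no | ND-SEG |
| neither | — | NOT-EXPRESSED |

**Cross-stage sets.** Sex-specific genes (detected in one genotype only,
across all libraries), all-stage co-expressed genes (COG at every stage),
and sex-enhanced genes — DIG or SEG for the same sex at the 5-dah anchor
stage and at ≥ 2 of the remaining stages, with the exact supporting stages
reported per gene.

**Simulator.** A Poisson count simulator plants these classes (co-expressed,
fold-change DIGs, one-side-zero SEGs, silent genes) by inverting the RPKM
formula, so the whole pipeline is testable without sequencing data and null
simulations are a calibrated check of the test's type-I error.

## Worked example

```python
from digseg import (SimulationConfig, generate_dataset, compute_rpkm,
                    detection_flags, classify_stage, five_type_counts,
                    enhanced_genes, log2_ratio)
from digseg.detest import test_stage

config = SimulationConfig(n_genes=2000, seed=42)
counts, genes, libraries, truth = generate_dataset(config)
rpkm = compute_rpkm(counts, genes, libraries)
flags = detection_flags(counts)

calls = {}
for stage in config.stages:
    tests = test_stage(counts, rpkm, libraries, stage)
    calls[stage] = classify_stage(tests, flags[f"XX_{stage}"],
                                  flags[f"XY_{stage}"])

print(five_type_counts(calls))
xx_enh, xy_enh = enhanced_genes(calls)
print(f"XX-enhanced: {len(xx_enh)}  XY-enhanced: {len(xy_enh)}")
print(f"log2(XX/XY) for RPKM pair 66.32 / 2.92: {log2_ratio(66.32, 2.92):.4f}")
```

prints

```
label   COG  XY-DIG  NOT-EXPRESSED  XX-DIG  XY-SEG  XX-SEG
stage
5      1100     300            300     200      80      20
30     1100     300            300     200      80      20
90     1100     300            300     200      80      20
180    1100     300            300     200      80      20
XX-enhanced: 220  XY-enhanced: 380
log2(XX/XY) for RPKM pair 66.32 / 2.92: 4.5054
```

The 2,000 simulated genes were planted as 55% co-expressed, 10%/15%
XX-/XY-differential at fold 8, 1%/4% XX-/XY-specific and 15% silent; at
these effect sizes and sequencing depths the classifier recovers every
planted class exactly, so each stage's tally reproduces the planted mix, and
the enhanced sets are exactly the planted DIGs+SEGs of each sex
(200+20 = 220 and 300+80 = 380). The final line is the fold-change statistic
for a strongly female-biased RPKM pair: 2^4.51 ≈ 23-fold higher in XX.

The same pipeline runs from the shell:

```
digseg simulate --n-genes 2000 --seed 42 --out fixture/
digseg classify --counts fixture/counts.tsv --lengths fixture/gene_lengths.tsv \
    --metadata fixture/libraries.tsv --out results/
digseg report --rundir results/
```

Real data enter as a counts TSV (`gene_id` + one column per library), a
library metadata TSV (`library_id`, `group`, `stage`, `total_mapped_reads`)
and either a gene-length TSV or a GFF3 annotation (lengths are per-gene
exon-interval unions).

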