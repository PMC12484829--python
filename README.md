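# dosagecomp

Allele-resolved analysis of gene dosage compensation in mammalian cells:
X-chromosome upregulation (XCU) calling from allele-split expression data,
copy-number-corrected compensation reports for heterozygous deletions,
protein-level compensation with RNA–protein concordance, and allele-resolved
ChIP promoter quantification.

## The scientific problem

In hybrid (e.g. *Mus musculus* × *Mus castaneus*) mouse pluripotent stem
cells, strain-specific SNPs let every RNA-seq read be assigned to its
parental allele, so expression can be measured per X chromosome rather than
per gene. Cells with a single active X (XO, XY, or cells carrying a
heterozygous X deletion) compensate the missing dose by upregulating the
remaining allele — but only for a subset of genes. `dosagecomp` implements
the downstream statistics of that analysis for anyone working with
allele-split count matrices: genotype sensing, gene-level upregulation
calling, region-level tests, and the proteomics and ChIP companions.

## The core statistics

For gene *g*, let *m<sub>gc</sub>* be the active-allele TPM in monosomic
cell *c* and *t<sub>gc</sub>* the total (both-allele) TPM in a biallelic XX
cell. Without compensation the single active allele should produce half the
biallelic output, so the null level is *t<sub>gc</sub>* ⁄ 2 and a gene is
**upregulated** when

> mean(*m*) / mean(*t* ⁄ 2) > 1.2 and a two-sided t-test of *m* against
> *t* ⁄ 2 gives *p* < 0.05.

Supporting machinery:

- **Joint-allele TPM**: both allele matrices are scaled by one per-sample
  factor (total = 10⁶ across genes *and* alleles), so monosomy stays visible
  as halved totals instead of being normalized away.
- **Trimmed means and X:A ratios**: per-cell mean of a gene set between its
  10th and 90th expression percentiles, divided by the allele-matched
  autosomal median.
- **Copy-number correction**: TPM (or protein abundance) divided by the
  number of gene copies, turning "is the remaining copy louder?" into a
  direct comparison across genotypes.
- **Statistical primitives**: Tukey HSD with the Tukey–Kramer statistic
  q = |m̄ᵢ − m̄ⱼ| ⁄ √((MSW⁄2)(1⁄nᵢ + 1⁄nⱼ)) against the studentized range
  distribution, paired t with Bonferroni for region contrasts, BH for ChIP
  families, Pearson chi-square for gene-set proportions.

A synthetic-data generator (`dosagecomp.simulate`) produces allele-split
negative-binomial counts, protein tables and coverage tracks with known
ground truth (which genes are compensated, where deletions lie), so every
stage is testable end to end.

## Worked example

```python
import dosagecomp as dc

cfg = dc.SimulationConfig(seed=7)                    # u=2, pi_u=0.4 defaults
ann = dc.simulate_annotation(cfg)
m, samples, truth = dc.simulate_allelic_counts(
    cfg, ann, dc.standard_genotypes(cfg, n_xx=60, n_xo_cast=40))
tpm = dc.normalize_expression(m, "umi_tpm")

x = ann.genes_on("chrX")
xo = samples.index[samples.genotype_label == "XCastOMus"]
xx = samples.index[samples.genotype_label == "XX"]
res = dc.XCUModel(tpm.allele2.loc[x, xo], tpm.total.loc[x, xx]).fit()
print(res.summary())
```

prints

```
Upregulation calls vs half-of-biallelic reference
=================================================
genes tested:        400 (of 400)
monosomic cells:     40
reference cells:     60
call rule:           p < 0.05 and FC > 1.2
upregulated genes:   157 (39.2% of tested)
median fold change:  1.129
```

157 of 400 X-linked genes are called upregulated — close to the simulated
compensated fraction (π_u = 0.4), with the median fold change near 1 because
most genes are not compensated. `res.table` holds the per-gene fold changes,
p-values and calls; `truth.compensated_gene_ids` is the ground truth to
score against.

The same analysis as a shell pipeline:

```sh
dosagecomp simulate --outdir out --seed 3
dosagecomp qc --outdir out
dosagecomp xcu --outdir out
dosagecomp region-report --outdir out
dosagecomp autosomal --outdir out
dosagecomp protein --outdir out
dosagecomp chip --outdir out
dosagecomp report --outdir out
cat out/summary.txt
```

```
dosagecomp pipeline report
config hash: a8f44a6c4b4b7eaf

XCU calling: 176 upregulated of 400 X-linked genes tested
  sensitivity vs truth: 1.000
  precision vs truth:   0.938
Protein: 177 upregulated of 399 X-linked proteins; RNA-protein log2FC r = 0.531
Autosomal: 369 silenced genes, 181 trans-upregulated on chr3
```

Identical config and seed reproduce byte-identical artifacts.

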