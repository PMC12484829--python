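# Methods

This note documents the models and procedures implemented in `dosagecomp`,
their assumptions, the defaults that matter, and the choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

All analyses operate on allele-split expression: a pair of genes × samples
matrices, one per parental allele (allele 1 plays the Mus role, allele 2 the
Cast role), plus an optional matrix of reads that carry no
allele-informative SNP. Coordinates are 0-based half-open internally; GFF3
is converted at the I/O boundary and the conversion is involutive.

**Normalization.** TPM scaling is joint over both alleles: one factor per
sample makes the grand total (genes × alleles) equal 10⁶. Normalizing each
allele to 10⁶ separately would erase exactly the signal under study — a
monosomic X produces half the allelic output, and that deficit (or its
compensation) must survive normalization. UMI counts get no length
correction (`umi_tpm`); bulk read counts are divided by gene length in kb
first (`length_tpm`, exonic length when the annotation provides exons, else
the genomic span). Unassigned reads are carried but excluded from allelic
statistics; whether they enter the scaling denominator is a flag
(default: excluded — the choice only rescales all values of a sample by a
common factor, so allelic ratios and fold changes are unaffected).

## Genotype sensing and QC

Cells need ≥ 10,000 raw UMIs on **each** allele (strict "less than" removal,
so a cell at exactly the threshold is kept). X status per cell comes from
mean allelic TPM over X-linked genes with a threshold of 2: one allele
above and the other below ⇒ monosomic for the high allele; both above ⇒
biallelic; anything else is flagged ambiguous and excluded downstream
rather than guessed. XY cells are indistinguishable from XO by this rule
(the classifier reports monosomic-X status only); metadata must separate
them. Pluripotency is a gate on log₂(total TPM) > 2.5 for every marker gene,
with zero expression failing cleanly.

**Deletion boundaries.** No published procedure exists for calling deletion
boundaries from allelic expression, so the package uses a documented
stand-in: per gene (TSS order) the allele-1 fraction a₁/(a₁+a₂), averaged
over replicates, smoothed with a centered 10-gene running mean; a deleted
segment is a maximal run of ≥ 5 genes with smoothed fraction < 0.1 (or
> 0.9 for the other allele); a run covering every expressed gene is flagged
as whole-chromosome monosomy. The smoothing window bounds the boundary
error (at most the window on each side) and tolerates single-gene dropout
in sparse cells.

## Dosage statistics

Percentiles are linear interpolation between order statistics, and the trim
keeps values equal to the boundary quantiles (inclusive), so a constant set
or a single gene survives trimming. With exactly two distinct values both
interpolated quantiles fall strictly between them and the trim would retain
nothing; that degenerate case falls back to the plain mean. The X:A ratio
is allele-matched — trimmed mean of the X set on one allele over the median
of the (same-trimmed) autosomal set on the same allele. Allele matching is
the only reading under which per-allele X:A in XX cells equals the
uncompensated-XO expectation; we also trim the autosomal set before taking
its median (the untrimmed alternative moves the median negligibly since the
trim is inclusive and central).

Copy-number correction divides by the total gene copies implied by a
profile (default one copy per allele; deletions/monosomy reduce it);
zero-copy genes become NA. Region membership is decided by TSS (a gene
straddling a deletion boundary belongs where its promoter is). Log₂ fold
changes against the per-gene reference mean are clipped to [−1, 4] only on
the visualization path; statistics always use unclipped values.

## Upregulation calling

**Single cell.** Per gene, active-allele TPM of monosomic cells is tested
against half the total TPM of biallelic cells (per-cell distributions, not
means of means — each observation is a cell). The default test is Welch's
unequal-variance t (the two groups have genuinely different variances: one
is a single allele, the other a halved sum of two); a pooled-variance mode
exists and rarely flips a call because the calls are threshold-gated:
upregulated ⇔ p < 0.05 **and** fold change > 1.2. The test is two-sided
with the directional gate. Under the null (no compensation) the gate makes
the caller strictly conservative — the called fraction stays below α.

**Bulk.** Genes expressed in the reference (mean copy-corrected TPM > 5)
with mean copy-corrected fold change strictly > 1.2 between the monosomic
and biallelic lines.

**Region tests.** Pairwise genotype contrasts are paired t-tests over
per-gene means (pairing by gene), Bonferroni-corrected over the C(k,2)
pairs. All-zero differences give p = 1 (no evidence of difference) rather
than NaN. Below 10 shared genes the test abstains with a reason instead of
returning an untrustworthy p — small within-deletion gene sets are reported
descriptively only.

**Autosomal silencing.** On the targeted allele, a gene is cis-silenced
when mean(+dox)/mean(−dox) < 0.15. The densely silenced region is found by
a 10 Mb window sliding in 1 Mb steps (≥ 2 silenced genes per window
qualifies; qualifying windows are merged, the densest run wins, and a run
reaching the last window extends to the telomere); detection can be
disabled in favor of a configured region. Trans upregulation on the other
allele defaults to log₂ fold change > 0.5 — a literal linear-ratio mode is
selectable, but a linear threshold of 0.5 would call essentially every
unchanged gene (FC ≈ 1), so the log₂ reading is the default and both are
documented.

**Primitives.** Tukey HSD uses the Tukey–Kramer statistic
q = |m̄ᵢ − m̄ⱼ| / √((MSW/2)(1/nᵢ + 1/nⱼ)) with p from the studentized range
distribution (k groups, N − k df); at k = 2 it reduces exactly to the
pooled t-test, which the tests verify, and a permutation oracle checks
k = 3. Zero within-group variance with unequal means reports the limiting
p = 0. BH/Bonferroni go through statsmodels; the 2×2 chi-square is
Pearson's without continuity correction (a corrected mode is flagged), and
a fully-annotated universe degenerates to statistic 0 rather than a
zero-margin error.

## Proteomics

Mass spectrometry has no allelic resolution, so abundances are divided by
per-sample gene copies (biallelic X and autosomes: 2; monosomic X or
deleted segment: 1). Only proteins detected in every sample are analyzed —
no imputation anywhere. The X:A detection-bias filter keeps proteins with
mean XX abundance > 1.2 × 10⁷ before ratioing against the per-sample
autosomal mean. Differential abundance is Tukey HSD across genotypes on
log₂ abundances (variance stabilization for LFQ data; raw-scale mode
available), and a protein is up-called only when log₂FC > 0 and p < 0.05 in
**every** monosomic-vs-biallelic contrast. RNA–protein concordance
cross-classifies genes into both / rna_only / protein_only / neither; the
default "up" rule is fold change > 1 on copy-corrected values, with a
significance-based rule selectable, and the Pearson r is computed on the
paired log₂ fold changes.

## ChIP quantification

Coverage tracks are stepwise-constant per-base signals; uncovered bases
read as zero everywhere (missing-data-as-zero). CP10M scaling multiplies by
10⁷/total and refuses to run twice. Promoters are the 1 kb biologically
upstream window ending at the TSS (genomically rightward for − strand
genes), clipped at chromosome bounds; gene bodies span TSS–TES.
Metaprofiles use the scale-regions layout — 1500 bp flanks at native 100 bp
bins plus the body linearly rescaled to 3000 bp (each body bin averages an
equal genomic slice), 60 bins total, strand-flipped to 5′→3′. Genes shorter
than one bin are skipped with a warning rather than zero-filled. Timepoint
contrasts are paired t-tests, gene-set contrasts two-sample t-tests; the
BH family is exactly the set of contrasts submitted in one call (the
grouping is an explicit input, not a hidden global).

## The synthetic-data generator

The generator emulates the downstream shape of allele-split data from
hybrid mouse PSCs; it defines the study conditions and is not a tuning
dial. Per gene, sample and allele:

    mu = base_g · copies · b^[allele 1] · e^[silenced] · u^[upregulated] · f_s
    count ~ NB(mu, variance = mu + α·mu²)

- `base_g`: log-normal across genes (ln-scale μ = 1, σ = 1 — a
  realistically long-tailed expression distribution).
- genome: 400 X-linked and 4000 autosomal genes (≈10:1), mirroring real
  allele-resolved data where the X carries ~3–4% of genes. This ratio is
  load-bearing: in an X-heavy genome, losing one X allele shrinks the
  library enough that joint-TPM renormalization alone inflates every gene
  ~20% and masquerades as upregulation.
- `u = 2.0` on the remaining active allele of a compensated gene wherever
  the gene is monoallelically expressed (full compensation restores the
  two-copy output); `pi_u = 0.4` of genes are compensated, matching the
  ~40% upregulated fraction this kind of analysis reports.
- mapping bias `b = 1.05` on allele 1 (the reference-strain allele), the
  small excess typical of reads mapped to one strain's reference.
- dispersion α = 0.3 (single-cell UMI) or 0.05 (bulk); library size 10⁵
  per cell / 5 × 10⁶ per bulk sample, CV 0.3.
- cis silencing multiplies the targeted allele by 0.1 (residual activity);
  compensated silenced genes get `u` on the trans allele — silencing is
  transcriptional, so copy numbers are untouched.
- proteins: abundance ∝ total expected RNA output × 2^N(0, σ_p), σ_p = 0.3
  in **log₂** units (the usual scale for LFQ replicate scatter), n
  replicates per genotype, detection limit 10⁶ on a 5 × 10⁶ scale.
  The allele-1 mapping bias is removed from protein means: it is a
  read-alignment artifact and mass spectrometry has no alignment step.
  Protein-only-compensated genes (30% of the non-RNA-compensated ones) get
  the extra `u` in monoallelic genotypes.
- coverage: per-allele promoter signal = background + gain × allelic mean
  + truncated Gaussian noise; background 1.0, gain 1.0, noise sd 0.5.

All randomness flows from one seed through named `SeedSequence` children,
so identical config ⇒ byte-identical outputs, including every pipeline
artifact (sorted JSON keys, fixed float formats, no timestamps).

**What the generator does not emulate** — transcriptional burst kinetics,
doublets/ambient RNA, batch effects, 3′ coverage bias, isoform structure,
peptide-level protein inference, and real SNP density (allele assignment is
taken as given). Passing tests therefore demonstrate that the statistics
recover the truth under the stated generative model at realistic depths,
not that the upstream read processing of real data is handled.

## Problem sizes and verification

The recovery checks run at sizes a laptop handles in seconds: 600 cells
for genotype sensing (accuracy ≥ 99%), 60 XX + 40 XO cells × 400 X genes
for caller calibration (null call fraction ≤ α) and recovery (sensitivity
≥ 0.8, precision ≥ 0.9), 20 randomized deletion lines for boundary
inference, 3 replicates per genotype for the bulk and protein stages.
Protein-stage sensitivity at n = 3 and σ_p = 0.3 has an expected value only
a little above the 0.7 requirement (the both-contrast Tukey rule at n = 3
is the binding constraint), so it is estimated by Monte Carlo over 25
independently-noised proteome replicates rather than a single draw — the
estimate then reflects the procedure's actual operating characteristic
instead of one noisy realization. The k = 3 Tukey check compares a fixed
toy dataset against a 100,000-permutation max-|q| oracle; permutation and
parametric p agree to well under 0.01 there, while the residual tolerance
absorbs the oracle's own Monte-Carlo noise.

## Known limitations

- The deletion-boundary algorithm is a stand-in; real analyses would
  corroborate boundaries with DNA evidence.
- The genotype classifier cannot separate XY from XO without metadata.
- `scale-regions` body rescaling matches the reference tool at the
  contract level (equal genomic slices per bin), not bit-for-bit.
- Copy numbers are restricted to {0, 1} per allele; amplifications are out
  of scope.
- Protein inference is one protein per gene in the generator; the analysis
  accepts many-to-one mappings but never re-apportions shared peptides.
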