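"""Cell/sample quality control, genotype sensing and deletion-boundary
inference from allelic expression.

Genotype sensing exploits the fact that a lost or absent X homolog produces
near-zero allelic TPM on the X: mean allelic X expression above a small
threshold on one allele and below it on the other marks a monosomic cell.
XY cells look identical to XO by this rule (the classifier reports
monosomic-X status only); distinguishing them requires sample metadata.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AllelicExpressionMatrix, GeneAnnotation, GenomicRegion

__all__ = [
    "filter_min_allelic_umis",
    "classify_x_status",
    "check_pluripotency",
    "infer_deletion_boundaries",
    "validate_deletion_ratio",
]

CALL_BIALLELIC = "biallelic_XX"
CALL_X1 = "X1_monosomic"  # only allele 1 active
CALL_X2 = "X2_monosomic"  # only allele 2 active
CALL_AMBIGUOUS = "ambiguous"

DEFAULT_PLURIPOTENCY_MARKERS = ("Esrrb", "Nanog", "Pou5f1")


def filter_min_allelic_umis(
    m: AllelicExpressionMatrix, min_umis: int = 10_000
) -> tuple[AllelicExpressionMatrix, pd.DataFrame]:
    """Drop cells with fewer than ``min_umis`` raw UMIs on either allele.

    The rule is a strict "less than": a cell with exactly ``min_umis`` on
    both alleles is retained.  Returns the filtered matrix and a per-cell
    report (totals per allele, kept flag).  Idempotent.
    """
    if m.unit != "raw_count":
        raise ValueError(f"UMI filter requires raw counts, got unit={m.unit!r}")
    t1 = m.allele1.sum(axis=0)
    t2 = m.allele2.sum(axis=0)
    keep = (t1 >= min_umis) & (t2 >= min_umis)
    report = pd.DataFrame(
        {"total_allele1": t1, "total_allele2": t2, "kept": keep}
    )
    return m.select_samples(m.sample_ids[keep]), report


def classify_x_status(
    m: AllelicExpressionMatrix,
    annotation: GeneAnnotation,
    threshold: float = 2.0,
    x_chrom: str = "chrX",
) -> pd.DataFrame:
    """Call X status per cell from mean allelic X-linked TPM.

    allele i mean > threshold and allele j mean < threshold -> monosomic for
    allele i; both above -> biallelic; anything else -> ambiguous (flagged
    for downstream omission rather than guessed).
    """
    if m.unit != "tpm":
        raise ValueError("classify_x_status requires TPM-normalized input")
    x_genes = annotation.genes_on(x_chrom)
    x_genes = x_genes[x_genes.isin(m.gene_ids)]
    if len(x_genes) == 0:
        raise ValueError(f"no {x_chrom} genes present in matrix")
    m1 = m.allele1.loc[x_genes].mean(axis=0)
    m2 = m.allele2.loc[x_genes].mean(axis=0)
    call = np.select(
        [
            (m1 > threshold) & (m2 > threshold),
            (m1 > threshold) & (m2 < threshold),
            (m2 > threshold) & (m1 < threshold),
        ],
        [CALL_BIALLELIC, CALL_X1, CALL_X2],
        default=CALL_AMBIGUOUS,
    )
    return pd.DataFrame(
        {"mean_x_allele1": m1, "mean_x_allele2": m2, "call": call}
    )


def check_pluripotency(
    m: AllelicExpressionMatrix,
    marker_genes: Sequence[str] = DEFAULT_PLURIPOTENCY_MARKERS,
    log2_threshold: float = 2.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample pluripotency check on total (both-allele) marker TPM.

    A sample passes iff log2(total TPM) > threshold for every marker; zero
    expression fails without numeric warnings.  Returns (pass flags,
    per-marker log2 TPM table).
    """
    missing = [g for g in marker_genes if g not in m.gene_ids]
    if missing:
        raise ValueError(f"missing pluripotency markers: {missing}")
    total = m.total.loc[list(marker_genes)]
    with np.errstate(divide="ignore"):
        log2 = np.log2(total.where(total > 0))
    ok = (log2 > log2_threshold).fillna(False).all(axis=0)
    table = log2.T
    table.columns = [f"log2_tpm_{g}" for g in marker_genes]
    return ok.rename("pluripotent"), table


def infer_deletion_boundaries(
    m: AllelicExpressionMatrix,
    annotation: GeneAnnotation,
    chrom: str,
    window_genes: int = 10,
    fraction_threshold: float = 0.1,
    min_run: int = 5,
    samples: Optional[Sequence[str]] = None,
) -> list[dict]:
    """Infer deleted (or monosomic) segments from allelic fractions.

    Per gene along the chromosome (TSS order), the allele-1 fraction
    a1/(a1+a2) is averaged over the given samples (replicates of one line),
    genes with zero total skipped, then smoothed by a centered running mean
    over ``window_genes``.  A maximal run of >= ``min_run`` genes with
    smoothed fraction < ``fraction_threshold`` (allele 1 deleted) or
    > 1 - threshold (allele 2 deleted) is reported; a run spanning every gene
    is flagged as whole-chromosome monosomy.

    Returns a list of dicts: allele, chrom, start, end, first/last gene and
    gene count, monosomy flag.
    """
    sub = annotation.on_chrom(chrom).sorted_by_position()
    genes = sub.gene_ids[sub.gene_ids.isin(m.gene_ids)]
    if len(genes) < min_run:
        raise ValueError(f"fewer than {min_run} genes on {chrom}")
    cols = list(samples) if samples is not None else list(m.sample_ids)
    a1 = m.allele1.loc[genes, cols]
    a2 = m.allele2.loc[genes, cols]
    total = a1 + a2
    frac = (a1.where(total > 0) / total.where(total > 0)).mean(axis=1)
    frac = frac.dropna()
    if len(frac) < min_run:
        raise ValueError(f"fewer than {min_run} expressed genes on {chrom}")
    smoothed = frac.rolling(window_genes, center=True, min_periods=1).mean()

    results = []
    for allele, lost in ((1, smoothed < fraction_threshold),
                         (2, smoothed > 1.0 - fraction_threshold)):
        run_start = None
        runs = []
        vals = lost.values
        for i, flag in enumerate(np.append(vals, False)):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                if i - run_start >= min_run:
                    runs.append((run_start, i))
                run_start = None
        for i0, i1 in runs:
            ids = frac.index[i0:i1]
            spans = sub.df.loc[ids]
            results.append(
                {
                    "allele": allele,
                    "chrom": chrom,
                    "start": int(spans["start"].min()),
                    "end": int(spans["end"].max()),
                    "first_gene": ids[0],
                    "last_gene": ids[-1],
                    "n_genes": len(ids),
                    "monosomy": len(ids) == len(frac),
                }
            )
    return results


def validate_deletion_ratio(
    m: AllelicExpressionMatrix,
    sample_ids: Sequence[str],
    reference_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-gene ratio of each sample's total TPM to the mean of reference
    samples (the parental-line deletion check: a heterozygously deleted,
    uncompensated gene sits near 0.5).  Genes with zero reference mean are
    NA."""
    if len(reference_ids) == 0:
        raise ValueError("empty reference sample set")
    ref = m.total[list(reference_ids)].mean(axis=1)
    ref = ref.where(ref > 0)
    return m.total[list(sample_ids)].div(ref, axis=0)
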