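"""Descriptive dosage statistics: trimmed means, X:A ratios, copy-number
correction, region partitioning, fold changes, sample correlation.

Percentiles use linear interpolation between order statistics throughout, and
trim bounds are inclusive (values equal to the boundary quantile are kept),
so a constant gene set or a single gene survives trimming unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import (
    AllelicExpressionMatrix,
    CopyNumberProfile,
    GeneAnnotation,
    GenomicRegion,
)

__all__ = [
    "AnalysisConfig",
    "trimmed_mean_expression",
    "x_to_autosome_ratio",
    "dosage_summary",
    "copy_number_correct",
    "partition_genes_by_region",
    "per_gene_log2fc",
    "sample_correlation",
]


@dataclass
class AnalysisConfig:
    """Analysis thresholds.

    Defaults: 10/90 percentile trim for single-cell gene sets (5/95 for the
    autosomal bulk analysis -- pass ``AnalysisConfig.bulk_autosomal()``),
    TPM > 5 expression filter for bulk, fold-change gate 1.2, alpha 0.05,
    visualization clipping of log2 fold changes at (-1, 4), cis-silencing
    call at fold change < 0.15, trans-upregulation call at log2 FC > 0.5,
    and abstention from region tests below 10 genes.
    """

    trim_lower_pct: float = 10.0
    trim_upper_pct: float = 90.0
    expressed_min_tpm: float = 5.0
    fc_threshold: float = 1.2
    alpha: float = 0.05
    clip_bounds: tuple = (-1.0, 4.0)
    min_genes_for_test: int = 10
    silenced_fc_threshold: float = 0.15
    trans_log2fc_threshold: float = 0.5
    min_protein_xx_abundance: float = 12_000_000.0

    def __post_init__(self):
        if not (0.0 <= self.trim_lower_pct < self.trim_upper_pct <= 100.0):
            raise ValueError("need 0 <= trim_lower < trim_upper <= 100")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must be > 1")

    @classmethod
    def bulk_autosomal(cls, **kw) -> "AnalysisConfig":
        kw.setdefault("trim_lower_pct", 5.0)
        kw.setdefault("trim_upper_pct", 95.0)
        return cls(**kw)


def _as_config(cfg: Optional[AnalysisConfig]) -> AnalysisConfig:
    return cfg if cfg is not None else AnalysisConfig()


# ---------------------------------------------------------------------------
# Trimmed means and X:A
# ---------------------------------------------------------------------------


def trimmed_mean_expression(values, cfg: Optional[AnalysisConfig] = None) -> float:
    """Mean of values between the configured percentiles (inclusive bounds).

    ``values``: expression of one gene set in one sample.  Quantiles are
    computed by linear interpolation within this sample's values.
    """
    cfg = _as_config(cfg)
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("trimmed mean of an empty gene set")
    q_low, q_high = np.percentile(
        v, [cfg.trim_lower_pct, cfg.trim_upper_pct], method="linear"
    )
    kept = v[(v >= q_low) & (v <= q_high)]
    if kept.size == 0:
        # only reachable for two distinct values, where both interpolated
        # quantiles fall strictly between them: trimming degenerates to the
        # plain mean
        return float(v.mean())
    return float(kept.mean())


def x_to_autosome_ratio(
    m: AllelicExpressionMatrix,
    sample: str,
    allele: int,
    annotation: GeneAnnotation,
    cfg: Optional[AnalysisConfig] = None,
    gene_set=None,
    x_chrom: str = "chrX",
) -> float:
    """Allele-matched X:A ratio for one sample.

    Trimmed mean of the X-linked (or explicitly supplied) gene set on the
    given allele, divided by the median of the trimmed autosomal set on the
    same allele.  The same trim is applied to both sets.
    """
    cfg = _as_config(cfg)
    col = m.allele(allele)[sample]
    x_genes = pd.Index(gene_set) if gene_set is not None else annotation.genes_on(x_chrom)
    a_genes = annotation.autosomal_genes(x_chrom=x_chrom)
    x_vals = col.reindex(x_genes).dropna().values
    a_vals = col.reindex(a_genes).dropna().values
    if x_vals.size == 0:
        raise ValueError("no X-linked genes in matrix")
    if a_vals.size == 0:
        raise ValueError("no autosomal genes in matrix")
    num = trimmed_mean_expression(x_vals, cfg)
    q_low, q_high = np.percentile(
        a_vals, [cfg.trim_lower_pct, cfg.trim_upper_pct], method="linear"
    )
    denom = float(np.median(a_vals[(a_vals >= q_low) & (a_vals <= q_high)]))
    if denom == 0:
        raise ValueError(f"zero autosomal median for sample {sample}")
    return num / denom


def dosage_summary(
    m: AllelicExpressionMatrix,
    annotation: GeneAnnotation,
    cfg: Optional[AnalysisConfig] = None,
    gene_set=None,
    gene_set_name: str = "chrX",
    x_chrom: str = "chrX",
) -> pd.DataFrame:
    """Per-sample trimmed means and X:A ratios for both alleles."""
    cfg = _as_config(cfg)
    genes = pd.Index(gene_set) if gene_set is not None else annotation.genes_on(x_chrom)
    rows = []
    for sample in m.sample_ids:
        row = {"sample_id": sample, "gene_set": gene_set_name, "n_genes_used": len(genes)}
        for allele in (1, 2):
            vals = m.allele(allele)[sample].reindex(genes).dropna().values
            row[f"trimmed_mean_allele{allele}"] = trimmed_mean_expression(vals, cfg)
            row[f"x_to_a_allele{allele}"] = x_to_autosome_ratio(
                m, sample, allele, annotation, cfg, gene_set=genes, x_chrom=x_chrom
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Copy-number correction
# ---------------------------------------------------------------------------


def copy_number_correct(
    values: pd.DataFrame,
    profile: Union[CopyNumberProfile, Mapping[str, CopyNumberProfile]],
    annotation: GeneAnnotation,
) -> pd.DataFrame:
    """Divide expression by total gene copies (per-copy output).

    ``values``: genes x samples (TPM or protein abundance).  ``profile`` is a
    single profile applied to every column, or a mapping sample -> profile.
    Genes with zero total copies are reported as NaN.
    """
    if isinstance(profile, CopyNumberProfile):
        copies = profile.copies_for(annotation)["total"].reindex(values.index)
        if copies.isna().any():
            missing = values.index[copies.isna()].tolist()
            raise ValueError(f"genes missing from annotation: {missing}")
        denom = copies.values.astype(float)
        denom[denom == 0] = np.nan
        return values.div(pd.Series(denom, index=values.index), axis=0)
    out = {}
    for sample in values.columns:
        if sample not in profile:
            raise ValueError(f"no copy profile for sample {sample!r}")
        out[sample] = copy_number_correct(values[[sample]], profile[sample], annotation)[sample]
    return pd.DataFrame(out, index=values.index)


def partition_genes_by_region(
    annotation: GeneAnnotation, region: GenomicRegion
) -> tuple[pd.Index, pd.Index]:
    """Split the region's chromosome into (inside, outside) gene sets by TSS.

    A gene is inside iff its TSS lies in [start, end); genes on other
    chromosomes belong to neither set.
    """
    df = annotation.df
    on_chrom = df["chrom"] == region.chrom
    inside = on_chrom & (df["tss"] >= region.start) & (df["tss"] < region.end)
    return df.index[inside], df.index[on_chrom & ~inside]


# ---------------------------------------------------------------------------
# Fold changes and correlation
# ---------------------------------------------------------------------------


def per_gene_log2fc(
    values: Union[pd.Series, pd.DataFrame],
    reference: pd.Series,
    cfg: Optional[AnalysisConfig] = None,
    clip: bool = False,
) -> Union[pd.Series, pd.DataFrame]:
    """log2(value / per-gene reference mean); NaN where the reference is 0.

    ``clip`` bounds extreme values to ``cfg.clip_bounds`` (visualization
    path only; statistics are computed on unclipped values).
    """
    cfg = _as_config(cfg)
    ref = reference.reindex(values.index if values.ndim == 1 else values.index)
    ref = ref.where(ref > 0)
    if isinstance(values, pd.DataFrame):
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(values.div(ref, axis=0))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(values / ref)
    fc = fc.replace([np.inf, -np.inf], np.nan)
    if clip:
        low, high = cfg.clip_bounds
        fc = fc.clip(lower=low, upper=high)
    return fc


def sample_correlation(
    m: AllelicExpressionMatrix,
    annotation: GeneAnnotation,
    x_chrom: str = "chrX",
) -> pd.DataFrame:
    """Pearson correlation between samples over total autosomal expression.

    Symmetric with unit diagonal; zero-variance samples yield NaN rows and
    columns.
    """
    if m.n_samples < 2:
        raise ValueError("sample correlation needs >= 2 samples")
    genes = annotation.autosomal_genes(x_chrom=x_chrom)
    total = m.total.reindex(genes).dropna(how="all")
    return total.corr(method="pearson")
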