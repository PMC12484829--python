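"""Protein-level dosage compensation and RNA-protein concordance.

Mass spectrometry gives no allelic resolution, so protein abundances are
made comparable across genotypes by copy-number correction: every protein's
abundance is divided by the number of gene copies in that sample (2 for
autosomal and biallelic X-linked proteins, 1 for X-linked proteins in
monosomic lines and for proteins inside a heterozygous deletion).  On this
per-copy scale, upregulation in single-active-X lines is the protein-level
signature of dosage compensation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calling import tukey_hsd
from .io import CopyNumberProfile, GeneAnnotation
from .stats import AnalysisConfig, _as_config

__all__ = [
    "ProteinMatrix",
    "filter_fully_detected",
    "copy_number_correct_protein",
    "protein_x_to_a",
    "differential_protein_abundance",
    "classify_rna_protein_concordance",
]

CONCORDANCE_CATEGORIES = ("both", "rna_only", "protein_only", "neither")


@dataclass
class ProteinMatrix:
    """Label-free protein quantification: proteins x samples.

    ``abundances`` holds NaN where a protein was not detected; ``gene_map``
    maps protein ids to gene ids (many-to-one allowed); ``detected`` defaults
    to the non-NaN mask.
    """

    abundances: pd.DataFrame
    gene_map: pd.Series
    detected: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.detected is None:
            self.detected = self.abundances.notna()
        if not self.detected.index.equals(self.abundances.index):
            raise ValueError("detection mask index mismatch")
        missing = self.abundances.index.difference(self.gene_map.index)
        if len(missing):
            raise ValueError(f"proteins without gene mapping: {missing.tolist()}")
        vals = self.abundances.values
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise ValueError("detected abundances must be positive")

    @property
    def protein_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundances.columns

    def genes(self) -> pd.Series:
        return self.gene_map.reindex(self.abundances.index)

    def select_proteins(self, protein_ids) -> "ProteinMatrix":
        ids = list(protein_ids)
        return replace(
            self,
            abundances=self.abundances.loc[ids],
            detected=self.detected.loc[ids],
            gene_map=self.gene_map.reindex(ids),
        )

    def write_tsv(self, path) -> None:
        out = self.abundances.copy()
        out.insert(0, "gene_id", self.genes())
        out.to_csv(path, sep="\t", float_format="%.17g", index_label="protein_id")

    @classmethod
    def read_tsv(cls, path) -> "ProteinMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_map = df.pop("gene_id")
        return cls(df, gene_map)


def filter_fully_detected(m: ProteinMatrix) -> ProteinMatrix:
    """Retain proteins detected in every sample (no imputation anywhere)."""
    keep = m.detected.all(axis=1)
    out = m.select_proteins(m.protein_ids[keep])
    if out.abundances.empty:
        import warnings

        warnings.warn("no protein detected in all samples", stacklevel=2)
    return out


def copy_number_correct_protein(
    m: ProteinMatrix,
    sample_profiles: Mapping[str, CopyNumberProfile],
    annotation: GeneAnnotation,
) -> ProteinMatrix:
    """Divide each sample's abundances by that sample's per-gene total copies.

    The per-allele default of one copy makes autosomal and biallelic X-linked
    genes two-copy; monosomy/deletion profiles reduce the affected genes to a
    single copy.  Proteins whose gene is absent from the annotation raise.
    """
    genes = m.genes()
    unknown = genes[~genes.isin(annotation.gene_ids)]
    if len(unknown):
        raise ValueError(
            f"proteins with unresolvable genes: {unknown.index.tolist()}"
        )
    out = {}
    for sample in m.sample_ids:
        if sample not in sample_profiles:
            raise ValueError(f"no copy profile for sample {sample!r}")
        copies = sample_profiles[sample].copies_for(annotation)["total"]
        denom = copies.reindex(genes.values).values.astype(float)
        denom[denom == 0] = np.nan
        out[sample] = m.abundances[sample].values / denom
    corrected = pd.DataFrame(out, index=m.protein_ids)
    return replace(m, abundances=corrected, detected=m.detected.copy())


def protein_x_to_a(
    m: ProteinMatrix,
    annotation: GeneAnnotation,
    xx_samples: Sequence[str],
    min_xx_mean_abundance: Optional[float] = None,
    x_chrom: str = "chrX",
    cfg: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Per-sample X:A ratios on raw (uncorrected) abundances.

    To avoid a detection bias against single-copy X-linked proteins, only
    proteins whose mean XX abundance exceeds the threshold (default 1.2e7)
    enter; each X-linked protein's abundance is divided by the mean autosomal
    abundance of the same sample.
    """
    cfg = _as_config(cfg)
    thr = cfg.min_protein_xx_abundance if min_xx_mean_abundance is None else min_xx_mean_abundance
    xx = list(xx_samples)
    if not xx:
        raise ValueError("need XX samples for the abundance filter")
    keep = m.abundances[xx].mean(axis=1) > thr
    if not keep.any():
        raise ValueError("no protein passes the XX mean-abundance filter")
    sub = m.select_proteins(m.protein_ids[keep])
    genes = sub.genes()
    chrom = annotation.df["chrom"].reindex(genes.values).values
    is_x = chrom == x_chrom
    if not is_x.any():
        raise ValueError("no X-linked proteins pass the filter")
    auto_mean = sub.abundances.loc[~is_x].mean(axis=0)
    return sub.abundances.loc[is_x].div(auto_mean, axis=1)


def differential_protein_abundance(
    m_cc: ProteinMatrix,
    groups: Mapping[str, Sequence[str]],
    reference: str = "XX",
    cfg: Optional[AnalysisConfig] = None,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-protein Tukey HSD across genotypes on copy-corrected abundances.

    Abundances are log2-transformed before testing (variance stabilization
    for LFQ data; ``log_transform=False`` tests the raw scale).  For each
    non-reference genotype the contrast log2 fold change vs the reference is
    reported with its Tukey-Kramer adjusted p.  A protein is up-called iff
    log2FC > 0 and p < alpha in EVERY non-reference comparison (the
    both-monosomic-lines rule).  Returns (results table, up-called ids).
    """
    cfg = _as_config(cfg)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    labels = [reference] + [g for g in groups if g != reference]
    for lab in labels:
        if len(groups[lab]) < 2:
            raise ValueError(f"group {lab!r} needs >= 2 replicates")
    contrasts = labels[1:]

    from scipy import stats as sps

    # vectorized Tukey-Kramer over all proteins at once: per protein the
    # within-group mean square pools every genotype, exactly as tukey_hsd does
    k = len(labels)
    mats = {lab: m_cc.abundances[list(groups[lab])].values.astype(float)
            for lab in labels}
    complete = ~np.any(
        [np.isnan(v).any(axis=1) for v in mats.values()], axis=0
    )
    data = {lab: (np.log2(v) if log_transform else v) for lab, v in mats.items()}
    ns = {lab: v.shape[1] for lab, v in mats.items()}
    df_within = sum(ns.values()) - k
    ssw = sum(((v - v.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              for v in data.values())
    msw = ssw / df_within
    log2_means = {lab: np.nanmean(np.log2(v), axis=1) for lab, v in mats.items()}
    means = {lab: v.mean(axis=1) for lab, v in data.items()}

    table = pd.DataFrame(index=m_cc.protein_ids)
    up_all = complete.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        for lab in contrasts:
            se = np.sqrt((msw / 2.0) * (1.0 / ns[lab] + 1.0 / ns[reference]))
            q = np.abs(means[lab] - means[reference]) / se
            p = sps.studentized_range.sf(q, k, df_within)
            zero_var = msw == 0
            p = np.where(zero_var,
                         np.where(means[lab] == means[reference], 1.0, 0.0), p)
            l2fc = log2_means[lab] - log2_means[reference]
            table[f"log2fc_{lab}"] = np.where(complete, l2fc, np.nan)
            table[f"p_{lab}"] = np.where(complete, np.clip(p, 0.0, 1.0), np.nan)
            up_all &= (l2fc > 0) & (p < cfg.alpha)
    table["up"] = pd.array(up_all, dtype="boolean")
    table.loc[~complete, "up"] = pd.NA
    table.index.name = "protein_id"
    table["gene_id"] = m_cc.genes()
    called = table.index[table["up"].fillna(False).astype(bool)]
    return table, called


def classify_rna_protein_concordance(
    rna_fc: pd.Series,
    prot_fc: pd.Series,
    rule: str = "fc_gt_1",
    rna_calls: Optional[pd.Series] = None,
    prot_calls: Optional[pd.Series] = None,
) -> dict:
    """Cross-classify genes by RNA vs protein upregulation.

    ``rna_fc``/``prot_fc``: per-gene copy-corrected monosomic/XX fold
    changes on a shared gene universe.  ``fc_gt_1`` (default) calls a level
    "up" when its fold change exceeds 1; ``significant_calls`` uses the
    supplied boolean call series instead.  Returns records (with exact
    category partition), category proportions, and the Pearson r of the
    paired log2 fold changes.
    """
    genes = rna_fc.index.intersection(prot_fc.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between RNA and protein data")
    rna = rna_fc.reindex(genes)
    prot = prot_fc.reindex(genes)
    if rule == "fc_gt_1":
        rna_up = rna > 1.0
        prot_up = prot > 1.0
    elif rule == "significant_calls":
        if rna_calls is None or prot_calls is None:
            raise ValueError("significant_calls rule needs call series")
        rna_up = rna_calls.reindex(genes).fillna(False).astype(bool)
        prot_up = prot_calls.reindex(genes).fillna(False).astype(bool)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    category = np.select(
        [rna_up & prot_up, rna_up & ~prot_up, ~rna_up & prot_up],
        ["both", "rna_only", "protein_only"],
        default="neither",
    )
    records = pd.DataFrame(
        {
            "rna_fc": rna,
            "protein_fc": prot,
            "rna_up": rna_up,
            "protein_up": prot_up,
            "category": category,
        },
        index=genes,
    )
    counts = records["category"].value_counts().reindex(
        CONCORDANCE_CATEGORIES, fill_value=0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2(rna.values.astype(float))
        lp = np.log2(prot.values.astype(float))
    ok = np.isfinite(lr) & np.isfinite(lp)
    r = float(np.corrcoef(lr[ok], lp[ok])[0, 1]) if ok.sum() >= 2 else np.nan
    return {
        "records": records,
        "counts": counts,
        "proportions": counts / counts.sum(),
        "pearson_r_log2fc": r,
    }
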