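"""Inferential core: upregulation calling and statistical primitives.

The central question is whether a gene's expression from a single active
allele exceeds half of the total biallelic reference level -- the signature
of dosage compensation by upregulation of the remaining allele.  The
single-cell test (:class:`XCUModel`) compares per-cell active-allele TPM in
monosomic cells against per-cell total TPM / 2 in biallelic XX cells, gene by
gene; a gene is called upregulated when the test is significant AND the fold
change clears a gate (default 1.2), which makes the caller strictly
conservative under the null.

Also here: the region-level paired tests with Bonferroni correction, the
autosomal cis-silencing / trans-upregulation calls, gene-set proportion
tests, and the shared statistical primitives (Tukey HSD with Tukey-Kramer
correction, BH/Bonferroni adjustment, 2x2 chi-square).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneAnnotation, GenomicRegion
from .stats import AnalysisConfig, _as_config

__all__ = [
    "XCUModel",
    "XCUResults",
    "call_xcu_genes",
    "select_upregulated_bulk",
    "test_region_compensation",
    "tukey_hsd",
    "adjust_pvalues",
    "chi_square_2x2",
    "call_silenced_genes",
    "define_silenced_region",
    "call_trans_upregulated",
    "compare_gene_set_proportions",
]


# ---------------------------------------------------------------------------
# Statistical primitives
# ---------------------------------------------------------------------------


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` (min(1, m*p)) or ``bh``
    (Benjamini-Hochberg step-up, monotone and rank-preserving)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """All-pairs Tukey HSD with the Tukey-Kramer correction for unequal n.

    For groups i, j with means m_i, m_j and sizes n_i, n_j, the statistic is

        q_ij = |m_i - m_j| / sqrt((MSW / 2) * (1/n_i + 1/n_j))

    with MSW the pooled within-group mean square, and the p-value comes from
    the studentized range distribution with k groups and N - k df.  When all
    within-group variance vanishes, p is reported as 1 for equal means and 0
    for unequal means (the limit of the test).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("tukey_hsd needs at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least two observations")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    df_within = int(ns.sum() - k)
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    msw = ssw / df_within

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        if msw > 0:
            se = np.sqrt((msw / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_within))
        else:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": diff,
                "q": q,
                "p_adj": min(max(p, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by
    default).  Raises on zero margins."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t with the degenerate conventions used throughout:
    all-zero differences -> (0, 1); zero-variance nonzero differences ->
    (inf, 0)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0.0:
        return np.inf if d.mean() > 0 else -np.inf, 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def _two_sample_t(a, b, equal_var: bool = False) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# XCU gene calling (single-cell): Model / Results
# ---------------------------------------------------------------------------


@dataclass
class XCUResults:
    """Fitted per-gene upregulation calls.

    ``table`` columns: mean_mono_active, half_ref, fold_change, p_value,
    upregulated.  A gene is upregulated iff p < alpha and fold change exceeds
    the configured gate.
    """

    table: pd.DataFrame
    alpha: float
    fc_threshold: float
    n_mono: int
    n_ref: int

    @property
    def upregulated_genes(self) -> pd.Index:
        return self.table.index[self.table["upregulated"].fillna(False)]

    @property
    def n_called(self) -> int:
        return int(self.table["upregulated"].fillna(False).sum())

    def summary(self) -> str:
        t = self.table
        tested = int(t["p_value"].notna().sum())
        lines = [
            "Upregulation calls vs half-of-biallelic reference",
            "=" * 49,
            f"genes tested:        {tested} (of {len(t)})",
            f"monosomic cells:     {self.n_mono}",
            f"reference cells:     {self.n_ref}",
            f"call rule:           p < {self.alpha:g} and FC > {self.fc_threshold:g}",
            f"upregulated genes:   {self.n_called} "
            f"({100.0 * self.n_called / max(tested, 1):.1f}% of tested)",
            f"median fold change:  {t['fold_change'].median():.3f}",
        ]
        return "\n".join(lines)


class XCUModel:
    """Gene-by-gene test of active-allele expression against half of the
    biallelic reference.

    Parameters
    ----------
    mono_values : DataFrame, genes x cells
        Active-allele TPM in cells with a single active X (or single active
        allele for the region under study).
    ref_total_values : DataFrame, genes x cells
        Total (both-allele) TPM in biallelic reference cells; the null level
        per allele is half of this.
    config : AnalysisConfig, optional
    equal_var : bool
        Pooled-variance Student's t instead of the default Welch test.
    """

    def __init__(
        self,
        mono_values: pd.DataFrame,
        ref_total_values: pd.DataFrame,
        config: Optional[AnalysisConfig] = None,
        equal_var: bool = False,
    ):
        genes = mono_values.index.intersection(ref_total_values.index)
        if len(genes) == 0:
            raise ValueError("no shared genes between groups")
        if mono_values.shape[1] < 2 or ref_total_values.shape[1] < 2:
            raise ValueError("need >= 2 observations per group")
        self.mono = mono_values.loc[genes]
        self.ref_half = ref_total_values.loc[genes] / 2.0
        self.config = _as_config(config)
        self.equal_var = equal_var

    def fit(self) -> XCUResults:
        cfg = self.config
        mono = self.mono.values
        half = self.ref_half.values
        mean_mono = mono.mean(axis=1)
        mean_half = half.mean(axis=1)
        fc = np.full(len(mean_mono), np.nan)
        pvals = np.full(len(mean_mono), np.nan)
        ok = mean_half > 0
        fc[ok] = mean_mono[ok] / mean_half[ok]
        for i in np.flatnonzero(ok):
            _, pvals[i] = _two_sample_t(mono[i], half[i], equal_var=self.equal_var)
        up = pd.array((pvals < cfg.alpha) & (fc > cfg.fc_threshold), dtype="boolean")
        up[~ok] = pd.NA
        table = pd.DataFrame(
            {
                "mean_mono_active": mean_mono,
                "half_ref": mean_half,
                "fold_change": fc,
                "p_value": pvals,
                "upregulated": up,
            },
            index=self.mono.index,
        )
        return XCUResults(
            table=table,
            alpha=cfg.alpha,
            fc_threshold=cfg.fc_threshold,
            n_mono=self.mono.shape[1],
            n_ref=self.ref_half.shape[1],
        )


def call_xcu_genes(
    mono_values: pd.DataFrame,
    xx_total_values: pd.DataFrame,
    cfg: Optional[AnalysisConfig] = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Functional wrapper around :class:`XCUModel`; returns the result table."""
    return XCUModel(mono_values, xx_total_values, cfg, equal_var=equal_var).fit().table


def select_upregulated_bulk(
    xo_cc: pd.DataFrame,
    xx_cc: pd.DataFrame,
    cfg: Optional[AnalysisConfig] = None,
) -> pd.Index:
    """Bulk upregulated-gene set: copy-corrected mean fold change > gate.

    Genes are first restricted to those expressed in the reference
    (mean copy-corrected TPM > ``expressed_min_tpm``); the call is a strict
    ``>`` on mean(xo) / mean(xx).
    """
    cfg = _as_config(cfg)
    genes = xo_cc.index.intersection(xx_cc.index)
    xx_mean = xx_cc.loc[genes].mean(axis=1)
    xo_mean = xo_cc.loc[genes].mean(axis=1)
    expressed = xx_mean > cfg.expressed_min_tpm
    fc = xo_mean[expressed] / xx_mean[expressed]
    return fc.index[fc > cfg.fc_threshold]


# ---------------------------------------------------------------------------
# Region-level tests
# ---------------------------------------------------------------------------


def test_region_compensation(
    genotype_values: Mapping[str, pd.DataFrame],
    region_name: str = "",
    method: str = "paired_t_bonferroni",
    cfg: Optional[AnalysisConfig] = None,
) -> dict:
    """Pairwise genotype comparison of per-gene mean expression in a region.

    ``genotype_values``: label -> genes x replicates DataFrame on a shared
    gene universe.  ``paired_t_bonferroni`` pairs by gene (per-gene means
    across replicates) and Bonferroni-corrects over the C(k, 2) pairs;
    ``tukey_hsd`` compares replicate-level region means.  With fewer genes
    than ``cfg.min_genes_for_test`` the test abstains (all p NA with a
    reason), mirroring the practice of not testing tiny within-deletion sets.
    """
    cfg = _as_config(cfg)
    labels = list(genotype_values)
    if len(labels) < 2:
        raise ValueError("need at least two genotypes")
    gene_sets = [set(df.index) for df in genotype_values.values()]
    shared = set.intersection(*gene_sets)
    if method == "paired_t_bonferroni" and any(s != shared for s in gene_sets):
        raise ValueError("paired test requires an identical gene universe")
    per_gene = {lab: df.loc[sorted(shared)].mean(axis=1) for lab, df in genotype_values.items()}
    result = {
        "region": region_name,
        "method": method,
        "n_genes": len(shared),
        "genotype_means": {lab: float(v.mean()) for lab, v in per_gene.items()},
        "pairs": [],
        "reason": None,
    }
    if len(shared) < cfg.min_genes_for_test:
        result["reason"] = (
            f"too few genes ({len(shared)} < {cfg.min_genes_for_test}); not tested"
        )
        for a, b in itertools.combinations(labels, 2):
            result["pairs"].append({"group_a": a, "group_b": b, "p_adj": None})
        return result

    if method == "paired_t_bonferroni":
        raw = []
        pairs = list(itertools.combinations(labels, 2))
        for a, b in pairs:
            _, p = _paired_t(per_gene[a].values, per_gene[b].values)
            raw.append(p)
        adj = adjust_pvalues(raw, method="bonferroni")
        for (a, b), p, pa in zip(pairs, raw, adj):
            result["pairs"].append(
                {"group_a": a, "group_b": b, "p_raw": float(p), "p_adj": float(pa)}
            )
    elif method == "tukey_hsd":
        groups = [df.loc[sorted(shared)].mean(axis=0).values for df in genotype_values.values()]
        tk = tukey_hsd(groups, labels=labels)
        for _, row in tk.iterrows():
            result["pairs"].append(
                {
                    "group_a": row["group_a"],
                    "group_b": row["group_b"],
                    "p_adj": float(row["p_adj"]),
                }
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return result


# ---------------------------------------------------------------------------
# Autosomal silencing and trans-upregulation
# ---------------------------------------------------------------------------


def call_silenced_genes(
    plus_dox: pd.DataFrame,
    minus_dox: pd.DataFrame,
    threshold: Optional[float] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Cis-silencing calls on the targeted allele.

    ``cis_fc`` = mean(+dox) / mean(-dox) per gene on the targeted allele;
    silenced iff cis_fc < threshold (default 0.15).  Genes with a zero
    baseline are reported NA.
    """
    cfg = _as_config(cfg)
    thr = cfg.silenced_fc_threshold if threshold is None else threshold
    genes = plus_dox.index.intersection(minus_dox.index)
    base = minus_dox.loc[genes].mean(axis=1)
    plus = plus_dox.loc[genes].mean(axis=1)
    fc = plus / base.where(base > 0)
    return pd.DataFrame(
        {"cis_fc": fc, "silenced": (fc < thr).where(fc.notna(), other=None)},
        index=genes,
    )


def define_silenced_region(
    silenced_tss: Sequence[int],
    chrom: str,
    chrom_length: int,
    window: int = 10_000_000,
    step: int = 1_000_000,
    min_density: float = 2.0,
    fallback: Optional[GenomicRegion] = None,
    detect: bool = True,
) -> Optional[GenomicRegion]:
    """Locate the contiguous region with a high density of silenced genes.

    Slides a ``window`` bp window in ``step`` bp increments; windows holding
    at least ``min_density`` silenced genes qualify, qualifying windows are
    merged, and the merged run covering the most silenced genes is returned
    (extended to the telomere when the last window qualifies).  With
    ``detect=False`` the configured ``fallback`` region is returned verbatim.
    Returns None (with nothing to merge) when no window qualifies.
    """
    if not detect:
        if fallback is None:
            raise ValueError("detect=False requires a fallback region")
        return fallback
    tss = np.sort(np.asarray(list(silenced_tss), dtype=int))
    if tss.size == 0:
        return None
    starts = np.arange(0, max(chrom_length - window, 0) + step, step)
    qual = []
    for s in starts:
        e = min(s + window, chrom_length)
        count = int(np.searchsorted(tss, e) - np.searchsorted(tss, s))
        if count >= min_density:
            qual.append((int(s), int(e)))
    if not qual:
        return None
    merged = []
    cs, ce = qual[0]
    for s, e in qual[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            merged.append((cs, ce))
            cs, ce = s, e
    merged.append((cs, ce))
    # pick the merged run containing the most silenced genes
    best = max(
        merged,
        key=lambda iv: int(np.searchsorted(tss, iv[1]) - np.searchsorted(tss, iv[0])),
    )
    start, end = best
    if end >= chrom_length - step:
        end = chrom_length
    return GenomicRegion("silenced_region", chrom, start, end)


def call_trans_upregulated(
    plus_dox: pd.DataFrame,
    minus_dox: pd.DataFrame,
    threshold: Optional[float] = None,
    scale: str = "log2",
    cfg: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Trans-allele upregulation calls after cis silencing.

    Default rule: log2(mean(+dox) / mean(-dox)) > threshold (0.5).  A
    literal linear-ratio mode (``scale='linear'``: fold change itself
    compared against the threshold) is provided for compatibility with the
    looser published phrasing; both are documented.  Zero-baseline genes are
    NA.
    """
    cfg = _as_config(cfg)
    thr = cfg.trans_log2fc_threshold if threshold is None else threshold
    genes = plus_dox.index.intersection(minus_dox.index)
    base = minus_dox.loc[genes].mean(axis=1)
    plus = plus_dox.loc[genes].mean(axis=1)
    ratio = plus / base.where(base > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(ratio)
    log2fc = log2fc.replace([np.inf, -np.inf], np.nan)
    if scale == "log2":
        called = log2fc > thr
    elif scale == "linear":
        called = ratio > thr
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return pd.DataFrame(
        {
            "trans_fc": ratio,
            "trans_log2fc": log2fc,
            "trans_upregulated": called.where(ratio.notna(), other=None),
        },
        index=genes,
    )


def compare_gene_set_proportions(
    set_a: Sequence[str],
    set_b: Sequence[str],
    annotation_set: Sequence[str],
) -> dict:
    """Compare the annotated fraction of two disjoint gene sets by 2x2
    chi-square (e.g. upregulated vs non-upregulated against escapee /
    complex-member / condensate / disease lists)."""
    a = set(set_a)
    b = set(set_b)
    ann = set(annotation_set)
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    table = [
        [len(a & ann), len(a - ann)],
        [len(b & ann), len(b - ann)],
    ]
    t = np.asarray(table)
    if (t.sum(axis=0) == 0).any():
        # every (or no) gene annotated in both sets: proportions are equal by
        # construction and the statistic degenerates to 0
        stat, p = 0.0, 1.0
    else:
        stat, p = chi_square_2x2(table)
    return {
        "proportion_a": len(a & ann) / len(a),
        "proportion_b": len(b & ann) / len(b),
        "table": table,
        "statistic": stat,
        "p_value": p,
    }
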