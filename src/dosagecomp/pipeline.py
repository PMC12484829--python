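"""End-to-end pipeline stages behind the command-line interface.

Every stage reads its inputs from, and writes its artifacts into, one output
directory, using fixed file names so stages compose:

    simulate   -> annotation.bed, sc.* / bulk.* / auto.* count bundles,
                  profiles/, proteins.tsv, coverage_allele*.bedgraph,
                  truth JSONs, markers.txt, config_used.json
    qc         -> qc_cells.tsv, qc_genotype.tsv, qc_pluripotency.tsv,
                  qc_regions.tsv
    xcu        -> xcu_calls.tsv, dosage_summary.tsv, xcu_summary.json
    region-report -> region_log2fc.tsv, region_report.json
    autosomal  -> autosomal_calls.tsv, autosomal_report.json
    protein    -> protein_results.tsv, concordance.tsv, protein_report.json
    chip       -> chip_promoter_means.tsv, chip_metaprofile.tsv,
                  chip_report.json
    report     -> report.json, summary.txt

All floats are written with fixed formatting and JSON keys are sorted, so an
identical config and seed reproduce byte-identical artifacts.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import calling, chip, proteomics, qc, simulate, stats
from .io import (
    AllelicExpressionMatrix,
    GeneAnnotation,
    GenomicRegion,
    normalize_expression,
    read_allelic_counts,
    read_copy_profile,
    read_sample_table,
    write_sample_table,
)
from .proteomics import ProteinMatrix
from .stats import AnalysisConfig

__all__ = [
    "load_config",
    "run_simulate",
    "run_qc",
    "run_xcu",
    "run_region_report",
    "run_autosomal",
    "run_protein",
    "run_chip",
    "run_report",
]

FLOAT_FMT = "%.6g"

_SIM_KEYS = {
    "pi_u", "u", "mapping_bias_b", "pi_protein_only", "protein_noise_sigma",
    "silencing_efficiency", "base_mean_log_mu", "base_mean_log_sigma",
    "library_size_cv",
}
_ANALYSIS_KEYS = {
    "trim_lower_pct", "trim_upper_pct", "expressed_min_tpm", "fc_threshold",
    "alpha", "min_genes_for_test", "silenced_fc_threshold",
    "trans_log2fc_threshold", "min_protein_xx_abundance",
}
_SIZE_KEYS = {
    "n_xx_cells", "n_xo_cast_cells", "n_xo_mus_cells", "n_xy_cells",
    "n_bulk_reps", "n_protein_reps",
}
_DEFAULT_SIZES = {
    "n_xx_cells": 40,
    "n_xo_cast_cells": 25,
    "n_xo_mus_cells": 10,
    "n_xy_cells": 25,
    "n_bulk_reps": 3,
    "n_protein_reps": 3,
}


class ConfigError(ValueError):
    """Pipeline config failed schema validation."""


def load_config(path: Optional[str]) -> dict:
    """Load and validate the YAML pipeline config (all keys optional)."""
    if path is None:
        return {}
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    allowed = _SIM_KEYS | _ANALYSIS_KEYS | _SIZE_KEYS | {"seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, val in raw.items():
        if not isinstance(val, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric, got {val!r}")
    return raw


def _analysis_config(cfg: dict) -> AnalysisConfig:
    return AnalysisConfig(**{k: cfg[k] for k in _ANALYSIS_KEYS if k in cfg})


def _config_hash(cfg: dict, seed: int) -> str:
    payload = json.dumps({"config": cfg, "seed": seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Index)):
        return list(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _require(outdir: Path, name: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing required input {name!r} in {outdir} (run the upstream "
            f"stage first)"
        )
    return p


def _read_bundle(outdir: Path, prefix: str) -> tuple[AllelicExpressionMatrix, pd.DataFrame]:
    m = read_allelic_counts(
        _require(outdir, f"{prefix}.allele1.tsv"),
        _require(outdir, f"{prefix}.allele2.tsv"),
        format="tsv",
        modality="cell" if prefix == "sc" else "bulk",
    )
    samples = read_sample_table(_require(outdir, f"{prefix}_samples.tsv"))
    return m, samples


def _profiles(outdir: Path) -> dict:
    profdir = _require(outdir, "profiles")
    return {
        p.stem: read_copy_profile(p, profile_id=p.stem)
        for p in sorted(profdir.glob("*.tsv"))
    }


def _sample_profiles(samples: pd.DataFrame, profiles: dict) -> dict:
    out = {}
    for sid, row in samples.iterrows():
        pid = row["copy_profile_id"]
        if pid not in profiles:
            raise ValueError(f"sample {sid}: unknown copy profile {pid!r}")
        out[sid] = profiles[pid]
    return out


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(outdir, seed: int, cfg: Optional[dict] = None) -> None:
    """Generate the full synthetic input bundle (single-cell, bulk deletion
    panel, autosomal silencing experiment, proteins, coverage) plus ground
    truth."""
    cfg = cfg or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = {**_DEFAULT_SIZES, **{k: int(cfg[k]) for k in _SIZE_KEYS if k in cfg}}
    sim_kw = {k: cfg[k] for k in _SIM_KEYS if k in cfg}

    # --- shared annotation (one genome for every experiment)
    sc_cfg = simulate.SimulationConfig(seed=seed, modality="cell", **sim_kw)
    ann = simulate.simulate_annotation(sc_cfg)
    ann.to_bed(outdir / "annotation.bed")
    x_len = sc_cfg.x_length()

    # --- single-cell experiment
    sc_geno = simulate.standard_genotypes(
        sc_cfg,
        n_xx=sizes["n_xx_cells"],
        n_xo_cast=sizes["n_xo_cast_cells"],
        n_xo_mus=sizes["n_xo_mus_cells"],
        n_xy=sizes["n_xy_cells"],
    )
    sc_m, sc_samples, sc_truth = simulate.simulate_allelic_counts(sc_cfg, ann, sc_geno)
    sc_m.write_tsv(outdir / "sc")
    write_sample_table(sc_samples, outdir / "sc_samples.tsv")
    sc_truth.to_json(outdir / "sc_truth.json")

    # --- bulk deletion panel (same genome, bulk noise/depth)
    bulk_cfg = simulate.SimulationConfig(seed=seed + 1, modality="bulk", **sim_kw)
    nrep = sizes["n_bulk_reps"]
    del_e = simulate.deletion_profile("chrX", 30_000_000, 60_000_000, 1, "del_e")
    del_k = simulate.deletion_profile("chrX", 100_000_000, 125_000_000, 1, "del_k")
    bulk_geno = simulate.standard_genotypes(bulk_cfg, n_xx=nrep, n_xo_cast=2,
                                            n_xy=2)
    bulk_geno += [
        simulate.GenotypeSpec("DelE", 2, del_e),
        simulate.GenotypeSpec("DelK", 2, del_k),
    ]
    bulk_m, bulk_samples, bulk_truth = simulate.simulate_allelic_counts(
        bulk_cfg, ann, bulk_geno
    )
    bulk_m.write_tsv(outdir / "bulk")
    write_sample_table(bulk_samples, outdir / "bulk_samples.tsv")
    bulk_truth.to_json(outdir / "bulk_truth.json")

    profdir = outdir / "profiles"
    profdir.mkdir(exist_ok=True)
    for spec in sc_geno + bulk_geno:
        spec.profile.intervals.to_csv(
            profdir / f"{spec.profile.profile_id}.tsv", sep="\t", index=False
        )

    # --- autosomal cis-silencing experiment (dox-inducible, chr3 analog)
    auto_cfg = simulate.SimulationConfig(seed=seed + 2, modality="bulk", **sim_kw)
    silenced = GenomicRegion("silenced", "chr3", 60_000_000, 120_000_000)
    diploid = simulate.CopyNumberProfile("diploid")
    auto_geno = [
        simulate.GenotypeSpec("dox_minus", nrep, diploid, condition="dox-"),
        simulate.GenotypeSpec(
            "dox_plus", nrep, diploid, silenced_region=silenced,
            silenced_allele=2, condition="dox+",
        ),
    ]
    auto_m, auto_samples, auto_truth = simulate.simulate_allelic_counts(
        auto_cfg, ann, auto_geno
    )
    auto_m.write_tsv(outdir / "auto")
    write_sample_table(auto_samples, outdir / "auto_samples.tsv")
    auto_truth.to_json(outdir / "auto_truth.json")

    # --- proteomics on the bulk panel
    prot, prot_samples = simulate.simulate_proteins(
        bulk_truth, bulk_cfg,
        genotype_labels=("XX", "XMusY", "XCastOMus", "DelE", "DelK"),
        n_reps=sizes["n_protein_reps"],
    )
    prot.write_tsv(outdir / "proteins.tsv")
    profile_of = {"XX": "diploid", "XMusY": "xy", "XCastOMus": "xo_cast",
                  "DelE": "del_e", "DelK": "del_k"}
    prot_samples["copy_profile_id"] = prot_samples["genotype_label"].map(profile_of)
    write_sample_table(prot_samples, outdir / "protein_samples.tsv")

    # --- allele-resolved coverage for the XO line
    tracks = simulate.simulate_coverage(sc_truth, sc_cfg, ann, "XCastOMus")
    for allele, track in tracks.items():
        chip.write_bedgraph(track, outdir / f"coverage_allele{allele}.bedgraph")

    # --- pluripotency-marker stand-ins: highly expressed autosomal genes
    base = sc_truth.base_means
    auto_genes = ann.autosomal_genes()
    markers = base.loc[auto_genes].sort_values(ascending=False).index[:3]
    (outdir / "markers.txt").write_text("\n".join(markers) + "\n")

    _write_json(
        {
            "seed": seed,
            "config": cfg,
            "config_hash": _config_hash(cfg, seed),
            "sizes": sizes,
            "chrom_plan": [list(c) for c in sc_cfg.chrom_plan],
            "x_chrom": sc_cfg.x_chrom,
            "x_length": x_len,
            "deletions": {
                "DelE": ["chrX", 30_000_000, 60_000_000],
                "DelK": ["chrX", 100_000_000, 125_000_000],
            },
            "silenced_chrom": "chr3",
        },
        outdir / "config_used.json",
    )


# ---------------------------------------------------------------------------
# qc
# ---------------------------------------------------------------------------


def run_qc(outdir, cfg: Optional[dict] = None) -> None:
    """Cell filtering, genotype sensing, pluripotency check and
    deletion-boundary inference."""
    outdir = Path(outdir)
    ann = GeneAnnotation.from_bed(_require(outdir, "annotation.bed"))
    m, samples = _read_bundle(outdir, "sc")

    filtered, report = qc.filter_min_allelic_umis(m)
    report.to_csv(outdir / "qc_cells.tsv", sep="\t", float_format=FLOAT_FMT,
                  index_label="sample_id")
    tpm = normalize_expression(filtered, "umi_tpm")
    calls = qc.classify_x_status(tpm, ann)
    calls["genotype_label"] = samples["genotype_label"].reindex(calls.index)
    calls.to_csv(outdir / "qc_genotype.tsv", sep="\t", float_format=FLOAT_FMT,
                 index_label="sample_id")

    markers = (outdir / "markers.txt").read_text().split()
    ok, table = qc.check_pluripotency(tpm, marker_genes=markers)
    table["pluripotent"] = ok
    table.to_csv(outdir / "qc_pluripotency.tsv", sep="\t",
                 float_format=FLOAT_FMT, index_label="sample_id")

    # deletion boundaries from the bulk deletion panel
    bulk_m, bulk_samples = _read_bundle(outdir, "bulk")
    bulk_tpm = normalize_expression(bulk_m, "length_tpm", annotation=ann)
    rows = []
    for label, grp in bulk_samples.groupby("genotype_label"):
        if not label.startswith("Del"):
            continue
        for hit in qc.infer_deletion_boundaries(
            bulk_tpm, ann, "chrX", samples=list(grp.index)
        ):
            rows.append({"genotype_label": label, **hit})
    pd.DataFrame(rows).to_csv(outdir / "qc_regions.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# xcu
# ---------------------------------------------------------------------------


def _monosomic_active_matrix(tpm, calls: pd.DataFrame, genes) -> pd.DataFrame:
    """Active-allele TPM for every monosomic cell (either direction)."""
    cols = {}
    for sid, row in calls.iterrows():
        if row["call"] == qc.CALL_X1:
            cols[sid] = tpm.allele1.loc[genes, sid]
        elif row["call"] == qc.CALL_X2:
            cols[sid] = tpm.allele2.loc[genes, sid]
    if not cols:
        raise ValueError("no monosomic cells after genotype sensing")
    return pd.DataFrame(cols)


def run_xcu(outdir, cfg: Optional[dict] = None) -> None:
    """Single-cell upregulated-gene calling against the half-of-XX null."""
    cfg = cfg or {}
    outdir = Path(outdir)
    acfg = _analysis_config(cfg)
    ann = GeneAnnotation.from_bed(_require(outdir, "annotation.bed"))
    m, samples = _read_bundle(outdir, "sc")
    filtered, _ = qc.filter_min_allelic_umis(m)
    tpm = normalize_expression(filtered, "umi_tpm")
    calls = qc.classify_x_status(tpm, ann)
    x_genes = ann.genes_on("chrX")
    x_genes = x_genes[x_genes.isin(tpm.gene_ids)]

    mono = _monosomic_active_matrix(tpm, calls, x_genes)
    xx_cells = calls.index[calls["call"] == qc.CALL_BIALLELIC]
    if len(xx_cells) < 2:
        raise ValueError("need >= 2 biallelic XX cells")
    results = calling.XCUModel(mono, tpm.total.loc[x_genes, xx_cells], acfg).fit()
    results.table.to_csv(outdir / "xcu_calls.tsv", sep="\t",
                         float_format=FLOAT_FMT, index_label="gene_id")

    summary = stats.dosage_summary(tpm, ann, acfg)
    summary["genotype_label"] = samples["genotype_label"].reindex(summary.index)
    summary.to_csv(outdir / "dosage_summary.tsv", sep="\t",
                   float_format=FLOAT_FMT)
    _write_json(
        {
            "n_cells_used": int(len(mono.columns) + len(xx_cells)),
            "n_monosomic": int(len(mono.columns)),
            "n_xx": int(len(xx_cells)),
            "n_genes_tested": int(results.table["p_value"].notna().sum()),
            "n_upregulated": results.n_called,
            "upregulated_genes": sorted(results.upregulated_genes),
        },
        outdir / "xcu_summary.json",
    )


# ---------------------------------------------------------------------------
# region-report
# ---------------------------------------------------------------------------


def run_region_report(outdir, cfg: Optional[dict] = None) -> None:
    """Copy-number-corrected compensation report for each deletion line."""
    cfg = cfg or {}
    outdir = Path(outdir)
    acfg = _analysis_config(cfg)
    ann = GeneAnnotation.from_bed(_require(outdir, "annotation.bed"))
    m, samples = _read_bundle(outdir, "bulk")
    tpm = normalize_expression(m, "length_tpm", annotation=ann)
    profiles = _profiles(outdir)
    sample_prof = _sample_profiles(samples, profiles)
    with open(_require(outdir, "config_used.json")) as fh:
        meta = json.load(fh)

    cc = stats.copy_number_correct(tpm.total, sample_prof, ann)
    by_geno = {lab: list(grp.index) for lab, grp in samples.groupby("genotype_label")}
    xx_cols = by_geno["XX"]
    xo_cols = by_geno["XCastOMus"]
    x_genes = ann.genes_on("chrX")
    x_genes = x_genes[x_genes.isin(cc.index)]

    up_bulk = calling.select_upregulated_bulk(
        cc.loc[x_genes, xo_cols], cc.loc[x_genes, xx_cols], acfg
    )
    xx_ref = cc.loc[x_genes, xx_cols].mean(axis=1)
    expressed = x_genes[xx_ref.reindex(x_genes) > acfg.expressed_min_tpm]

    log2fc_frames = []
    report = {"upregulated_in_xo": sorted(up_bulk), "regions": {}}
    for label, (chrom, start, end) in meta["deletions"].items():
        region = GenomicRegion(label, chrom, int(start), int(end))
        inside, outside = stats.partition_genes_by_region(ann, region)
        entry = {"chrom": chrom, "start": int(start), "end": int(end)}
        for side, genes in (("inside", inside), ("outside", outside)):
            genes = pd.Index([g for g in genes if g in expressed and g in up_bulk])
            groups = {
                "XX": cc.loc[genes, xx_cols],
                "XCastOMus": cc.loc[genes, xo_cols],
                label: cc.loc[genes, by_geno[label]],
            }
            entry[side] = {
                "n_genes": int(len(genes)),
                "mean_cc_tpm": {k: (float(v.values.mean()) if len(genes) else None)
                                for k, v in groups.items()},
            }
            if len(genes):
                entry[side]["test"] = calling.test_region_compensation(
                    groups, region_name=f"{label}_{side}",
                    method="paired_t_bonferroni", cfg=acfg,
                )
                fc = stats.per_gene_log2fc(
                    cc.loc[genes, by_geno[label]], xx_ref, acfg, clip=True
                )
                fc.insert(0, "region", label)
                fc.insert(1, "side", side)
                log2fc_frames.append(fc)
        report["regions"][label] = entry

    if log2fc_frames:
        pd.concat(log2fc_frames).to_csv(
            outdir / "region_log2fc.tsv", sep="\t", float_format=FLOAT_FMT,
            index_label="gene_id",
        )
    _write_json(report, outdir / "region_report.json")


# ---------------------------------------------------------------------------
# autosomal
# ---------------------------------------------------------------------------


def run_autosomal(outdir, cfg: Optional[dict] = None) -> None:
    """Cis-silencing and trans-upregulation calls on the dox experiment."""
    cfg = cfg or {}
    outdir = Path(outdir)
    acfg = _analysis_config(cfg)
    ann = GeneAnnotation.from_bed(_require(outdir, "annotation.bed"))
    m, samples = _read_bundle(outdir, "auto")
    tpm = normalize_expression(m, "length_tpm", annotation=ann)
    with open(_require(outdir, "config_used.json")) as fh:
        meta = json.load(fh)
    chrom = meta["silenced_chrom"]
    chrom_len = {c[0]: int(c[1]) for c in meta["chrom_plan"]}[chrom]

    plus = samples.index[samples["genotype_label"] == "dox_plus"]
    minus = samples.index[samples["genotype_label"] == "dox_minus"]
    genes = ann.genes_on(chrom)
    genes = genes[genes.isin(tpm.gene_ids)]

    sil = calling.call_silenced_genes(
        tpm.allele2.loc[genes, plus], tpm.allele2.loc[genes, minus], cfg=acfg
    )
    silenced_ids = sil.index[sil["silenced"].fillna(False).astype(bool)]
    region = calling.define_silenced_region(
        ann.df.loc[silenced_ids, "tss"].values, chrom, chrom_len
    )
    trans = calling.call_trans_upregulated(
        tpm.allele1.loc[genes, plus], tpm.allele1.loc[genes, minus], cfg=acfg
    )
    out = sil.join(trans)
    out.to_csv(outdir / "autosomal_calls.tsv", sep="\t",
               float_format=FLOAT_FMT, index_label="gene_id")

    bcfg = AnalysisConfig.bulk_autosomal(
        **{k: cfg[k] for k in _ANALYSIS_KEYS
           if k in cfg and not k.startswith("trim")}
    )
    report = {
        "silenced_chrom": chrom,
        "n_silenced": int(len(silenced_ids)),
        "silenced_region": None if region is None else
            {"chrom": region.chrom, "start": region.start, "end": region.end},
        "n_trans_upregulated": int(trans["trans_upregulated"].fillna(False).astype(bool).sum()),
    }
    if region is not None:
        inside, outside = stats.partition_genes_by_region(ann, region)
        for side, gset in (("inside", inside), ("outside", outside)):
            gset = gset[gset.isin(tpm.gene_ids)]
            report[f"{side}_mean_allele1"] = {
                "dox_minus": float(np.mean([
                    stats.trimmed_mean_expression(tpm.allele1.loc[gset, s], bcfg)
                    for s in minus
                ])),
                "dox_plus": float(np.mean([
                    stats.trimmed_mean_expression(tpm.allele1.loc[gset, s], bcfg)
                    for s in plus
                ])),
            }
    _write_json(report, outdir / "autosomal_report.json")


# ---------------------------------------------------------------------------
# protein
# ---------------------------------------------------------------------------


def run_protein(outdir, cfg: Optional[dict] = None) -> None:
    """Protein-level compensation calls and RNA-protein concordance."""
    cfg = cfg or {}
    outdir = Path(outdir)
    acfg = _analysis_config(cfg)
    ann = GeneAnnotation.from_bed(_require(outdir, "annotation.bed"))
    prot = ProteinMatrix.read_tsv(_require(outdir, "proteins.tsv"))
    prot_samples = read_sample_table(_require(outdir, "protein_samples.tsv"))
    profiles = _profiles(outdir)
    sample_prof = _sample_profiles(prot_samples, profiles)

    detected = proteomics.filter_fully_detected(prot)
    cc = proteomics.copy_number_correct_protein(detected, sample_prof, ann)
    by_geno = {lab: list(grp.index) for lab, grp in prot_samples.groupby("genotype_label")}
    groups = {k: by_geno[k] for k in ("XX", "XMusY", "XCastOMus")}
    results, up = proteomics.differential_protein_abundance(
        cc.select_proteins(
            cc.protein_ids[cc.genes().isin(ann.genes_on("chrX"))]
        ),
        groups, reference="XX", cfg=acfg,
    )
    results.to_csv(outdir / "protein_results.tsv", sep="\t",
                   float_format=FLOAT_FMT, index_label="protein_id")

    # RNA fold changes (copy-corrected XO/XX) from the bulk panel
    bulk_m, bulk_samples = _read_bundle(outdir, "bulk")
    tpm = normalize_expression(bulk_m, "length_tpm", annotation=ann)
    bulk_prof = _sample_profiles(bulk_samples, profiles)
    rna_cc = stats.copy_number_correct(tpm.total, bulk_prof, ann)
    xx = bulk_samples.index[bulk_samples["genotype_label"] == "XX"]
    xo = bulk_samples.index[bulk_samples["genotype_label"] == "XCastOMus"]
    rna_fc = rna_cc[xo].mean(axis=1) / rna_cc[xx].mean(axis=1).where(
        rna_cc[xx].mean(axis=1) > 0
    )
    prot_fc = (
        cc.abundances[by_geno["XCastOMus"]].mean(axis=1)
        / cc.abundances[by_geno["XX"]].mean(axis=1)
    )
    prot_fc.index = cc.genes().values
    x_genes = ann.genes_on("chrX")
    conc = proteomics.classify_rna_protein_concordance(
        rna_fc[rna_fc.index.isin(x_genes)], prot_fc[prot_fc.index.isin(x_genes)]
    )
    conc["records"].to_csv(outdir / "concordance.tsv", sep="\t",
                           float_format=FLOAT_FMT, index_label="gene_id")
    _write_json(
        {
            "n_proteins_detected_all": int(len(detected.protein_ids)),
            "n_x_proteins_tested": int(results["up"].notna().sum()),
            "n_upregulated": int(len(up)),
            "upregulated_proteins": sorted(up),
            "concordance_counts": {k: int(v) for k, v in conc["counts"].items()},
            "pearson_r_log2fc": conc["pearson_r_log2fc"],
        },
        outdir / "protein_report.json",
    )


# ---------------------------------------------------------------------------
# chip
# ---------------------------------------------------------------------------


def run_chip(outdir, cfg: Optional[dict] = None) -> None:
    """Allele-resolved promoter quantification and gene-set contrast."""
    cfg = cfg or {}
    outdir = Path(outdir)
    ann = GeneAnnotation.from_bed(_require(outdir, "annotation.bed"))
    xcu_path = _require(outdir, "xcu_summary.json")
    with open(xcu_path) as fh:
        up_set = set(json.load(fh)["upregulated_genes"])

    tracks = {}
    for allele in (1, 2):
        raw = chip.read_bedgraph(
            _require(outdir, f"coverage_allele{allele}.bedgraph"),
            allele=f"allele{allele}",
        )
        total = sum(cum[-1] for cum in raw._cum.values())
        tracks[allele] = chip.cp10m_scale(raw, total)

    x_ann = ann.on_chrom("chrX")
    promoters = [
        chip.promoter_region(row) for _, row in x_ann.df.iterrows()
    ]
    means = pd.DataFrame(
        {
            f"allele{a}": chip.region_mean_signal(tracks[a], promoters).values
            for a in (1, 2)
        },
        index=x_ann.gene_ids,
    )
    means.to_csv(outdir / "chip_promoter_means.tsv", sep="\t",
                 float_format=FLOAT_FMT, index_label="gene_id")

    up_ids = means.index[means.index.isin(up_set)]
    non_ids = means.index[~means.index.isin(up_set)]
    contrast = chip.compare_gene_sets(
        {"promoter_allele2": (means.loc[up_ids, "allele2"],
                              means.loc[non_ids, "allele2"])}
    )
    profile = chip.metaprofile(tracks[2], x_ann.subset(up_ids), gene_set="upregulated")
    profile.to_frame().to_csv(outdir / "chip_metaprofile.tsv", sep="\t",
                              float_format=FLOAT_FMT, index=False)
    _write_json(
        {
            "n_up": int(len(up_ids)),
            "n_non_up": int(len(non_ids)),
            "contrast_p_adj": float(contrast["p_adj"].iloc[0]),
            "metaprofile_bins": int(profile.n_bins),
        },
        outdir / "chip_report.json",
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def run_report(outdir, cfg: Optional[dict] = None, seed: Optional[int] = None) -> None:
    """Aggregate stage outputs and score calls against simulation truth."""
    cfg = cfg or {}
    outdir = Path(outdir)
    with open(_require(outdir, "config_used.json")) as fh:
        meta = json.load(fh)
    report = {"config_hash": meta["config_hash"], "stages": {}}

    sc_truth = simulate.SimulationTruth.from_json(_require(outdir, "sc_truth.json"))
    with open(_require(outdir, "xcu_summary.json")) as fh:
        xcu_summary = json.load(fh)
    ann = GeneAnnotation.from_bed(_require(outdir, "annotation.bed"))
    x_genes = set(ann.genes_on(meta["x_chrom"]))
    true_up = set(sc_truth.compensated_gene_ids) & x_genes
    called = set(xcu_summary["upregulated_genes"])
    tp = len(called & true_up)
    report["stages"]["xcu"] = {
        **{k: v for k, v in xcu_summary.items() if k != "upregulated_genes"},
        "sensitivity_vs_truth": tp / len(true_up) if true_up else None,
        "precision_vs_truth": tp / len(called) if called else None,
    }
    for stage, name in (
        ("region_report", "region_report.json"),
        ("autosomal", "autosomal_report.json"),
        ("protein", "protein_report.json"),
        ("chip", "chip_report.json"),
    ):
        p = outdir / name
        if p.exists():
            with open(p) as fh:
                report["stages"][stage] = json.load(fh)
    _write_json(report, outdir / "report.json")

    lines = [
        "dosagecomp pipeline report",
        f"config hash: {report['config_hash']}",
        "",
        f"XCU calling: {report['stages']['xcu']['n_upregulated']} upregulated "
        f"of {report['stages']['xcu']['n_genes_tested']} X-linked genes tested",
        f"  sensitivity vs truth: {report['stages']['xcu']['sensitivity_vs_truth']:.3f}",
        f"  precision vs truth:   {report['stages']['xcu']['precision_vs_truth']:.3f}",
    ]
    if "protein" in report["stages"]:
        pr = report["stages"]["protein"]
        lines.append(
            f"Protein: {pr['n_upregulated']} upregulated of "
            f"{pr['n_x_proteins_tested']} X-linked proteins; RNA-protein "
            f"log2FC r = {pr['pearson_r_log2fc']:.3f}"
        )
    if "autosomal" in report["stages"]:
        au = report["stages"]["autosomal"]
        lines.append(
            f"Autosomal: {au['n_silenced']} silenced genes, "
            f"{au['n_trans_upregulated']} trans-upregulated on {au['silenced_chrom']}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
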