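"""Synthetic allele-resolved datasets with known ground truth.

The generator emulates the downstream shape of allele-split expression data
from hybrid (Mus x Cast) mouse pluripotent stem cells: UMI or read counts per
gene per parental allele, across genotypes such as biallelic XX, X-monosomies
in either direction, XY, heterozygous segmental deletions, and dox-inducible
cis silencing of one autosomal allele.  Allele 1 plays the role of the Mus
allele (and carries the reference-mapping bias), allele 2 the Cast allele.

Data-generating model, per gene g, sample s, allele a:

    mu_{gsa} = base_g * copies_{ga} * b^{[a=1]} * e_{ga} * u^{[upregulated]} * f_s
    count    ~ NegativeBinomial(mean=mu, variance=mu + alpha * mu^2)

where ``base_g`` is log-normal across genes, ``copies`` come from the
genotype's copy-number profile, ``b`` is the allele-1 mapping bias,
``e_{ga}`` is the residual activity of a cis-silenced allele, ``u`` is the
dosage-compensation factor applied to the remaining active allele of a
compensated gene whenever the gene is monoallelically expressed in that
genotype, and ``f_s`` is a per-sample library-size factor.  Compensation is
modeled as mean scaling; the analysis only observes means, so transcriptional
burst mechanics are deliberately out of scope.

All randomness derives from ``config.seed`` through named
``numpy.random.SeedSequence`` children, so every artifact is byte-identical
under an identical config.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    AllelicExpressionMatrix,
    CopyNumberProfile,
    GeneAnnotation,
    GenomicRegion,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "GenotypeSpec",
    "monosomy_profile",
    "deletion_profile",
    "standard_genotypes",
    "simulate_annotation",
    "simulate_allelic_counts",
    "simulate_proteins",
    "simulate_coverage",
]

# Stream labels for SeedSequence spawn keys: stable, order-independent.
_STREAM = {"annotation": 1, "truth": 2, "counts": 3, "proteins": 4, "coverage": 5}


@dataclass
class GenotypeSpec:
    """One simulated genotype: label, group size and allele copy profile.

    ``silenced_region`` models dox-inducible cis silencing: genes whose TSS
    lies in the region have their ``silenced_allele`` mean multiplied by the
    config's ``silencing_efficiency`` (copies are untouched -- silencing is
    transcriptional, not genetic).
    """

    label: str
    n: int
    profile: CopyNumberProfile
    silenced_region: Optional[GenomicRegion] = None
    silenced_allele: int = 2
    condition: str = ""


@dataclass
class SimulationConfig:
    """Parameters of the generative model.  Defaults are the study conditions.

    ``base_mean_log_mu``/``base_mean_log_sigma``: natural-log parameters of
    the per-gene base expression (log-normal across genes; sigma 1.0 gives a
    realistically long-tailed expression distribution).
    ``nb_dispersion``: alpha in variance = mu + alpha mu^2 (0.3 for UMI
    single-cell data, 0.05 for bulk, chosen per modality when left None).
    ``library_size_mean``: expected total counts per sample over both alleles
    (1e5 for cells -- comfortably above the 10k-per-allele QC gate -- and 5e6
    for bulk when left None).
    ``pi_u``: fraction of genes designated dosage-compensated; ``u``: the
    upregulation factor on the remaining active allele under monoallelic
    expression.  ``mapping_bias_b``: multiplicative bias on allele-1 (Mus)
    means.  ``pi_protein_only``: fraction of non-RNA-compensated genes
    compensated at the protein level only.  ``protein_noise_sigma``: standard
    deviation of log2 protein abundance noise between replicates.
    ``silencing_efficiency``: residual activity of a cis-silenced allele.
    """

    seed: int = 0
    # ~10:1 autosomal:X gene ratio, mirroring the downstream shape of real
    # allele-resolved data (hundreds of X-linked vs ~12k autosomal genes).
    # An X-heavy genome would let library renormalization masquerade as
    # upregulation after one X allele is lost.
    chrom_plan: tuple = (
        ("chr1", 120_000_000, 800),
        ("chr2", 120_000_000, 800),
        ("chr3", 120_000_000, 800),
        ("chr4", 120_000_000, 800),
        ("chr5", 120_000_000, 800),
        ("chrX", 160_000_000, 400),
    )
    modality: str = "cell"
    base_mean_log_mu: float = 1.0
    base_mean_log_sigma: float = 1.0
    nb_dispersion: Optional[float] = None
    library_size_mean: Optional[float] = None
    library_size_cv: float = 0.3
    pi_u: float = 0.4
    u: float = 2.0
    mapping_bias_b: float = 1.05
    pi_protein_only: float = 0.3
    protein_noise_sigma: float = 0.3
    protein_scale: float = 5e6
    protein_detection_limit: float = 1e6
    silencing_efficiency: float = 0.1
    compensated_gene_ids: Optional[tuple] = None
    min_gene_gap: int = 2500
    coverage_background: float = 1.0
    coverage_gain: float = 1.0
    coverage_noise_sd: float = 0.5
    x_chrom: str = "chrX"

    def __post_init__(self):
        if not (0.0 <= self.pi_u <= 1.0):
            raise ValueError("pi_u must be in [0, 1]")
        if not (0.0 <= self.pi_protein_only <= 1.0):
            raise ValueError("pi_protein_only must be in [0, 1]")
        if self.u < 1.0:
            raise ValueError("u must be >= 1")
        if self.nb_dispersion is not None and self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not self.chrom_plan:
            raise ValueError("chrom_plan must be non-empty")

    @property
    def dispersion(self) -> float:
        if self.nb_dispersion is not None:
            return self.nb_dispersion
        return 0.3 if self.modality == "cell" else 0.05

    @property
    def library_size(self) -> float:
        if self.library_size_mean is not None:
            return self.library_size_mean
        return 1e5 if self.modality == "cell" else 5e6

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAM[stream],))
        return np.random.default_rng(ss)

    def x_length(self) -> int:
        for chrom, length, _n in self.chrom_plan:
            if chrom == self.x_chrom:
                return int(length)
        raise ValueError(f"{self.x_chrom} not in chrom_plan")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every simulated dataset."""

    compensated_gene_ids: tuple
    protein_only_compensated_ids: tuple
    silenced_gene_ids: dict  # genotype label -> tuple of gene ids
    deleted_intervals: dict  # genotype label -> list of interval dicts
    base_means: pd.Series
    expected_allele_mean: dict  # genotype label -> DataFrame genes x [allele1, allele2]
    monoallelic: pd.DataFrame  # genes x genotype labels, bool

    def expected_total_mean(self, label: str) -> pd.Series:
        df = self.expected_allele_mean[label]
        return df["allele1"] + df["allele2"]

    def to_json(self, path) -> None:
        import json

        payload = {
            "compensated_gene_ids": list(self.compensated_gene_ids),
            "protein_only_compensated_ids": list(self.protein_only_compensated_ids),
            "silenced_gene_ids": {k: list(v) for k, v in self.silenced_gene_ids.items()},
            "deleted_intervals": self.deleted_intervals,
            "base_means": self.base_means.to_dict(),
            "expected_allele_mean": {
                k: df.to_dict(orient="index") for k, df in self.expected_allele_mean.items()
            },
            "monoallelic": {
                c: self.monoallelic[c].astype(bool).to_dict() for c in self.monoallelic.columns
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        base = pd.Series(payload["base_means"], dtype=float)
        base = base.loc[sorted(base.index)]
        eam = {
            k: pd.DataFrame.from_dict(v, orient="index").reindex(base.index)
            for k, v in payload["expected_allele_mean"].items()
        }
        mono = pd.DataFrame(
            {k: pd.Series(v) for k, v in payload["monoallelic"].items()}
        ).reindex(base.index).fillna(False)
        return cls(
            compensated_gene_ids=tuple(payload["compensated_gene_ids"]),
            protein_only_compensated_ids=tuple(payload["protein_only_compensated_ids"]),
            silenced_gene_ids={k: tuple(v) for k, v in payload["silenced_gene_ids"].items()},
            deleted_intervals=payload["deleted_intervals"],
            base_means=base,
            expected_allele_mean=eam,
            monoallelic=mono,
        )


# ---------------------------------------------------------------------------
# Genotype helpers
# ---------------------------------------------------------------------------


def monosomy_profile(lost_allele: int, x_chrom: str, x_length: int,
                     profile_id: str) -> CopyNumberProfile:
    """Whole-X loss of one allele (XO in either direction, or the single X
    of an XY male where allele 2 stands in for the missing homolog)."""
    c1, c2 = (0, 1) if lost_allele == 1 else (1, 0)
    iv = pd.DataFrame(
        [[x_chrom, 0, x_length, c1, c2]],
        columns=["chrom", "start", "end", "copies_allele1", "copies_allele2"],
    )
    return CopyNumberProfile(profile_id, iv)


def deletion_profile(chrom: str, start: int, end: int, deleted_allele: int,
                     profile_id: str) -> CopyNumberProfile:
    """Heterozygous segmental deletion on one allele."""
    c1, c2 = (0, 1) if deleted_allele == 1 else (1, 0)
    iv = pd.DataFrame(
        [[chrom, start, end, c1, c2]],
        columns=["chrom", "start", "end", "copies_allele1", "copies_allele2"],
    )
    return CopyNumberProfile(profile_id, iv)


def standard_genotypes(
    config: SimulationConfig,
    n_xx: int = 60,
    n_xo_cast: int = 40,
    n_xo_mus: int = 0,
    n_xy: int = 0,
) -> list[GenotypeSpec]:
    """The study's core genotype panel.

    ``XCastOMus`` lost the Mus X (allele 1), leaving Cast active;
    ``XMusOCast`` and ``XMusY`` have only the Mus X (allele 2 absent).
    """
    x_len = config.x_length()
    specs = [GenotypeSpec("XX", n_xx, CopyNumberProfile("diploid"))]
    if n_xo_cast:
        specs.append(
            GenotypeSpec(
                "XCastOMus", n_xo_cast,
                monosomy_profile(1, config.x_chrom, x_len, "xo_cast"),
            )
        )
    if n_xo_mus:
        specs.append(
            GenotypeSpec(
                "XMusOCast", n_xo_mus,
                monosomy_profile(2, config.x_chrom, x_len, "xo_mus"),
            )
        )
    if n_xy:
        specs.append(
            GenotypeSpec(
                "XMusY", n_xy, monosomy_profile(2, config.x_chrom, x_len, "xy"),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Place non-overlapping genes uniformly at random along each chromosome.

    Genes are kept at least ``config.min_gene_gap`` bp apart so 1 kb promoter
    windows of neighboring genes never collide.
    """
    rng = config.rng("annotation")
    rows = []
    for chrom, length, n_genes in config.chrom_plan:
        length = int(length)
        n_genes = int(n_genes)
        if n_genes == 0:
            continue
        gene_lens = rng.integers(2_000, 20_001, size=n_genes)
        gap = config.min_gene_gap
        slack = length - int(gene_lens.sum()) - gap * (n_genes + 1)
        if slack < 0:
            raise ValueError(f"{chrom}: {n_genes} genes do not fit in {length} bp")
        w = rng.random(n_genes + 1)
        gaps = gap + np.floor(w / w.sum() * slack).astype(int)
        pos = 0
        strands = rng.choice(["+", "-"], size=n_genes)
        for i in range(n_genes):
            pos += gaps[i]
            start, end = pos, pos + int(gene_lens[i])
            rows.append((f"{chrom}_g{i:04d}", chrom, start, end, strands[i]))
            pos = end
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(df.set_index("gene_id"))


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _activity(config: SimulationConfig, spec: GenotypeSpec,
              annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-gene per-allele mean multiplier (copies x silencing residual)."""
    copies = spec.profile.copies_for(annotation)
    act = copies[["copies_allele1", "copies_allele2"]].astype(float)
    act.columns = ["allele1", "allele2"]
    if spec.silenced_region is not None:
        tss = annotation.df["tss"]
        in_region = spec.silenced_region.contains(
            spec.silenced_region.chrom, tss
        ) & (annotation.df["chrom"] == spec.silenced_region.chrom)
        col = f"allele{spec.silenced_allele}"
        act.loc[in_region, col] *= config.silencing_efficiency
    return act


def _silenced_ids(spec: GenotypeSpec, annotation: GeneAnnotation) -> tuple:
    if spec.silenced_region is None:
        return ()
    df = annotation.df
    mask = (df["chrom"] == spec.silenced_region.chrom) & (
        df["tss"] >= spec.silenced_region.start
    ) & (df["tss"] < spec.silenced_region.end)
    return tuple(df.index[mask])


def simulate_allelic_counts(
    config: SimulationConfig,
    annotation: Optional[GeneAnnotation] = None,
    genotypes: Optional[Sequence[GenotypeSpec]] = None,
):
    """Draw allele-split counts for every genotype in the panel.

    Returns ``(matrix, sample_table, truth)``.  The expected per-allele means
    recorded in the truth object exclude the library factor, i.e. they are on
    the base-expression scale shared by all samples.
    """
    if annotation is None:
        annotation = simulate_annotation(config)
    if genotypes is None:
        genotypes = standard_genotypes(config)
    labels = [g.label for g in genotypes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genotype labels")

    genes = annotation.gene_ids
    rng_truth = config.rng("truth")
    base = pd.Series(
        rng_truth.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma,
                            size=len(genes)),
        index=genes, name="base_mean",
    )
    if config.compensated_gene_ids is not None:
        unknown = set(config.compensated_gene_ids) - set(genes)
        if unknown:
            raise ValueError(f"compensated_gene_ids not in annotation: {sorted(unknown)}")
        comp = genes.isin(config.compensated_gene_ids)
    else:
        comp = rng_truth.random(len(genes)) < config.pi_u
    comp = pd.Series(comp, index=genes)
    # Protein-only compensation: drawn among genes NOT compensated at RNA level.
    ponly = pd.Series(
        (~comp.values) & (rng_truth.random(len(genes)) < config.pi_protein_only),
        index=genes,
    )

    rng = config.rng("counts")
    disp = config.dispersion
    sigma_l = np.sqrt(np.log1p(config.library_size_cv ** 2))

    expected_allele_mean: dict[str, pd.DataFrame] = {}
    monoallelic = {}
    silenced = {}
    deleted = {}
    blocks1, blocks2, sample_rows = [], [], []

    for spec in genotypes:
        act = _activity(config, spec, annotation)
        mu = pd.DataFrame(
            {
                "allele1": base.values * act["allele1"].values * config.mapping_bias_b,
                "allele2": base.values * act["allele2"].values,
            },
            index=genes,
        )
        # A gene is monoallelically expressed when exactly one allele retains
        # full activity (the other lost or silenced); compensation then boosts
        # the remaining active allele by u.
        full1 = act["allele1"].values == 1.0
        full2 = act["allele2"].values == 1.0
        mono = full1 ^ full2
        up = comp.values & mono
        mu.loc[up & full1, "allele1"] *= config.u
        mu.loc[up & full2, "allele2"] *= config.u
        expected_allele_mean[spec.label] = mu
        monoallelic[spec.label] = pd.Series(mono, index=genes)
        silenced[spec.label] = _silenced_ids(spec, annotation)
        deleted[spec.label] = [
            {
                "chrom": iv["chrom"],
                "start": int(iv["start"]),
                "end": int(iv["end"]),
                "copies_allele1": int(iv["copies_allele1"]),
                "copies_allele2": int(iv["copies_allele2"]),
            }
            for _, iv in spec.profile.intervals.iterrows()
        ]

        total_mu = float(mu.values.sum())
        if total_mu <= 0:
            raise ValueError(f"genotype {spec.label}: all-zero expected expression")
        for rep in range(spec.n):
            sid = f"{spec.label}_{rep:03d}"
            lib = config.library_size / total_mu * rng.lognormal(
                -0.5 * sigma_l ** 2, sigma_l
            )
            m1 = mu["allele1"].values * lib
            m2 = mu["allele2"].values * lib
            if disp > 0:
                r = 1.0 / disp
                c1 = rng.negative_binomial(r, r / (r + np.maximum(m1, 1e-300)))
                c2 = rng.negative_binomial(r, r / (r + np.maximum(m2, 1e-300)))
                c1 = np.where(m1 > 0, c1, 0)
                c2 = np.where(m2 > 0, c2, 0)
            else:
                c1 = rng.poisson(m1)
                c2 = rng.poisson(m2)
            blocks1.append(c1)
            blocks2.append(c2)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "genotype_label": spec.label,
                    "condition": spec.condition,
                    "replicate": rep,
                    "copy_profile_id": spec.profile.profile_id,
                }
            )

    sample_table = pd.DataFrame(sample_rows).set_index("sample_id")
    a1 = pd.DataFrame(np.column_stack(blocks1), index=genes, columns=sample_table.index)
    a2 = pd.DataFrame(np.column_stack(blocks2), index=genes, columns=sample_table.index)
    matrix = AllelicExpressionMatrix(a1, a2, unit="raw_count", modality=config.modality)
    truth = SimulationTruth(
        compensated_gene_ids=tuple(genes[comp.values]),
        protein_only_compensated_ids=tuple(genes[ponly.values]),
        silenced_gene_ids=silenced,
        deleted_intervals=deleted,
        base_means=base,
        expected_allele_mean=expected_allele_mean,
        monoallelic=pd.DataFrame(monoallelic),
    )
    return matrix, sample_table, truth


# ---------------------------------------------------------------------------
# Proteins
# ---------------------------------------------------------------------------


def simulate_proteins(
    truth: SimulationTruth,
    config: SimulationConfig,
    genotype_labels: Sequence[str] = ("XX", "XMusY", "XCastOMus"),
    n_reps: int = 3,
):
    """Protein abundances proportional to total RNA output, with log2-normal
    replicate noise and an extra factor ``u`` for protein-only-compensated
    genes in monoallelic genotypes.

    Returns ``(ProteinMatrix, sample_table)``.  Abundances below
    ``config.protein_detection_limit`` are flagged undetected (NaN).
    """
    from .proteomics import ProteinMatrix

    for label in genotype_labels:
        if label not in truth.expected_allele_mean:
            raise ValueError(f"genotype {label!r} not present in RNA truth")
    rng = config.rng("proteins")
    genes = truth.base_means.index
    ponly = genes.isin(truth.protein_only_compensated_ids)

    cols, data, rows = [], [], []
    for label in genotype_labels:
        # mass spectrometry has no read-mapping step, so the allele-1
        # reference-mapping bias baked into the RNA means is removed here
        eam = truth.expected_allele_mean[label]
        total = (
            eam["allele1"].values / config.mapping_bias_b + eam["allele2"].values
        )
        boost = ponly & truth.monoallelic[label].values
        total = total * np.where(boost, config.u, 1.0)
        for rep in range(n_reps):
            sid = f"{label}_P{rep}"
            noise = rng.normal(0.0, config.protein_noise_sigma, size=len(genes))
            ab = config.protein_scale * total * np.exp2(noise)
            data.append(ab)
            cols.append(sid)
            rows.append({"sample_id": sid, "genotype_label": label, "replicate": rep})
    abundances = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index([f"P_{g}" for g in genes], name="protein_id"),
        columns=cols,
    )
    detected = abundances >= config.protein_detection_limit
    abundances = abundances.where(detected)
    gene_map = pd.Series(genes, index=abundances.index, name="gene_id")
    sample_table = pd.DataFrame(rows).set_index("sample_id")
    return ProteinMatrix(abundances, gene_map, detected=detected), sample_table


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def simulate_coverage(
    truth: SimulationTruth,
    config: SimulationConfig,
    annotation: GeneAnnotation,
    genotype_label: str,
    alleles: Sequence[int] = (1, 2),
    promoter_upstream: int = 1000,
):
    """Per-allele coverage tracks with promoter signal tied to expression.

    Each gene's 1 kb upstream promoter window carries
    ``background + gain * allelic_mean + noise`` (noise Gaussian truncated at
    zero); everything else sits at the flat background.  Returns a dict
    ``allele number -> CoverageTrack``.
    """
    from .chip import CoverageTrack, promoter_region

    if genotype_label not in truth.expected_allele_mean:
        raise ValueError(f"genotype {genotype_label!r} not present in truth")
    rng = config.rng("coverage")
    means = truth.expected_allele_mean[genotype_label]
    chrom_len = {chrom: int(length) for chrom, length, _ in config.chrom_plan}

    tracks = {}
    for allele in alleles:
        per_chrom = {}
        col = f"allele{allele}"
        for chrom, length in chrom_len.items():
            sub = annotation.df[annotation.df["chrom"] == chrom]
            promoters = []
            for gid, row in sub.iterrows():
                reg = promoter_region(row, upstream=promoter_upstream,
                                      chrom_length=length)
                signal = config.coverage_background + config.coverage_gain * float(
                    means.at[gid, col]
                ) + rng.normal(0.0, config.coverage_noise_sd)
                promoters.append((reg.start, reg.end, max(signal, 0.0)))
            promoters.sort()
            starts, ends, values = [], [], []
            pos = 0
            for s, e, v in promoters:
                if s > pos:
                    starts.append(pos)
                    ends.append(s)
                    values.append(config.coverage_background)
                starts.append(s)
                ends.append(e)
                values.append(v)
                pos = e
            if pos < length:
                starts.append(pos)
                ends.append(length)
                values.append(config.coverage_background)
            per_chrom[chrom] = (
                np.asarray(starts, dtype=float),
                np.asarray(ends, dtype=float),
                np.asarray(values, dtype=float),
            )
        tracks[allele] = CoverageTrack(per_chrom, allele=col, normalization="raw")
    return tracks
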