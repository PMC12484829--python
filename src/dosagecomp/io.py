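"""Readers, writers and normalization for allele-resolved expression data.

Everything downstream operates on a small set of in-memory containers:

* :class:`GeneAnnotation` -- per-gene coordinates, strand, TSS/TES, length.
* :class:`AllelicExpressionMatrix` -- paired genes x samples matrices, one per
  parental allele, plus an optional unassigned matrix.
* :class:`CopyNumberProfile` -- per-allele copy intervals (heterozygous
  deletions, whole-chromosome monosomy).
* :class:`GenomicRegion` -- a named interval (deletion segment, silenced
  region, promoter, ...).

Internal coordinates are 0-based half-open (BED convention) everywhere;
conversion to/from 1-based inclusive GFF3 happens only at the I/O boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GeneAnnotation",
    "AllelicExpressionMatrix",
    "CopyNumberProfile",
    "GenomicRegion",
    "read_gene_annotation",
    "read_allelic_counts",
    "read_copy_profile",
    "read_regions",
    "read_coverage",
    "read_sample_table",
    "write_sample_table",
    "normalize_expression",
]

# Matrix unit tags; changed only by normalization operations.
UNIT_RAW = "raw_count"
UNIT_TPM = "tpm"
UNIT_CP10M = "cp10m"


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


class GeneAnnotation:
    """Per-gene genomic annotation.

    Wraps a DataFrame indexed by gene id with columns ``chrom``, ``start``,
    ``end`` (0-based half-open), ``strand`` (+/-), and derived ``tss``,
    ``tes`` and ``length``.  ``length`` is the exonic length when the source
    provided one, otherwise the genomic span.
    """

    COLUMNS = ("chrom", "start", "end", "strand", "tss", "tes", "length")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dups}")
        for col in ("chrom", "start", "end", "strand"):
            if col not in df.columns:
                raise ValueError(f"annotation missing column {col!r}")
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            raise ParseError(f"start >= end for genes {bad.tolist()}")
        bad = df.index[~df["strand"].isin(["+", "-"])]
        if len(bad):
            raise ParseError(f"missing/invalid strand for genes {bad.tolist()}")
        plus = df["strand"] == "+"
        df["tss"] = np.where(plus, df["start"], df["end"])
        df["tes"] = np.where(plus, df["end"], df["start"])
        if "length" not in df.columns or df["length"].isna().any():
            df["length"] = df["end"] - df["start"]
        df = df[list(self.COLUMNS)]
        df.index.name = "gene_id"
        self.df = df

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        """Read a BED file (>= 6 columns: chrom start end name score strand).

        BED is 0-based half-open; coordinates are taken verbatim.
        """
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ParseError(
                        f"{path}:{lineno}: BED line needs >= 6 columns "
                        f"(chrom start end name score strand), got {len(parts)}"
                    )
                chrom, start, end, name, _score, strand = parts[:6]
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: missing strand")
                rows.append((name, chrom, start_i, end_i, strand))
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        return cls(df.set_index("gene_id"))

    @classmethod
    def from_gff3(cls, path, feature: str = "gene") -> "GeneAnnotation":
        """Read gene records from GFF3 (1-based inclusive -> internal 0-based).

        Gene ids come from the ``ID=`` or ``gene_id=`` attribute.  If exon
        features with ``Parent=`` attributes are present, per-gene exonic
        length is computed as the summed exon span.
        """
        names = ["chrom", "source", "type", "start", "end", "score", "strand",
                 "phase", "attributes"]
        try:
            raw = pd.read_csv(path, sep="\t", comment="#", header=None,
                              names=names, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"{path}: {exc}") from exc
        if raw.empty:
            return cls(pd.DataFrame(columns=["chrom", "start", "end", "strand"]))
        genes = raw[raw["type"] == feature].copy()
        if genes.empty:
            raise ParseError(f"{path}: no {feature!r} features found")
        if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
            raise ParseError(f"{path}: {feature} record with missing strand")
        ids = genes["attributes"].map(_gff3_id)
        if ids.isna().any():
            raise ParseError(f"{path}: {feature} record without ID/gene_id attribute")
        df = pd.DataFrame(
            {
                "chrom": genes["chrom"].values,
                # GFF3 1-based inclusive -> 0-based half-open
                "start": genes["start"].astype(int).values - 1,
                "end": genes["end"].astype(int).values,
                "strand": genes["strand"].values,
            },
            index=pd.Index(ids.values, name="gene_id"),
        )
        exons = raw[raw["type"] == "exon"]
        if len(exons):
            parent = exons["attributes"].str.extract(r"Parent=([^;]+)", expand=False)
            span = exons["end"].astype(int) - (exons["start"].astype(int) - 1)
            exonic = span.groupby(parent).sum()
            df["length"] = exonic.reindex(df.index)
        return cls(df)

    # -- writers ------------------------------------------------------------

    def to_bed(self, path) -> None:
        out = self.df.reset_index()
        out["score"] = 0
        out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid, row in self.df.iterrows():
                fh.write(
                    f"{row.chrom}\tdosagecomp\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={gid}\n"
                )

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    def on_chrom(self, chrom: str) -> "GeneAnnotation":
        return GeneAnnotation(self.df[self.df["chrom"] == chrom])

    def genes_on(self, chrom: str) -> pd.Index:
        return self.df.index[self.df["chrom"] == chrom]

    def autosomal_genes(self, x_chrom: str = "chrX",
                        exclude: Sequence[str] = ("chrY", "chrM")) -> pd.Index:
        drop = set(exclude) | {x_chrom}
        return self.df.index[~self.df["chrom"].isin(drop)]

    def subset(self, gene_ids) -> "GeneAnnotation":
        return GeneAnnotation(self.df.loc[list(gene_ids)])

    def sorted_by_position(self) -> "GeneAnnotation":
        return GeneAnnotation(self.df.sort_values(["chrom", "tss", "start"]))


def _gff3_id(attrs: str) -> Optional[str]:
    if not isinstance(attrs, str):
        return None
    m = re.search(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)", attrs)
    return m.group(1).strip() if m else None


def read_gene_annotation(path, format: str = "bed") -> GeneAnnotation:
    """Read gene annotation in ``bed`` or ``gff3`` dialect."""
    if format == "bed":
        return GeneAnnotation.from_bed(path)
    if format == "gff3":
        return GeneAnnotation.from_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Genomic regions and copy-number profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicRegion:
    """A named half-open genomic interval."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.name}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos) -> bool | np.ndarray:
        return (chrom == self.chrom) & (pos >= self.start) & (pos < self.end)


def read_regions(path) -> list[GenomicRegion]:
    """Read named regions from a 4-column BED-like file."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: need chrom start end name")
            try:
                regions.append(GenomicRegion(parts[3], parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


@dataclass
class CopyNumberProfile:
    """Per-allele copy-number intervals; copies default to 1 outside intervals.

    ``intervals`` columns: chrom, start, end, copies_allele1, copies_allele2,
    each copy count in {0, 1}.  Intervals must not overlap within a chromosome.
    """

    profile_id: str
    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "copies_allele1", "copies_allele2"]
        )
    )

    def __post_init__(self):
        iv = self.intervals.reset_index(drop=True).copy()
        need = ["chrom", "start", "end", "copies_allele1", "copies_allele2"]
        for col in need:
            if col not in iv.columns:
                raise ValueError(f"copy profile missing column {col!r}")
        iv = iv[need]
        for col in ("copies_allele1", "copies_allele2"):
            if not iv[col].isin([0, 1]).all():
                raise ValueError("allele copy counts must be 0 or 1")
        if (iv["start"] >= iv["end"]).any():
            raise ValueError("copy interval with start >= end")
        for chrom, grp in iv.groupby("chrom"):
            grp = grp.sort_values("start")
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"overlapping copy intervals on {chrom}")
        self.intervals = iv

    def copies_for(self, annotation: GeneAnnotation) -> pd.DataFrame:
        """Per-gene allele copies, assigned by gene-span overlap.

        A gene overlapping two intervals with conflicting copy states raises;
        genes outside all intervals get one copy per allele.
        """
        df = annotation.df
        c1 = np.ones(len(df), dtype=int)
        c2 = np.ones(len(df), dtype=int)
        assigned = np.zeros(len(df), dtype=bool)
        for _, iv in self.intervals.iterrows():
            hit = (
                (df["chrom"] == iv["chrom"])
                & (df["start"] < iv["end"])
                & (df["end"] > iv["start"])
            ).values
            conflict = hit & assigned & (
                (c1 != iv["copies_allele1"]) | (c2 != iv["copies_allele2"])
            )
            if conflict.any():
                genes = df.index[conflict].tolist()
                raise ValueError(
                    f"profile {self.profile_id}: genes overlap intervals with "
                    f"conflicting copies: {genes}"
                )
            c1[hit] = iv["copies_allele1"]
            c2[hit] = iv["copies_allele2"]
            assigned |= hit
        out = pd.DataFrame(
            {"copies_allele1": c1, "copies_allele2": c2}, index=df.index
        )
        out["total"] = out["copies_allele1"] + out["copies_allele2"]
        return out

    def to_tsv(self, path) -> None:
        iv = self.intervals.copy()
        iv.insert(0, "profile_id", self.profile_id)
        iv.to_csv(path, sep="\t", index=False)


def read_copy_profile(path, profile_id: Optional[str] = None) -> CopyNumberProfile:
    """Read one copy-number profile from a BED-like 5-column table.

    Columns: chrom, start, end, copies_allele1, copies_allele2 (whitespace or
    tab separated).  A header line is detected and skipped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] in ("chrom", "profile_id"):
                continue
            if parts[0] != "chrom" and len(parts) == 6:
                # profile_id leading column, as written by to_tsv
                pid, parts = parts[0], parts[1:]
                profile_id = profile_id or pid
            if len(parts) < 5:
                raise ParseError(
                    f"{path}:{lineno}: need chrom start end copies1 copies2"
                )
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), int(parts[3]), int(parts[4]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "copies_allele1", "copies_allele2"]
    )
    return CopyNumberProfile(profile_id or Path(path).stem, df)


# ---------------------------------------------------------------------------
# Allelic expression matrices
# ---------------------------------------------------------------------------


@dataclass
class AllelicExpressionMatrix:
    """Genes x samples expression split by parental allele.

    ``allele1`` and ``allele2`` share an identical gene index and sample
    columns; ``unassigned`` (reads without an allele-informative SNP) is
    optional and excluded from allelic statistics.
    """

    allele1: pd.DataFrame
    allele2: pd.DataFrame
    unassigned: Optional[pd.DataFrame] = None
    unit: str = UNIT_RAW
    modality: str = "cell"

    def __post_init__(self):
        a1, a2 = self.allele1, self.allele2
        if not a1.index.equals(a2.index) or not a1.columns.equals(a2.columns):
            raise ValueError("allele matrices must share gene and sample index")
        for name, df in (("allele1", a1), ("allele2", a2)):
            if (df.values < 0).any():
                raise ValueError(f"negative values in {name} matrix")
        if self.unassigned is not None:
            u = self.unassigned
            if not u.index.equals(a1.index) or not u.columns.equals(a1.columns):
                raise ValueError("unassigned matrix index mismatch")
            if (u.values < 0).any():
                raise ValueError("negative values in unassigned matrix")

    # -- accessors ----------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.allele1.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.allele1.columns

    @property
    def n_genes(self) -> int:
        return len(self.allele1.index)

    @property
    def n_samples(self) -> int:
        return len(self.allele1.columns)

    @property
    def total(self) -> pd.DataFrame:
        """Summed expression over both alleles (unassigned excluded)."""
        return self.allele1 + self.allele2

    def allele(self, which: int) -> pd.DataFrame:
        if which == 1:
            return self.allele1
        if which == 2:
            return self.allele2
        raise ValueError("allele must be 1 or 2")

    def select_genes(self, gene_ids) -> "AllelicExpressionMatrix":
        gene_ids = list(gene_ids)
        return replace(
            self,
            allele1=self.allele1.loc[gene_ids],
            allele2=self.allele2.loc[gene_ids],
            unassigned=None if self.unassigned is None else self.unassigned.loc[gene_ids],
        )

    def select_samples(self, sample_ids) -> "AllelicExpressionMatrix":
        sample_ids = list(sample_ids)
        return replace(
            self,
            allele1=self.allele1[sample_ids],
            allele2=self.allele2[sample_ids],
            unassigned=None if self.unassigned is None else self.unassigned[sample_ids],
        )

    # -- I/O ----------------------------------------------------------------

    def write_tsv(self, prefix) -> dict[str, Path]:
        """Write one TSV per matrix as ``<prefix>.allele1.tsv`` etc.

        Floats are written with 17 significant digits so read-back is exact.
        """
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {}
        frames = {"allele1": self.allele1, "allele2": self.allele2}
        if self.unassigned is not None:
            frames["unassigned"] = self.unassigned
        for name, df in frames.items():
            p = prefix.with_suffix(f".{name}.tsv")
            df.to_csv(p, sep="\t", float_format="%.17g", index_label="gene_id")
            paths[name] = p
        return paths


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_matrix_mtx(path) -> pd.DataFrame:
    from scipy.io import mmread

    path = Path(path)
    mat = mmread(path)
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    rows = Path(str(path) + ".rows").read_text().split()
    cols = Path(str(path) + ".cols").read_text().split()
    return pd.DataFrame(np.asarray(mat), index=rows, columns=cols)


def read_allelic_counts(
    path_allele1,
    path_allele2,
    format: str = "tsv",
    path_unassigned=None,
    modality: str = "cell",
) -> AllelicExpressionMatrix:
    """Read per-allele raw count matrices and align them.

    TSV matrices have genes as rows (first column = gene id) and a header of
    sample ids; MatrixMarket input expects ``<path>.rows`` / ``<path>.cols``
    name sidecars.  Matrices are aligned on the intersection of genes and
    samples, preserving the first file's order.
    """
    reader = {"tsv": _read_matrix_tsv, "mtx": _read_matrix_mtx}.get(format)
    if reader is None:
        raise ValueError(f"unknown counts format {format!r}")
    a1 = reader(path_allele1)
    a2 = reader(path_allele2)
    genes = a1.index[a1.index.isin(a2.index)]
    samples = a1.columns[a1.columns.isin(a2.columns)]
    if len(samples) == 0:
        raise ValueError("allele matrices share no samples")
    if len(genes) == 0:
        raise ValueError("allele matrices share no genes")
    a1 = a1.loc[genes, samples]
    a2 = a2.loc[genes, samples]
    un = None
    if path_unassigned is not None:
        un = reader(path_unassigned).reindex(index=genes, columns=samples).fillna(0.0)
    return AllelicExpressionMatrix(a1, a2, unassigned=un, modality=modality)


def read_sample_table(path) -> pd.DataFrame:
    """Read the sample table (sample_id, genotype_label, condition, replicate,
    copy_profile_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).fillna({"condition": ""})
    if "sample_id" not in df.columns or "genotype_label" not in df.columns:
        raise ParseError(f"{path}: sample table needs sample_id and genotype_label")
    return df.set_index("sample_id")


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_coverage(path, allele: str = "", normalization: str = "raw"):
    """Read a 4-column bedGraph into a :class:`dosagecomp.chip.CoverageTrack`."""
    from .chip import read_bedgraph

    return read_bedgraph(path, allele=allele, normalization=normalization)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_expression(
    m: AllelicExpressionMatrix,
    mode: str = "umi_tpm",
    annotation: Optional[GeneAnnotation] = None,
    include_unassigned: bool = False,
) -> AllelicExpressionMatrix:
    """Scale raw counts to TPM, jointly over both alleles per sample.

    Both allele matrices are multiplied by a single per-sample factor so the
    grand total over genes and alleles is 1e6; within-gene allelic fractions
    are therefore unchanged, and monosomy remains visible as halved totals
    rather than being renormalized away.

    ``umi_tpm`` treats counts as molecule counts (no length correction);
    ``length_tpm`` divides by gene length in kb before the joint scaling.
    The unassigned matrix, when present, contributes to the scaling
    denominator only if ``include_unassigned`` is set; by default it is
    carried along (rescaled) but excluded from the denominator.
    """
    if m.unit != UNIT_RAW:
        raise ValueError(f"normalize_expression requires raw counts, got unit={m.unit!r}")
    if mode not in ("umi_tpm", "length_tpm"):
        raise ValueError(f"unknown normalization mode {mode!r}")

    a1 = m.allele1.astype(float)
    a2 = m.allele2.astype(float)
    un = None if m.unassigned is None else m.unassigned.astype(float)

    if mode == "length_tpm":
        if annotation is None:
            raise ValueError("length_tpm requires gene annotation")
        lengths = annotation.df["length"].reindex(m.gene_ids)
        if lengths.isna().any():
            missing = m.gene_ids[lengths.isna()].tolist()
            raise ValueError(f"length_tpm: no length for genes {missing}")
        kb = lengths.values[:, None] / 1000.0
        a1 = a1 / kb
        a2 = a2 / kb
        if un is not None:
            un = un / kb

    denom = a1.sum(axis=0) + a2.sum(axis=0)
    if include_unassigned and un is not None:
        denom = denom + un.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"zero total assigned counts for samples: {zero.index.tolist()}")
    factor = 1e6 / denom
    return replace(
        m,
        allele1=a1 * factor,
        allele2=a2 * factor,
        unassigned=None if un is None else un * factor,
        unit=UNIT_TPM,
    )
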