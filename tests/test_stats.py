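import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dosagecomp as dc
from dosagecomp.stats import AnalysisConfig


# ---------------------------------------------------------------------------
# trimmed mean
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,expected",
    [
        ([5.0] * 20, 5.0),            # constant set
        (list(range(1, 11)), 5.5),    # 10/90 pct of 1..10 = (1.9, 9.1) -> mean{2..9}
        ([7.3], 7.3),                 # single gene retained
    ],
)
def test_trimmed_mean_examples(values, expected):
    assert dc.trimmed_mean_expression(values) == pytest.approx(expected)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=50),
       st.randoms(use_true_random=False))
def test_trimmed_mean_permutation_invariant_and_bounded(values, rnd):
    tm = dc.trimmed_mean_expression(values)
    shuffled = list(values)
    rnd.shuffle(shuffled)
    assert dc.trimmed_mean_expression(shuffled) == pytest.approx(tm)
    assert min(values) - 1e-9 <= tm <= max(values) + 1e-9


def test_trimmed_mean_empty_errors():
    with pytest.raises(ValueError):
        dc.trimmed_mean_expression([])


# ---------------------------------------------------------------------------
# X:A
# ---------------------------------------------------------------------------


def _flat_matrix(x_val, a_val, n_x=20, n_a=50):
    genes = [f"x{i}" for i in range(n_x)] + [f"a{i}" for i in range(n_a)]
    ann = dc.GeneAnnotation(
        pd.DataFrame(
            {
                "chrom": ["chrX"] * n_x + ["chr1"] * n_a,
                "start": np.arange(n_x + n_a) * 1000,
                "end": np.arange(n_x + n_a) * 1000 + 500,
                "strand": ["+"] * (n_x + n_a),
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )
    vals = [x_val] * n_x + [a_val] * n_a
    m = dc.AllelicExpressionMatrix(
        pd.DataFrame({"s": vals}, index=genes, dtype=float),
        pd.DataFrame({"s": vals}, index=genes, dtype=float),
        unit="tpm",
    )
    return m, ann


def test_x_to_a_simple_ratios():
    m, ann = _flat_matrix(4.0, 8.0)
    assert dc.x_to_autosome_ratio(m, "s", 1, ann) == pytest.approx(0.5)
    m, ann = _flat_matrix(3.0, 3.0)
    assert dc.x_to_autosome_ratio(m, "s", 2, ann) == pytest.approx(1.0)
    m, ann = _flat_matrix(3.0, 0.0)
    with pytest.raises(ValueError, match="median"):
        dc.x_to_autosome_ratio(m, "s", 1, ann)


def test_x_to_a_fold_change_matches_generator_expectation(sc_tpm, sc_data, annotation, sim_cfg):
    """Active-allele X:A in XO over per-allele X:A in XX estimates
    1 + pi_u (u - 1)."""
    _, samples, _ = sc_data
    xo = samples.index[samples["genotype_label"] == "XCastOMus"]
    xx = samples.index[samples["genotype_label"] == "XX"]
    xa_xo = np.mean([dc.x_to_autosome_ratio(sc_tpm, s, 2, annotation) for s in xo])
    xa_xx = np.mean([dc.x_to_autosome_ratio(sc_tpm, s, 2, annotation) for s in xx])
    expected = 1 + sim_cfg.pi_u * (sim_cfg.u - 1)
    assert xa_xo / xa_xx == pytest.approx(expected, rel=0.10)


# ---------------------------------------------------------------------------
# copy-number correction
# ---------------------------------------------------------------------------


def test_copy_number_correct_values_and_na(annotation):
    x = annotation.on_chrom("chrX").sorted_by_position()
    g_in = x.gene_ids[0]
    g_out = x.gene_ids[-1]
    span = x.df.loc[g_in]
    het = dc.deletion_profile("chrX", int(span.start), int(span.end), 2, "het")
    values = pd.DataFrame({"s": [10.0, 10.0]}, index=[g_in, g_out])
    cc = dc.copy_number_correct(values, het, annotation)
    assert cc.loc[g_in, "s"] == pytest.approx(10.0)   # 1 copy
    assert cc.loc[g_out, "s"] == pytest.approx(5.0)   # 2 copies
    hom = dc.CopyNumberProfile(
        "hom",
        pd.DataFrame(
            [["chrX", int(span.start), int(span.end), 0, 0]],
            columns=["chrom", "start", "end", "copies_allele1", "copies_allele2"],
        ),
    )
    cc0 = dc.copy_number_correct(values, hom, annotation)
    assert np.isnan(cc0.loc[g_in, "s"])


def test_copy_number_correct_is_linear(annotation):
    rng = np.random.default_rng(0)
    genes = annotation.gene_ids[:50]
    values = pd.DataFrame(
        rng.random((50, 3)) * 100, index=genes, columns=["a", "b", "c"]
    )
    prof = dc.CopyNumberProfile("diploid")
    cc = dc.copy_number_correct(values, prof, annotation)
    cc2 = dc.copy_number_correct(2 * values, prof, annotation)
    pd.testing.assert_frame_equal(cc2, 2 * cc)
    pd.testing.assert_frame_equal(cc, values / 2.0)  # all-two-copy: exact halving


# ---------------------------------------------------------------------------
# region partition
# ---------------------------------------------------------------------------


def test_partition_by_tss_rule():
    ann = dc.GeneAnnotation(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [10, 15, 10],
                "end": [40, 40, 40],
                "strand": ["+", "+", "+"],
            },
            index=pd.Index(["before", "at_edge", "other_chrom"], name="gene_id"),
        )
    )
    region = dc.GenomicRegion("r", "chr1", 15, 30)
    inside, outside = dc.partition_genes_by_region(ann, region)
    assert list(inside) == ["at_edge"]   # TSS 15 included (half-open)
    assert list(outside) == ["before"]   # TSS 10 outside
    chrom_genes = set(ann.genes_on("chr1"))
    assert set(inside) | set(outside) == chrom_genes
    assert set(inside) & set(outside) == set()


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------


def test_per_gene_log2fc_and_clipping():
    values = pd.Series({"g1": 4.0, "g2": 2.0, "g3": 80.0, "g4": 1.0})
    ref = pd.Series({"g1": 2.0, "g2": 2.0, "g3": 2.0, "g4": 0.0})
    fc = dc.per_gene_log2fc(values, ref)
    assert fc["g1"] == pytest.approx(1.0)
    assert fc["g2"] == pytest.approx(0.0)
    assert fc["g3"] == pytest.approx(np.log2(40))  # ~5.32, unclipped
    assert np.isnan(fc["g4"])
    clipped = dc.per_gene_log2fc(values, ref, clip=True)
    assert clipped["g3"] == pytest.approx(4.0)
    low = dc.per_gene_log2fc(pd.Series({"g1": 0.25}), pd.Series({"g1": 2.0}), clip=True)
    assert low["g1"] == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def test_sample_correlation_hand_computed(annotation):
    genes = list(annotation.genes_on("chr1")[:3])
    a = np.array([1.0, 2.0, 4.0])
    b = np.array([2.0, 1.0, 3.0])
    m = dc.AllelicExpressionMatrix(
        pd.DataFrame({"sa": a, "sb": b, "sa2": a}, index=genes),
        pd.DataFrame({"sa": 0 * a, "sb": 0 * b, "sa2": 0 * a}, index=genes),
        unit="tpm",
    )
    corr = dc.sample_correlation(m, annotation)
    # hand Pearson for (a, b)
    r = np.corrcoef(a, b)[0, 1]
    assert corr.loc["sa", "sb"] == pytest.approx(r, abs=1e-12)
    assert corr.loc["sa", "sa2"] == pytest.approx(1.0)
    assert (np.diag(corr.values) == pytest.approx(1.0))
    assert np.allclose(corr.values, corr.values.T)


def test_sample_correlation_zero_variance_is_na(annotation):
    genes = list(annotation.genes_on("chr1")[:3])
    m = dc.AllelicExpressionMatrix(
        pd.DataFrame({"flat": [5.0, 5.0, 5.0], "var": [1.0, 2.0, 3.0]}, index=genes),
        pd.DataFrame({"flat": [0.0] * 3, "var": [0.0] * 3}, index=genes),
        unit="tpm",
    )
    corr = dc.sample_correlation(m, annotation)
    assert np.isnan(corr.loc["flat", "var"])
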