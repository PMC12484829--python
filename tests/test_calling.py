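import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dosagecomp as dc
from dosagecomp.stats import AnalysisConfig


# ---------------------------------------------------------------------------
# XCU calling
# ---------------------------------------------------------------------------


def _frame(rows, cols, values):
    return pd.DataFrame(values, index=rows, columns=cols, dtype=float)


def test_xcu_call_hand_example():
    """mono = [2.0, 2.1, 1.9] vs half-of-XX = [1.0, 1.0, 1.0]: FC = 2, the
    equal-variance t is (2-1)/(0.1/sqrt(3)) ~ 17.3, clearly significant."""
    mono = _frame(["g"], ["c1", "c2", "c3"], [[2.0, 2.1, 1.9]])
    xx = _frame(["g"], ["x1", "x2", "x3"], [[2.0, 2.0, 2.0]])
    res = dc.XCUModel(mono, xx, equal_var=True).fit()
    row = res.table.loc["g"]
    assert row.fold_change == pytest.approx(2.0)
    t_oracle = (2.0 - 1.0) / (np.std([2.0, 2.1, 1.9], ddof=1) / np.sqrt(3))
    assert t_oracle == pytest.approx(17.32, abs=0.01)
    assert row.p_value < 0.05
    assert bool(row.upregulated) is True
    # Welch variant reaches the same call
    welch = dc.XCUModel(mono, xx).fit().table.loc["g"]
    assert bool(welch.upregulated) is True


def test_xcu_no_call_without_fold_change():
    mono = _frame(["g"], ["c1", "c2", "c3"], [[1.0, 1.0, 1.0]])
    xx = _frame(["g"], ["x1", "x2", "x3"], [[2.0, 2.0, 2.0]])
    row = dc.XCUModel(mono, xx).fit().table.loc["g"]
    assert row.fold_change == pytest.approx(1.0)
    assert bool(row.upregulated) is False


def test_xcu_fc_gate_blocks_significant_small_effects():
    """Fold change 1.19 with a tiny p-value is still not called (FC gate)."""
    rng = np.random.default_rng(0)
    mono_vals = 1.19 + rng.normal(0, 1e-4, 200)
    xx_vals = np.full(200, 2.0) + rng.normal(0, 1e-4, 200)
    mono = _frame(["g"], [f"c{i}" for i in range(200)], [mono_vals])
    xx = _frame(["g"], [f"x{i}" for i in range(200)], [xx_vals])
    row = dc.XCUModel(mono, xx).fit().table.loc["g"]
    assert row.p_value < 1e-6
    assert row.fold_change == pytest.approx(1.19, abs=0.01)
    assert bool(row.upregulated) is False


def test_xcu_zero_reference_reported_na():
    mono = _frame(["g"], ["c1", "c2"], [[1.0, 2.0]])
    xx = _frame(["g"], ["x1", "x2"], [[0.0, 0.0]])
    row = dc.XCUModel(mono, xx).fit().table.loc["g"]
    assert np.isnan(row.p_value)
    assert pd.isna(row.upregulated)


def test_xcu_null_calibration(annotation):
    """With u = 1 the called fraction stays below alpha (FC gate makes the
    caller strictly conservative)."""
    cfg = dc.SimulationConfig(seed=29, u=1.0)
    m, samples, _ = dc.simulate_allelic_counts(
        cfg, annotation, dc.standard_genotypes(cfg, n_xx=60, n_xo_cast=40)
    )
    tpm = dc.normalize_expression(m, "umi_tpm")
    x = annotation.genes_on("chrX")
    xo = samples.index[samples["genotype_label"] == "XCastOMus"]
    xx = samples.index[samples["genotype_label"] == "XX"]
    res = dc.XCUModel(tpm.allele2.loc[x, xo], tpm.total.loc[x, xx]).fit()
    assert res.n_called / len(x) <= 0.05


def test_xcu_recovery_and_bulk_concordance(annotation):
    """u = 2, pi_u = 0.4: sensitivity >= 0.8 and precision >= 0.9 vs truth;
    the matched bulk call overlaps the single-cell call with Jaccard >= 0.6."""
    cfg = dc.SimulationConfig(seed=31)
    m, samples, truth = dc.simulate_allelic_counts(
        cfg, annotation, dc.standard_genotypes(cfg, n_xx=60, n_xo_cast=40)
    )
    tpm = dc.normalize_expression(m, "umi_tpm")
    x = annotation.genes_on("chrX")
    xo = samples.index[samples["genotype_label"] == "XCastOMus"]
    xx = samples.index[samples["genotype_label"] == "XX"]
    res = dc.XCUModel(tpm.allele2.loc[x, xo], tpm.total.loc[x, xx]).fit()
    called = set(res.upregulated_genes)
    true = set(truth.compensated_gene_ids) & set(x)
    assert len(called & true) / len(true) >= 0.80
    assert len(called & true) / len(called) >= 0.90

    # bulk replicate experiment on matched truth
    bcfg = dc.SimulationConfig(seed=47, modality="bulk",
                               compensated_gene_ids=truth.compensated_gene_ids)
    bm, bsamples, _ = dc.simulate_allelic_counts(
        bcfg, annotation, dc.standard_genotypes(bcfg, n_xx=3, n_xo_cast=3)
    )
    btpm = dc.normalize_expression(bm, "length_tpm", annotation=annotation)
    prof = dc.monosomy_profile(1, "chrX", 160_000_000, "xo")
    profiles = {
        s: (prof if g == "XCastOMus" else dc.CopyNumberProfile("diploid"))
        for s, g in bsamples["genotype_label"].items()
    }
    cc = dc.copy_number_correct(btpm.total, profiles, annotation)
    bxo = bsamples.index[bsamples["genotype_label"] == "XCastOMus"]
    bxx = bsamples.index[bsamples["genotype_label"] == "XX"]
    bulk_set = set(dc.select_upregulated_bulk(cc.loc[x, bxo], cc.loc[x, bxx]))
    jaccard = len(bulk_set & called) / len(bulk_set | called)
    assert jaccard >= 0.6


def test_select_upregulated_bulk_rules():
    genes = ["strong", "exact", "low_ref"]
    xo = _frame(genes, ["a", "b"], [[15.0, 15.0], [12.0, 12.0], [4.0, 4.0]])
    xx = _frame(genes, ["c", "d"], [[10.0, 10.0], [10.0, 10.0], [2.0, 2.0]])
    sel = dc.select_upregulated_bulk(xo, xx)
    assert "strong" in sel          # FC 1.5
    assert "exact" not in sel       # FC exactly 1.2: strict >
    assert "low_ref" not in sel     # reference below the TPM > 5 filter


# ---------------------------------------------------------------------------
# region tests
# ---------------------------------------------------------------------------


def test_region_test_degenerate_and_abstention():
    genes = [f"g{i}" for i in range(12)]
    vals = _frame(genes, ["r1", "r2"], np.tile(np.arange(12.0)[:, None], 2))
    res = dc.test_region_compensation({"A": vals, "B": vals.copy()})
    assert all(p["p_adj"] == 1.0 for p in res["pairs"])  # identical -> p = 1
    few = vals.iloc[:8]
    res = dc.test_region_compensation({"A": few, "B": few * 2})
    assert res["reason"] is not None and "too few" in res["reason"]
    assert all(p["p_adj"] is None for p in res["pairs"])


def test_region_test_three_genotypes_bonferroni_factor():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(30)]
    base = rng.random((30, 2)) + 1
    groups = {
        "A": _frame(genes, ["r1", "r2"], base),
        "B": _frame(genes, ["r1", "r2"], base + rng.normal(0, 0.01, (30, 2))),
        "C": _frame(genes, ["r1", "r2"], base * 2),
    }
    res = dc.test_region_compensation(groups)
    assert len(res["pairs"]) == 3
    for pair in res["pairs"]:
        assert pair["p_adj"] == pytest.approx(min(1.0, 3 * pair["p_raw"]))


def test_region_test_unpaired_universe_errors():
    a = _frame(["g1", "g2"] + [f"g{i}" for i in range(3, 13)], ["r1", "r2"], np.ones((12, 2)))
    b = _frame([f"h{i}" for i in range(12)], ["r1", "r2"], np.ones((12, 2)))
    with pytest.raises(ValueError, match="universe|shared genes|gene"):
        dc.test_region_compensation({"A": a, "B": b})


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------


def test_tukey_equals_pooled_t_at_k2():
    """At k = 2 the studentized range test is the pooled-variance t-test
    (q = t * sqrt(2))."""
    rng = np.random.default_rng(2)
    for _ in range(5):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 9)
        p_tukey = dc.tukey_hsd([a, b])["p_adj"].iloc[0]
        _, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert abs(p_tukey - p_t) <= 1e-6


def _perm_max_q_p(groups, n_perm=20_000, seed=0):
    """Permutation oracle: null distribution of the maximum |q| statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    k = len(groups)
    N = pooled.size
    dfw = N - k

    def max_q(parts):
        means = np.array([p.mean() for p in parts])
        ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
        msw = ssw / dfw
        qmax = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(msw / 2 * (1 / sizes[i] + 1 / sizes[j]))
                qmax = max(qmax, abs(means[i] - means[j]) / se)
        return qmax

    obs = {}
    parts = groups
    means = [p.mean() for p in parts]
    ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
    msw = ssw / dfw
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2 * (1 / sizes[i] + 1 / sizes[j]))
            obs[(i, j)] = abs(means[i] - means[j]) / se
    exceed = {key: 0 for key in obs}
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        m = max_q(parts)
        for key, q in obs.items():
            if m >= q:
                exceed[key] += 1
    return {key: exceed[key] / n_perm for key in obs}


def test_tukey_matches_permutation_oracle_k3():
    rng = np.random.default_rng(3)
    groups = [rng.normal(0, 1, 5), rng.normal(0.5, 1, 5), rng.normal(1.2, 1, 5)]
    table = dc.tukey_hsd(groups)
    perm = _perm_max_q_p(groups, n_perm=20_000, seed=4)
    for idx, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
        assert abs(table["p_adj"].iloc[idx] - perm[(i, j)]) <= 0.02


def test_tukey_cross_checked_against_scipy():
    rng = np.random.default_rng(5)
    groups = [rng.normal(0, 1, 4), rng.normal(1, 1, 6), rng.normal(0.3, 1, 5)]
    ours = dc.tukey_hsd(groups)
    ref = sps.tukey_hsd(*groups)
    pairs = [(0, 1), (0, 2), (1, 2)]
    for idx, (i, j) in enumerate(pairs):
        assert ours["p_adj"].iloc[idx] == pytest.approx(ref.pvalue[i, j], abs=1e-8)


def test_tukey_identical_groups_and_degenerate():
    g = np.array([1.0, 2.0, 3.0])
    table = dc.tukey_hsd([g, g.copy(), g.copy()])
    assert (table["p_adj"] > 0.99).all()
    flat = dc.tukey_hsd([np.zeros(3), np.ones(3)])
    assert flat["p_adj"].iloc[0] == 0.0  # zero variance, unequal means


# ---------------------------------------------------------------------------
# p-value adjustment, chi-square, proportions
# ---------------------------------------------------------------------------


def test_adjust_pvalues_hand_vectors():
    # BH step-up on [.01, .02, .03, .04]: p(i) * 4 / i monotonized -> all .04
    bh = dc.adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="bh")
    assert bh.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])
    bonf = dc.adjust_pvalues([0.03, 0.4], method="bonferroni")
    assert bonf.tolist() == pytest.approx([0.06, 0.8])
    assert dc.adjust_pvalues([0.2], method="bh").tolist() == [0.2]
    assert dc.adjust_pvalues([0.2], method="bonferroni").tolist() == [0.2]
    with pytest.raises(ValueError):
        dc.adjust_pvalues([1.2], method="bh")


def test_bh_monotone_and_permutation_invariant():
    rng = np.random.default_rng(6)
    p = rng.random(40)
    adj = dc.adjust_pvalues(p, method="bh")
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    perm = rng.permutation(40)
    adj_perm = dc.adjust_pvalues(p[perm], method="bh")
    np.testing.assert_allclose(adj_perm, adj[perm])


def test_chi_square_hand_formula():
    stat, p = dc.chi_square_2x2([[10, 10], [10, 10]])
    assert stat == 0.0 and p == pytest.approx(1.0)
    stat, _ = dc.chi_square_2x2([[20, 10], [10, 20]])
    # n (ad - bc)^2 / (r1 r2 c1 c2) = 60 * (400-100)^2 / 30^4
    assert stat == pytest.approx(60 * (20 * 20 - 10 * 10) ** 2 / 30**4, abs=1e-9)
    assert stat == pytest.approx(6.667, abs=1e-3)
    stat_t, _ = dc.chi_square_2x2([[20, 10], [10, 20]])
    stat_tt, _ = dc.chi_square_2x2(np.array([[20, 10], [10, 20]]).T)
    assert stat_t == pytest.approx(stat_tt)
    with pytest.raises(ValueError):
        dc.chi_square_2x2([[0, 0], [5, 5]])


def test_compare_gene_set_proportions():
    universe = [f"g{i}" for i in range(40)]
    up = universe[:20]
    down = universe[20:]
    ann_all = universe
    res = dc.compare_gene_set_proportions(up, down, ann_all)
    assert res["statistic"] == 0.0
    res2 = dc.compare_gene_set_proportions(up, down, up)  # full/zero overlap
    stat_hand, _ = dc.chi_square_2x2([[20, 0], [0, 20]])
    assert res2["statistic"] == pytest.approx(stat_hand)
    with pytest.raises(ValueError):
        dc.compare_gene_set_proportions([], down, ann_all)


# ---------------------------------------------------------------------------
# autosomal calls
# ---------------------------------------------------------------------------


def test_call_silenced_threshold():
    genes = ["off", "partial", "dead_ref"]
    plus = _frame(genes, ["p1", "p2"], [[1.0, 1.0], [2.0, 2.0], [1.0, 1.0]])
    minus = _frame(genes, ["m1", "m2"], [[10.0, 10.0], [10.0, 10.0], [0.0, 0.0]])
    calls = dc.call_silenced_genes(plus, minus)
    assert bool(calls.loc["off", "silenced"]) is True      # fc 0.10
    assert bool(calls.loc["partial", "silenced"]) is False  # fc 0.20
    assert pd.isna(calls.loc["dead_ref", "silenced"])


def test_trans_upregulation_rule_and_linear_mode():
    genes = ["up", "flat"]
    plus = _frame(genes, ["p1", "p2"], [[4.5, 4.5], [3.0, 3.0]])
    minus = _frame(genes, ["m1", "m2"], [[3.0, 3.0], [3.0, 3.0]])
    calls = dc.call_trans_upregulated(plus, minus)
    assert calls.loc["up", "trans_log2fc"] == pytest.approx(np.log2(1.5))
    assert bool(calls.loc["up", "trans_upregulated"]) is True
    assert bool(calls.loc["flat", "trans_upregulated"]) is False
    linear = dc.call_trans_upregulated(plus, minus, scale="linear")
    assert bool(linear.loc["flat", "trans_upregulated"]) is True  # FC 1.0 > 0.5


def test_silenced_region_recovery_and_trans_recall(annotation):
    """The dox experiment: the dense silenced region is recovered near its
    simulated bounds and trans-upregulated compensated genes are recalled."""
    cfg = dc.SimulationConfig(seed=13, modality="bulk")
    region = dc.GenomicRegion("sil", "chr3", 60_000_000, 120_000_000)
    diploid = dc.CopyNumberProfile("diploid")
    genotypes = [
        dc.GenotypeSpec("minus", 3, diploid),
        dc.GenotypeSpec("plus", 3, diploid, silenced_region=region, silenced_allele=2),
    ]
    m, samples, truth = dc.simulate_allelic_counts(cfg, annotation, genotypes)
    tpm = dc.normalize_expression(m, "length_tpm", annotation=annotation)
    genes = annotation.genes_on("chr3")
    plus = samples.index[samples["genotype_label"] == "plus"]
    minus = samples.index[samples["genotype_label"] == "minus"]

    sil = dc.call_silenced_genes(tpm.allele2.loc[genes, plus], tpm.allele2.loc[genes, minus])
    sil_ids = sil.index[sil["silenced"].fillna(False).astype(bool)]
    found = dc.define_silenced_region(
        annotation.df.loc[sil_ids, "tss"].values, "chr3", 120_000_000
    )
    assert found is not None
    assert abs(found.start - region.start) <= 10_000_000
    assert found.end >= region.end - 10_000_000

    trans = dc.call_trans_upregulated(
        tpm.allele1.loc[genes, plus], tpm.allele1.loc[genes, minus]
    )
    called = set(trans.index[trans["trans_upregulated"].fillna(False).astype(bool)])
    true_set = set(truth.silenced_gene_ids["plus"]) & set(truth.compensated_gene_ids)
    assert len(called & true_set) / len(true_set) >= 0.8


def test_silenced_region_disabled_returns_fallback():
    fb = dc.GenomicRegion("configured", "chr3", 80_000_000, 160_000_000)
    out = dc.define_silenced_region([], "chr3", 160_000_000, detect=False, fallback=fb)
    assert out == fb
    assert dc.define_silenced_region([], "chr3", 160_000_000) is None
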