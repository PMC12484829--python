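import numpy as np
import pandas as pd
import pytest

import dosagecomp as dc
from dosagecomp.proteomics import ProteinMatrix


def _ann(n_x=3, n_a=3):
    names = [f"xg{i}" for i in range(n_x)] + [f"ag{i}" for i in range(n_a)]
    return dc.GeneAnnotation(
        pd.DataFrame(
            {
                "chrom": ["chrX"] * n_x + ["chr1"] * n_a,
                "start": np.arange(n_x + n_a) * 10_000,
                "end": np.arange(n_x + n_a) * 10_000 + 5000,
                "strand": ["+"] * (n_x + n_a),
            },
            index=pd.Index(names, name="gene_id"),
        )
    )


def _pm(values, genes, samples):
    ab = pd.DataFrame(values, index=[f"P_{g}" for g in genes], columns=samples,
                      dtype=float)
    gm = pd.Series(genes, index=ab.index)
    return ProteinMatrix(ab, gm)


def test_filter_fully_detected():
    ab = pd.DataFrame(
        {"s1": [1e7, np.nan], "s2": [2e7, 1e7]}, index=["P_a", "P_b"]
    )
    m = ProteinMatrix(ab, pd.Series(["a", "b"], index=ab.index))
    kept = dc.filter_fully_detected(m)
    assert list(kept.protein_ids) == ["P_a"]
    with pytest.warns(UserWarning):
        empty = dc.filter_fully_detected(
            ProteinMatrix(
                pd.DataFrame({"s1": [np.nan]}, index=["P_a"]),
                pd.Series(["a"], index=["P_a"]),
            )
        )
    assert len(empty.protein_ids) == 0


def test_copy_number_correction_rules_and_roundtrip():
    ann = _ann()
    genes = ["xg0", "ag0"]
    m = _pm([[1.0e7, 1.0e7], [2.0e7, 2.0e7]], genes, ["XX_1", "XO_1"])
    diploid = dc.CopyNumberProfile("diploid")
    xo = dc.monosomy_profile(1, "chrX", 1_000_000, "xo")
    profiles = {"XX_1": diploid, "XO_1": xo}
    cc = dc.copy_number_correct_protein(m, profiles, ann)
    assert cc.abundances.loc["P_xg0", "XX_1"] == pytest.approx(5.0e6)   # 2 copies
    assert cc.abundances.loc["P_xg0", "XO_1"] == pytest.approx(1.0e7)   # 1 copy
    assert cc.abundances.loc["P_ag0", "XO_1"] == pytest.approx(1.0e7)   # autosome / 2
    # multiplying back by copies restores the input exactly
    copies = {
        s: profiles[s].copies_for(ann)["total"].reindex(m.genes().values).values
        for s in m.sample_ids
    }
    restored = pd.DataFrame(
        {s: cc.abundances[s].values * copies[s] for s in m.sample_ids},
        index=m.protein_ids,
    )
    pd.testing.assert_frame_equal(restored, m.abundances)


def test_deletion_line_correction():
    ann = _ann()
    span = ann.df.loc["xg0"]
    del_prof = dc.deletion_profile("chrX", int(span.start), int(span.end), 2, "del")
    m = _pm([[1.0e7], [1.0e7]], ["xg0", "xg1"], ["Del_1"])
    cc = dc.copy_number_correct_protein(m, {"Del_1": del_prof}, ann)
    assert cc.abundances.loc["P_xg0", "Del_1"] == pytest.approx(1.0e7)  # inside: 1 copy
    assert cc.abundances.loc["P_xg1", "Del_1"] == pytest.approx(5.0e6)  # outside: halved


def test_protein_x_to_a_filter_and_ratio():
    ann = _ann()
    genes = ["xg0", "xg1", "ag0", "ag1"]
    m = _pm(
        [[2.0e7, 2.0e7], [1.1e7, 1.1e7], [4.0e7, 4.0e7], [4.0e7, 4.0e7]],
        genes, ["xx1", "xx2"],
    )
    ratios = dc.protein_x_to_a(m, ann, xx_samples=["xx1", "xx2"])
    assert "P_xg1" not in ratios.index          # below the 1.2e7 XX-mean filter
    assert ratios.loc["P_xg0", "xx1"] == pytest.approx(0.5)
    flat = _pm([[2e7, 2e7], [2e7, 2e7]], ["xg0", "ag0"], ["xx1", "xx2"])
    r = dc.protein_x_to_a(flat, ann, xx_samples=["xx1", "xx2"])
    assert r.loc["P_xg0"].values == pytest.approx(1.0)


def test_differential_requires_both_contrasts():
    """A protein elevated in only one monosomic line is not up-called."""
    ann = _ann()
    rng = np.random.default_rng(0)
    samples = [f"{g}_{i}" for g in ("XX", "XY", "XO") for i in range(3)]
    base = 1e7
    vals = np.concatenate([
        base * np.exp2(rng.normal(0, 0.1, 3)),        # XX
        4 * base * np.exp2(rng.normal(0, 0.1, 3)),    # XY: up
        base * np.exp2(rng.normal(0, 0.1, 3)),        # XO: flat
    ])
    m = _pm([vals], ["xg0"], samples)
    groups = {"XX": samples[:3], "XY": samples[3:6], "XO": samples[6:]}
    table, up = dc.differential_protein_abundance(m, groups, reference="XX")
    assert table.loc["P_xg0", "p_XY"] < 0.05
    assert len(up) == 0


def test_differential_recovery_on_simulation(sc_data, sim_cfg, annotation):
    """Protein-only compensated genes are recovered at sigma = 0.3, n = 3
    with sensitivity >= 0.7, and the u = 1 false-positive rate stays under
    alpha."""
    _, _, truth = sc_data
    prot, samples = dc.simulate_proteins(
        truth, sim_cfg, ("XX", "XMusY", "XCastOMus"), n_reps=3
    )
    detected = dc.filter_fully_detected(prot)
    x_ids = detected.protein_ids[detected.genes().isin(annotation.genes_on("chrX"))]
    sub = detected.select_proteins(x_ids)
    diploid = dc.CopyNumberProfile("diploid")
    xo = dc.monosomy_profile(1, "chrX", 160_000_000, "xo")
    xy = dc.monosomy_profile(2, "chrX", 160_000_000, "xy")
    prof_of = {"XX": diploid, "XMusY": xy, "XCastOMus": xo}
    profiles = {s: prof_of[g] for s, g in samples["genotype_label"].items()}
    cc = dc.copy_number_correct_protein(sub, profiles, annotation)
    groups = {
        g: list(samples.index[samples["genotype_label"] == g])
        for g in ("XX", "XMusY", "XCastOMus")
    }
    table, up = dc.differential_protein_abundance(cc, groups, reference="XX")
    up_genes = set(table.loc[list(up), "gene_id"])
    ponly = set(truth.protein_only_compensated_ids) & set(table["gene_id"])
    assert len(ponly) >= 20
    assert len(up_genes & ponly) / len(ponly) >= 0.7
    # non-compensated genes are rarely called
    null_genes = (
        set(table["gene_id"]) - set(truth.compensated_gene_ids) - ponly
    )
    fp = len(up_genes & null_genes) / len(null_genes)
    assert fp <= 0.05


def test_concordance_partition_and_example():
    rna = pd.Series({"A": 1.8, "B": 1.9, "C": 0.9, "D": 0.8})
    prot = pd.Series({"A": 0.9, "B": 2.1, "C": 1.7, "D": 0.7})
    res = dc.classify_rna_protein_concordance(rna, prot)
    cats = res["records"]["category"]
    assert cats["B"] == "both"
    assert cats["A"] == "rna_only"
    assert cats["C"] == "protein_only"
    assert cats["D"] == "neither"
    assert res["counts"].sum() == 4
    assert -1.0 <= res["pearson_r_log2fc"] <= 1.0
    with pytest.raises(ValueError):
        dc.classify_rna_protein_concordance(
            pd.Series({"A": 1.0}), pd.Series({"Z": 1.0})
        )


def test_concordance_noise_free_simulation(annotation):
    """With no protein noise, every RNA-compensated gene lands in 'both' and
    every protein-only gene in 'protein_only'."""
    cfg = dc.SimulationConfig(seed=37, protein_noise_sigma=0.0,
                              protein_detection_limit=0.0, mapping_bias_b=1.0)
    _, _, truth = dc.simulate_allelic_counts(
        cfg, annotation, dc.standard_genotypes(cfg, n_xx=2, n_xo_cast=2)
    )
    prot, samples = dc.simulate_proteins(truth, cfg, ("XX", "XCastOMus"), n_reps=1)
    x = annotation.genes_on("chrX")
    ab = prot.abundances
    genes = prot.genes()
    keep = genes.isin(x).values
    prot_fc = (ab["XCastOMus_P0"] / (ab["XX_P0"] / 2.0))[keep]
    prot_fc.index = genes[keep].values
    # noise-free RNA fold change from the truth means
    rna_tot = truth.expected_total_mean("XCastOMus") / (
        truth.expected_total_mean("XX") / 2.0
    )
    rna_fc = rna_tot[rna_tot.index.isin(x)]
    res = dc.classify_rna_protein_concordance(rna_fc, prot_fc)
    cats = res["records"]["category"]
    comp = [g for g in truth.compensated_gene_ids if g in cats.index]
    ponly = [g for g in truth.protein_only_compensated_ids if g in cats.index]
    assert (cats.loc[comp] == "both").all()
    assert (cats.loc[ponly] == "protein_only").all()
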