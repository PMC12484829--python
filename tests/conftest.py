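import numpy as np
import pandas as pd
import pytest

import dosagecomp as dc


@pytest.fixture(scope="session")
def sim_cfg():
    return dc.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def annotation(sim_cfg):
    return dc.simulate_annotation(sim_cfg)


@pytest.fixture(scope="session")
def sc_data(sim_cfg, annotation):
    """Single-cell counts for the standard genotype panel (small but
    representative group sizes)."""
    genotypes = dc.standard_genotypes(
        sim_cfg, n_xx=30, n_xo_cast=20, n_xo_mus=6, n_xy=10
    )
    return dc.simulate_allelic_counts(sim_cfg, annotation, genotypes)


@pytest.fixture(scope="session")
def sc_tpm(sc_data):
    matrix, _, _ = sc_data
    return dc.normalize_expression(matrix, "umi_tpm")


@pytest.fixture()
def toy_matrix():
    """Tiny 3-gene x 2-sample allelic matrix with known values."""
    genes = ["g1", "g2", "g3"]
    samples = ["s1", "s2"]
    a1 = pd.DataFrame([[10, 4], [0, 6], [30, 0]], index=genes, columns=samples, dtype=float)
    a2 = pd.DataFrame([[10, 0], [20, 6], [0, 4]], index=genes, columns=samples, dtype=float)
    return dc.AllelicExpressionMatrix(a1, a2)
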