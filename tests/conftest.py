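import numpy as np
import pandas as pd
import pytest

from hypolnc.core_io import ExpressionMatrix
from hypolnc.synthetic import SimConfig, design_samples, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated study shared across tests."""
    cfg = SimConfig(
        n_mrna=25, n_lncrna=25, n_mirna=12, conserved_fraction=0.5,
        n_target_sites=10, n_mimic_sites=6, n_none_sites=4,
        coexpr_blocks=((8, 2.0, 0.15),), de_fraction=0.05, seed=42,
        len_dist={"mrna_meanlog": 6.6, "lncrna_meanlog": 6.2},
    )
    return simulate_all(cfg)


@pytest.fixture
def tiny_expression():
    """2 transcripts x 4 samples with matching metadata."""
    design = design_samples(tissues=("heart",), oxygens=(6.5, 21.0), replicates=2)
    meta = pd.DataFrame(
        [{"sample_id": s.sample_id, "tissue": s.tissue,
          "oxygen_pct": s.oxygen_pct, "replicate": s.replicate} for s in design]
    ).set_index("sample_id", drop=False)
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 0.0, 7.0, 8.0]],
        index=["t1", "t2"], columns=meta.index)
    return ExpressionMatrix(values, meta)
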