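import numpy as np
import pandas as pd
import pytest

from hybridexpr import CountMatrix, SampleDesign, SimConfig, simulate_experiment


@pytest.fixture
def toy_counts():
    return CountMatrix(
        pd.DataFrame(
            {"s1": [5, 0, 100], "s2": [7, 0, 120]},
            index=["gA", "gB", "gC"],
        )
    )


@pytest.fixture
def small_design():
    rows = []
    for line in ("P1", "P2", "H_fwd"):
        for rep in (1, 2):
            rows.append(
                {"sample_id": f"t_{line}_{rep}", "line": line, "tissue": "t",
                 "replicate": rep}
            )
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def random_matrix_design():
    """Random 200-gene matrix with a 3-condition, 2-replicate design."""
    rng = np.random.default_rng(42)
    rows = [
        {"sample_id": f"t_{line}_{rep}", "line": line, "tissue": "t", "replicate": rep}
        for line in ("P1", "P2", "H_fwd")
        for rep in (1, 2)
    ]
    samples = [r["sample_id"] for r in rows]
    counts = rng.poisson(50, size=(200, len(samples)))
    # sprinkle weak genes
    counts[:20] = rng.poisson(0.5, size=(20, len(samples)))
    matrix = CountMatrix(
        pd.DataFrame(counts, index=[f"g{i:04d}" for i in range(200)], columns=samples)
    )
    design = SampleDesign(pd.DataFrame(rows))
    return matrix, design


@pytest.fixture(scope="session")
def strong_sim():
    """One-tissue simulation with strong effects, shared across tests."""
    cfg = SimConfig(
        n_genes=1200,
        n_replicates=3,
        tissues=("testis",),
        parental_divergence_log2=2.0,
        transgressive_shift_log2=2.0,
        dispersion=0.05,
        seed=7,
    )
    return cfg, simulate_experiment(cfg)
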