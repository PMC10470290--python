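import numpy as np
import pandas as pd
import pytest

from plasma_subtyper import SimulationConfig, scale_matrix, simulate_cohort
from plasma_subtyper.pipeline_cli import preprocess_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (seed 1), raw and preprocessed."""
    cfg = SimulationConfig(seed=1)
    ms, ab, clinical, truth = simulate_cohort(cfg)
    merged, de_ms, de_ab = preprocess_cohort(ms, ab, clinical)
    dlbcl = clinical.loc[clinical["group"] == "DLBCL", "sample_id"].tolist()
    V = scale_matrix(merged.subset_samples(dlbcl), "fraction_of_total")
    return {
        "config": cfg,
        "ms": ms,
        "ab": ab,
        "clinical": clinical,
        "truth": truth,
        "merged": merged,
        "dlbcl_ids": dlbcl,
        "V": V.values.to_numpy(),
        "V_protein_ids": V.protein_ids,
    }


@pytest.fixture(scope="session")
def rank_survey(default_cohort):
    """Consensus-NMF rank survey on the default cohort (50 restarts/rank)."""
    from plasma_subtyper.subtyping_nmf import select_rank

    k_star, rho, consensus = select_rank(
        default_cohort["V"], k_range=range(2, 7), n_restarts=50, base_seed=1
    )
    return k_star, rho, consensus


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_matrix():
    """Small expression matrix with two batches and some missing cells."""
    from plasma_subtyper import ExpressionMatrix

    vals = pd.DataFrame(
        {
            "s1": [5.0, 1.0, np.nan],
            "s2": [7.0, np.nan, np.nan],
            "s3": [np.nan, 3.0, 4.0],
            "s4": [2.0, 8.0, np.nan],
        },
        index=["pA", "pB", "pC"],
    )
    batch = pd.Series(["b1", "b1", "b2", "b2"], index=vals.columns)
    return ExpressionMatrix(vals, platform="MS", batch=batch)
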