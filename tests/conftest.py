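import numpy as np
import pandas as pd
import pytest

from pkdrx import expression as expr
from pkdrx import simulate as sim


@pytest.fixture(scope="session")
def exact_cfg() -> sim.SimulationConfig:
    """Deterministic (dispersion=0) study-design configuration."""
    return sim.SimulationConfig(seed=11, dispersion=0.0)


@pytest.fixture(scope="session")
def exact_cohort(exact_cfg):
    """Noise-free cohort with treatment arms: (counts, info, truth)."""
    return sim.simulate_cohort(exact_cfg)


@pytest.fixture(scope="session")
def exact_db(exact_cfg, exact_cohort):
    """Planted bioactivity database built on the noise-free cohort truth."""
    _, _, truth = exact_cohort
    return sim.simulate_bioactivity_db(exact_cfg, truth)


@pytest.fixture(scope="session")
def exact_expr(exact_cohort):
    """Noise-filtered expression matrix of the noise-free cohort."""
    counts, info, _ = exact_cohort
    em = expr.normalize(counts)
    kept = expr.noise_filter(expr.compute_cpm(counts, tmm=em.tmm))
    return expr.ExpressionMatrix(logcpm=em.logcpm.loc[kept], lib_size=em.lib_size, tmm=em.tmm)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    counts = rng.poisson(100, size=(50, 4))
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(50)], columns=list("abcd"))
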