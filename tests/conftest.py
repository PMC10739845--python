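import numpy as np
import pandas as pd
import pytest

from telocausal import synthetic
from telocausal.containers import TruthSet


@pytest.fixture(scope="session")
def small_genotypes():
    """300 samples x 100 variants in 10-variant LD blocks."""
    return synthetic.simulate_genotypes(300, 100, 10, seed=11)


@pytest.fixture(scope="session")
def eqtl_dataset():
    """Genotypes + expression with one planted cis-eQTL (beta = 0.8 SD)."""
    geno = synthetic.simulate_genotypes(400, 60, 10, seed=21, spacing=20_000)
    truth = TruthSet(planted_eqtls=[("snp000030", "gene0040", 0.8)])
    expr = synthetic.simulate_expression(geno, truth, 80, seed=22)
    return geno, expr, truth


@pytest.fixture(scope="session")
def trf_setup():
    """A ladder + reference + 6 sample lanes in the placental aTL range."""
    gel = synthetic.GelConfig()
    true_tls = [8000.0, 10000.0, 11000.0, 12500.0, 14000.0, 17000.0]
    ladder, lanes, flags = synthetic.simulate_trf_lanes(
        true_tls, spread=1200.0, gel=gel, reference_tl=6000.0, seed=31
    )
    return gel, ladder, lanes, flags, true_tls


def make_covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"sex": rng.integers(0, 2, n).astype(float), "age": rng.normal(32, 4, n)}
    )
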