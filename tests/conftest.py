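import numpy as np
import pytest

import omniblup as ob


@pytest.fixture(scope="session")
def tiny_bundle() -> ob.Bundle:
    """Small transcript-mediated panel shared by fast tests."""
    cfg = ob.SimConfig(
        n_lines=60,
        p_variants=300,
        n_genes=100,
        n_terms=10,
        term_size_range=(5, 20),
        causal_term_size=20,
        causal=ob.CausalSpec(n_causal_genes=10, n_causal_variants=30),
    )
    return ob.simulate_bundle(cfg, seed=3)


@pytest.fixture(scope="session")
def tiny_panel(tiny_bundle) -> ob.Panel:
    return tiny_bundle.panel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_psd_kernel(rng: np.random.Generator, n: int, p: int = None) -> np.ndarray:
    """Linear kernel of a random standardized feature matrix (mean diag 1)."""
    p = p or 3 * n
    M = rng.standard_normal((n, p))
    W = (M - M.mean(axis=0)) / M.std(axis=0)
    return W @ W.T / p
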