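import numpy as np
import pytest

from conada.core_data import RegionDataset, VariantSite


def make_variants(L):
    return [VariantSite(f"v{l + 1}", "1", 100 * (l + 1), "C", l) for l in range(L)]


def random_trio_dataset(rng, n=20, L=5, freq=0.3, n_controls=0):
    """Random Mendelian-valid dataset: parents Bernoulli alleles, child by transmission."""
    F = ((rng.random((n, L)) < freq).astype(float) + (rng.random((n, L)) < freq))
    M = ((rng.random((n, L)) < freq).astype(float) + (rng.random((n, L)) < freq))
    tf = np.where(F == 1, rng.integers(0, 2, (n, L)), F / 2)
    tm = np.where(M == 1, rng.integers(0, 2, (n, L)), M / 2)
    controls = (
        ((rng.random((n_controls, L)) < freq).astype(float)
         + (rng.random((n_controls, L)) < freq))
        if n_controls
        else None
    )
    return RegionDataset(
        variants=make_variants(L),
        trio_ids=[f"t{i}" for i in range(n)],
        father=F,
        mother=M,
        child=(tf + tm).astype(float),
        control_ids=[f"c{i}" for i in range(n_controls)] if n_controls else None,
        controls=controls,
    )


@pytest.fixture
def small_ds():
    """2 trios, 3 variants, 3 controls — fully deterministic."""
    F = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]])
    M = np.array([[0.0, 1.0, 0.0], [1.0, 1.0, 0.0]])
    C = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
    controls = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    return RegionDataset(
        variants=make_variants(3),
        trio_ids=["t1", "t2"],
        father=F,
        mother=M,
        child=C,
        control_ids=["c1", "c2", "c3"],
        controls=controls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
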