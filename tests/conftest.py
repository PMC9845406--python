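import numpy as np
import pytest

from triogxe import (
    GRRModelSpec,
    GRRParams,
    TrioDataset,
    TrioSimConfig,
    default_haplotype_table,
    mendelian_probs,
    simulate_trios,
)


@pytest.fixture(scope="session")
def haplotype_table():
    return default_haplotype_table()


@pytest.fixture(scope="session")
def single_stratum_data():
    """3,000 informative trios from the complete-LD stratum (test locus
    carries the causal GRRs exactly), no interaction."""
    return simulate_trios(TrioSimConfig.for_strata(1, n_trios=3000, seed=42))


@pytest.fixture(scope="session")
def two_strata_null_data():
    """3,000 informative trios from two unequal strata under no G x E."""
    return simulate_trios(TrioSimConfig.for_strata(2, n_trios=3000, seed=43))


def random_small_dataset(rng, n=12, k=1):
    """A small random trio dataset with valid Mendelian children and random
    covariates, for oracle comparisons."""
    gm = rng.integers(0, 3, size=n)
    gf = rng.integers(0, 3, size=n)
    gc = np.array(
        [rng.choice(3, p=mendelian_probs(int(a), int(b))) for a, b in zip(gm, gf)]
    )
    return TrioDataset(
        g_child=gc,
        g_mother=gm,
        g_father=gf,
        exposure=rng.normal(size=n),
        covariates=rng.normal(size=(n, k)),
    )


def random_params(rng, spec: GRRModelSpec, scale=0.5) -> GRRParams:
    return GRRParams.from_vector(rng.normal(scale=scale, size=spec.n_params), spec)
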