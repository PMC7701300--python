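import dataclasses

import pytest

from mfmda import factorization, synthetic


@pytest.fixture(scope="session")
def toy():
    """Hand-checkable micro-cases (sibling DAGs, identity GIP, NMF fixed point)."""
    return synthetic.toy_fixture()


@pytest.fixture(scope="session")
def small_bundle():
    """A quick cluster-structured dataset for pipeline-level tests."""
    spec = synthetic.SyntheticSpec(
        n_m=40, n_d=20, k_true=4, density=0.1, noise=0.0, seed=7
    )
    return synthetic.generate(spec)


@pytest.fixture(scope="session")
def quick_hyper():
    """Small, fast solver settings for pipeline-level tests."""
    return factorization.Hyperparams(k=8, max_iter=150, tol=1e-7, seed=3)


@pytest.fixture()
def replace_spec():
    return dataclasses.replace
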