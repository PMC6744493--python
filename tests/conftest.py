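import numpy as np
import pandas as pd
import pytest

from oncomodules.filtering import apply_filters
from oncomodules.network import network_from_assignments
from oncomodules.simulate import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (5 pathways, 40-DEG signatures, 200 tumours)."""
    return generate_cohort(SyntheticCohortSpec(seed=7))


@pytest.fixture(scope="session")
def filtered(default_cohort):
    return apply_filters(default_cohort.assignments,
                         default_cohort.observations)


@pytest.fixture(scope="session")
def network(filtered):
    return network_from_assignments(filtered.significant_assignments)


@pytest.fixture(scope="session")
def truth_module_labels(default_cohort):
    """Planted module id per signature DEG."""
    return {g: int(p)
            for p, info in default_cohort.truth["pathways"].items()
            for g in info["signature"]}


def planted_block_affinity(rng: np.random.Generator, sizes: list[int],
                           within: float = 5.0, between: float = 0.0,
                           jitter: float = 0.5) -> np.ndarray:
    """Symmetric block-structured affinity with multiplicative jitter."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    base = np.where(labels[:, None] == labels[None, :], within, between)
    noise = rng.uniform(1 - jitter, 1 + jitter, size=(n, n))
    A = base * (noise + noise.T) / 2
    np.fill_diagonal(A, 0.0)
    return (A + A.T) / 2


@pytest.fixture()
def blocks3():
    rng = np.random.default_rng(42)
    A = planted_block_affinity(rng, [12, 10, 8])
    labels = np.repeat([0, 1, 2], [12, 10, 8])
    return A, labels


def make_blobs(rng: np.random.Generator, n_per: int = 30, sd: float = 0.5
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Three well-separated Gaussian blobs as a patient feature table."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([rng.normal(c, sd, size=(n_per, 2)) for c in centers])
    frame = pd.DataFrame(X, index=[f"P{i}" for i in range(3 * n_per)],
                         columns=["f1", "f2"])
    return frame, np.repeat([0, 1, 2], n_per)
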