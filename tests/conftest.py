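import numpy as np
import pytest

from superbarcode import Alignment, calypogeia_like, make_dataset

BASES = "ACGT"


@pytest.fixture
def tiny_aln():
    return Alignment(
        ["s1", "s2", "s3"], ["AAAA", "AAAT", "AATT"],
        {"s1": "A", "s2": "B", "s3": "B"},
    )


def random_alignment(rng, n=8, length=300, n_species=3, gap_frac=0.05, n_frac=0.02):
    """Random alignment with sprinkled gaps and Ns, for oracle comparisons."""
    mat = rng.integers(0, 4, size=(n, length))
    mat[rng.random(mat.shape) < gap_frac] = 5
    mat[rng.random(mat.shape) < n_frac] = 4
    ids = [f"t{i}" for i in range(n)]
    species = {ids[i]: f"sp{i % n_species}" for i in range(n)}
    return Alignment.from_matrix(ids, mat.astype(np.uint8), species)


def similar_alignment(rng, n=8, length=300, n_species=3, divergence=0.05,
                      gap_frac=0.0):
    """Low-divergence alignment (mutations from one ancestor): K2P stays defined."""
    base = rng.integers(0, 4, size=length)
    mat = np.tile(base, (n, 1))
    hit = rng.random(mat.shape) < divergence
    mat[hit] = (mat[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    if gap_frac:
        mat[rng.random(mat.shape) < gap_frac] = 5
    ids = [f"t{i}" for i in range(n)]
    species = {ids[i]: f"sp{i % n_species}" for i in range(n)}
    return Alignment.from_matrix(ids, mat.astype(np.uint8), species)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def preset_ds():
    """One small organelle-like dataset with known truth, shared read-only."""
    return make_dataset(calypogeia_like(seed=7, total_length=8000))
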