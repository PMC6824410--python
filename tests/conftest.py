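import numpy as np
import pytest

from merinoscan.genotype_io import GenotypeDataset, SnpMap


def make_map(positions, chromosomes=None, prefix="snp"):
    positions = np.asarray(positions, dtype=np.int64)
    if chromosomes is None:
        chromosomes = np.ones(len(positions), dtype=np.int64)
    ids = np.array([f"{prefix}{i + 1}" for i in range(len(positions))],
                   dtype=object)
    return SnpMap(ids, np.asarray(chromosomes, dtype=np.int64), positions)


def make_dataset(dosages, breeds=None, snp_map=None, spacing=50_000):
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    if snp_map is None:
        snp_map = make_map(np.arange(1, L + 1) * spacing)
    if breeds is None:
        breeds = ["B1"] * n
    ids = np.array([f"s{i + 1}" for i in range(n)], dtype=object)
    return GenotypeDataset(ids, np.asarray(breeds, dtype=object), snp_map,
                           dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
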