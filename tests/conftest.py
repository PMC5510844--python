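import numpy as np
import pandas as pd
import pytest

from triohet import CountMatrix, TrioSimConfig, generate_trio_counts
from triohet.patterns import classify_all

ROLES = {"maternal": "maternal", "hybrid": "hybrid", "paternal": "paternal"}

# Genotype trait means and SDs of the two hybrid crosses and their parents
# (plant height cm, nodes/stem, pods/plant, seeds/plant, 100-seed weight g,
# protein %, oil %), used across heterosis tests.
TRAIT_NAMES = ["PH", "NNS", "NPS", "NSP", "HSW", "PC", "OC"]
GENOTYPE_MEANS = {
    "JLCMS9A": [99.1, 15.4, 38.2, 91.5, 20.3, 39.53, 19.93],
    "JLH1": [100.6, 22.8, 56.3, 107.0, 15.5, 38.29, 22.22],
    "HYBSOY-1": [94.7, 22.8, 63.3, 127.1, 19.0, 39.39, 21.48],
    "JLCMS84A": [67.0, 17.1, 34.9, 77.8, 14.7, 37.29, 20.69],
    "HYBSOY-5": [67.3, 25.9, 65.4, 145.3, 18.6, 38.79, 22.38],
}
GENOTYPE_SDS = {
    "JLCMS9A": [3.9, 1.3, 5.4, 8.8, 0.6, 0.3, 0.2],
    "JLH1": [2.8, 2.0, 8.7, 8.1, 0.4, 0.2, 0.3],
    "HYBSOY-1": [2.9, 1.4, 10.4, 10.0, 0.6, 0.4, 0.4],
    "JLCMS84A": [2.9, 1.3, 4.7, 9.0, 0.8, 0.2, 0.2],
    "HYBSOY-5": [2.5, 1.2, 10.6, 11.1, 0.8, 0.3, 0.3],
}


def trait_spec(names):
    return [
        (
            g,
            dict(zip(TRAIT_NAMES, GENOTYPE_MEANS[g])),
            dict(zip(TRAIT_NAMES, GENOTYPE_SDS[g])),
        )
        for g in names
    ]


@pytest.fixture(scope="session")
def small_trio():
    """A modest planted-effect trio, shared read-only across tests."""
    cfg = TrioSimConfig(
        n_genes=1500,
        depth_per_library=400_000,
        dispersion=0.0,
        effect_log2fc=2.0,
        category_fractions={
            "null": 0.88,
            "additivity": 0.04,
            "dominance_maternal": 0.02,
            "dominance_paternal": 0.02,
            "transgressive_up": 0.02,
            "transgressive_down": 0.02,
        },
        seed=42,
    )
    return generate_trio_counts(cfg)


@pytest.fixture(scope="session")
def small_classification(small_trio):
    cm, truth = small_trio
    return classify_all(cm, ROLES), truth


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 300, size=(100, 3))
    idx = pd.Index([f"g{i:03d}" for i in range(100)], name="gene_id")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=["a", "b", "c"], dtype=np.int64),
        lengths=pd.Series(rng.integers(200, 5000, size=100), index=idx),
    )
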