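import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msatabc.io import GenotypeDataset, GenotypeRecord, LocusDef, PopulationMeta

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(geno_by_pop, n_loci=None, motif_lengths=None, meta=False):
    """Build a dataset from {pop: [per-individual list of (a, b) per locus]}."""
    first = next(iter(geno_by_pop.values()))[0]
    L = n_loci or len(first)
    motifs = motif_lengths or [2] * L
    loci = [LocusDef(f"L{j + 1}", motif_length=motifs[j]) for j in range(L)]
    recs = []
    for pop, genos in geno_by_pop.items():
        for i, calls in enumerate(genos):
            recs.append(GenotypeRecord(f"{pop}_{i}", pop, tuple(calls)))
    metas = []
    if meta:
        metas = [
            PopulationMeta(p, 36.0 + 0.1 * k, -118.0 - 0.1 * k, 10.0, "g")
            for k, p in enumerate(geno_by_pop)
        ]
    return GenotypeDataset(loci, recs, metas)


@pytest.fixture
def two_pop_dataset():
    """Two populations, two dinucleotide loci, one missing genotype."""
    return make_dataset(
        {
            "north": [
                [(100, 102), (200, 200)],
                [(100, 100), (200, 204)],
                [(102, 102), (-1, -1)],
            ],
            "south": [
                [(104, 104), (204, 204)],
                [(100, 104), (200, 204)],
            ],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
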