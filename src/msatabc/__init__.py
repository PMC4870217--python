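"""msatabc: microsatellite population genetics and coalescent ABC inference.

Tools for diploid microsatellite datasets of grove-structured tree
populations: diversity and relatedness statistics, kin pruning, F_ST/R_ST
differentiation with allele-size permutation tests, isolation-by-distance
Mantel machinery, a coalescent simulator with generalized stepwise mutation,
and approximate Bayesian computation over competing demographic scenarios
with full validation (pseudo-observed datasets, error rates, RMAE,
posterior-predictive checks).
"""

from importlib.resources import files as _files

import pandas as _pd

from .io import (
    GenotypeDataset,
    GenotypeRecord,
    LocusDef,
    PopulationMeta,
    read_genepop,
    read_population_meta,
    validate_dataset,
    write_genepop,
)

__version__ = "0.1.0"


def load_grove_metadata() -> _pd.DataFrame:
    """The published grove table: coordinates, area (ha), sample counts and
    mean diversity statistics per grove, with the contiguity groups used for
    the indicator matrix and the pooled demes used for demographic inference."""
    path = _files("msatabc").joinpath("data/grove_metadata.csv")
    return _pd.read_csv(path)


def grove_population_meta() -> list[PopulationMeta]:
    """Grove metadata as :class:`PopulationMeta` records."""
    df = load_grove_metadata()
    return [
        PopulationMeta(
            population_id=r.population_id,
            latitude=r.lat,
            longitude=getattr(r, "long"),
            grove_area=r.area,
            group_label=r.group,
        )
        for r in df.itertuples(index=False)
    ]


__all__ = [
    "GenotypeDataset",
    "GenotypeRecord",
    "LocusDef",
    "PopulationMeta",
    "read_genepop",
    "write_genepop",
    "read_population_meta",
    "validate_dataset",
    "load_grove_metadata",
    "grove_population_meta",
]
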