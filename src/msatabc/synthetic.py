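"""Synthetic datasets with the statistical structure the pipeline assumes.

Two generators: (a) a clonal-orchard sampler producing open-pollinated
half-sib families within groves (so the kin-pruning stage has realistic
input, with a known pedigree to check against), and (b) pseudo-observed
datasets simulated under a demographic scenario with recorded true
parameters, for ABC validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import MutationModel, build_scenario, simulate_genotypes
from .io import GenotypeDataset, GenotypeRecord, LocusDef, PopulationMeta

__all__ = [
    "OrchardDesign",
    "GroveDesign",
    "generate_orchard",
    "generate_dyads",
    "generate_pseudo_observed",
    "TABLE_POSTERIOR_MEDIANS",
]


@dataclass(frozen=True)
class GroveDesign:
    name: str
    n_mothers: int
    seedlings_per_mother: int

    def __post_init__(self) -> None:
        if self.n_mothers < 1 or self.seedlings_per_mother < 1:
            raise ValueError("n_mothers and seedlings_per_mother must be >= 1")


@dataclass
class OrchardDesign:
    """Open-pollinated seed-orchard sampling design.

    Each grove is panmictic: mother trees are drawn from the grove allele
    frequencies, and every seedling receives one Mendelian maternal gamete
    and one paternal gamete from the grove pollen pool (equal to the grove
    frequencies; selfing with probability ``selfing_rate`` replaces the
    pollen-pool father with the mother).
    """

    groves: list[GroveDesign]
    n_alleles: int = 10
    selfing_rate: float = 0.0
    dirichlet_alpha: float = 1.0
    allele_freqs: dict[str, np.ndarray] | None = field(default=None)


def _grove_freqs(design: OrchardDesign, n_loci: int, rng) -> dict[str, np.ndarray]:
    if design.allele_freqs is not None:
        return design.allele_freqs
    if design.n_alleles < 2:
        raise ValueError("degenerate frequency spec: need >= 2 alleles")
    out = {}
    for g in design.groves:
        out[g.name] = rng.dirichlet(
            np.full(design.n_alleles, design.dirichlet_alpha), size=n_loci
        )
    return out


def _gamete(genotype: np.ndarray, rng) -> np.ndarray:
    # one allele per locus, Mendelian
    pick = rng.integers(0, 2, size=genotype.shape[0])
    return genotype[np.arange(genotype.shape[0]), pick]


def generate_orchard(
    design: OrchardDesign, n_loci: int = 11, seed: int | None = None
) -> tuple[GenotypeDataset, np.ndarray]:
    """Simulate orchard seedlings; returns (dataset, true relatedness matrix).

    The truth matrix holds the pedigree expectation for each seedling pair:
    0.25 for maternal half-sibs, 0.5 for full sibs (same father by chance or
    selfing), 0 otherwise.  Allele sizes are 2 bp x (10 + allele index).
    """
    rng = np.random.default_rng(seed)
    freqs = _grove_freqs(design, n_loci, rng)
    loci = [LocusDef(f"L{j + 1}", motif_length=2) for j in range(n_loci)]
    sizes = 2 * (10 + np.arange(design.n_alleles))

    records: list[GenotypeRecord] = []
    mothers_of: list[tuple[str, int, int]] = []  # (grove, mother idx, father tag)
    for g in design.groves:
        f = freqs[g.name]
        # mother genotypes: HWE draws from grove frequencies
        mothers = np.stack(
            [
                np.stack([rng.choice(design.n_alleles, p=f[j], size=2) for j in range(n_loci)])
                for _ in range(g.n_mothers)
            ]
        )  # (n_mothers, n_loci, 2)
        for m in range(g.n_mothers):
            for s in range(g.seedlings_per_mother):
                maternal = _gamete(mothers[m], rng)
                if design.selfing_rate and rng.random() < design.selfing_rate:
                    paternal = _gamete(mothers[m], rng)
                    father = -(m + 1)  # selfed
                else:
                    paternal = np.array(
                        [rng.choice(design.n_alleles, p=f[j]) for j in range(n_loci)]
                    )
                    father = rng.integers(0, 10 ** 9)  # effectively unique
                calls = tuple(
                    (int(sizes[maternal[j]]), int(sizes[paternal[j]]))
                    for j in range(n_loci)
                )
                records.append(
                    GenotypeRecord(
                        f"{g.name}_m{m}_s{s}", g.name, calls, family_id=f"{g.name}_m{m}"
                    )
                )
                mothers_of.append((g.name, m, father))

    n = len(records)
    truth = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gi, mi, fi = mothers_of[i]
            gj, mj, fj = mothers_of[j]
            if gi == gj and mi == mj:
                truth[i, j] = truth[j, i] = 0.5 if fi == fj or fi < 0 or fj < 0 else 0.25
    meta = [
        PopulationMeta(g.name, 36.0 + 0.1 * i, -118.0 - 0.1 * i, 50.0, "orchard")
        for i, g in enumerate(design.groves)
    ]
    return GenotypeDataset(loci, records, meta), truth


def generate_dyads(
    relationship: str,
    n_pairs: int,
    n_loci: int = 20,
    n_alleles: int = 10,
    seed: int | None = None,
) -> tuple[GenotypeDataset, list[tuple[str, str]]]:
    """Dyads of known relationship on a uniform allele-frequency background.

    relationship: 'parent_offspring', 'full_sib', 'half_sib' or 'unrelated'.
    Returns the dataset (all dyads pooled in one population, so allele
    frequencies are estimated from 2*n_pairs individuals) and the id pairs.
    """
    if relationship not in ("parent_offspring", "full_sib", "half_sib", "unrelated"):
        raise ValueError(f"unknown relationship {relationship!r}")
    rng = np.random.default_rng(seed)
    loci = [LocusDef(f"L{j + 1}", motif_length=2) for j in range(n_loci)]
    sizes = 2 * (10 + np.arange(n_alleles))

    def random_genotype():
        return rng.integers(0, n_alleles, size=(n_loci, 2))

    records = []
    pairs = []
    for k in range(n_pairs):
        a = random_genotype()
        if relationship == "parent_offspring":
            b = np.column_stack([_gamete(a, rng), rng.integers(0, n_alleles, n_loci)])
        elif relationship == "full_sib":
            p1, p2 = random_genotype(), random_genotype()
            a = np.column_stack([_gamete(p1, rng), _gamete(p2, rng)])
            b = np.column_stack([_gamete(p1, rng), _gamete(p2, rng)])
        elif relationship == "half_sib":
            shared = random_genotype()
            a = np.column_stack([_gamete(shared, rng), rng.integers(0, n_alleles, n_loci)])
            b = np.column_stack([_gamete(shared, rng), rng.integers(0, n_alleles, n_loci)])
        else:
            b = random_genotype()
        for tag, geno in (("a", a), ("b", b)):
            calls = tuple((int(sizes[x]), int(sizes[y])) for x, y in geno)
            records.append(GenotypeRecord(f"d{k}_{tag}", "dyads", calls))
        pairs.append((f"d{k}_a", f"d{k}_b"))
    meta = [PopulationMeta("dyads", 36.0, -118.0, 1.0, "sim")]
    return GenotypeDataset(loci, records, meta), pairs


# Posterior medians of the published five-deme simultaneous-divergence fit,
# used as the default pseudo-observed truth (sizes in diploid individuals,
# times in generations).
TABLE_POSTERIOR_MEDIANS: dict[str, float] = {
    "N1": 5380.0,
    "N2": 480.0,
    "N3": 284.0,
    "N4": 592.0,
    "N5": 329.0,
    "N_div": 1870.0,
    "N_anc": 23_000.0,
    "t_div1": 68.0,
    "t_anc": 7610.0,
}

# Pooled per-deme sample counts mirroring the grove sampling (southern pool,
# McKinley, Mariposa+Nelder, Tuolumne+Merced, Calaveras pair).
DEFAULT_SAMPLE_SIZES: list[int] = [200, 19, 44, 16, 50]


def generate_pseudo_observed(
    truth_params: dict[str, float] | None = None,
    scenario_kind: str = "simultaneous_divergence",
    sample_sizes: list[int] | None = None,
    seed: int | None = None,
    mutation_model: MutationModel | None = None,
) -> tuple[GenotypeDataset, dict[str, float]]:
    """Simulate a dataset with known parameters for ABC validation.

    Returns (dataset, truth).  Default truth: the published posterior medians
    of the simultaneous-divergence scenario; default sample sizes mirror the
    pooled grove sampling.
    """
    import warnings as _w

    from .demography import default_prior_spec

    truth = dict(truth_params or TABLE_POSTERIOR_MEDIANS)
    spec = default_prior_spec(scenario_kind)
    for name, (lo, hi) in spec.bounds.items():
        if name in truth and not (lo <= truth[name] <= hi):
            _w.warn(f"truth for {name} ({truth[name]}) lies outside prior [{lo}, {hi}]")
    scen = build_scenario(scenario_kind, truth, sample_sizes or DEFAULT_SAMPLE_SIZES)
    ds = simulate_genotypes(scen, mutation_model, seed)
    return ds, truth
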