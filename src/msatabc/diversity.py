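"""Per-population diversity statistics and association tests.

Implements the standard FSTAT/GENEPOP-style battery: observed heterozygosity,
unbiased gene diversity (Nei), allelic richness by hypergeometric rarefaction,
a Markov-chain exact test of Hardy-Weinberg proportions, a genotypic
permutation test of linkage disequilibrium, Holm's sequential Bonferroni
correction, and partial correlations for relating diversity to population
covariates.

Missing genotypes are handled by pairwise deletion: an individual is dropped
at a locus where it is untyped but contributes at all other loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import MISSING, GenotypeDataset

__all__ = [
    "allele_counts",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "allelic_richness",
    "hwe_exact_test",
    "ld_permutation_test",
    "sequential_bonferroni",
    "partial_correlation",
    "diversity_table",
]


def _pop_array(dataset: GenotypeDataset, population: str) -> np.ndarray:
    arr = dataset.allele_array()
    mask = np.array([r.population_id == population for r in dataset.records])
    if not mask.any():
        raise KeyError(f"unknown population {population!r}")
    return arr[mask]


def allele_counts(genotypes: np.ndarray) -> dict[int, int]:
    """Counts of each allele among non-missing gene copies of one locus.

    ``genotypes`` is an (n, 2) array for one population x locus.
    """
    flat = genotypes.ravel()
    flat = flat[flat != MISSING]
    vals, cnt = np.unique(flat, return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


def observed_heterozygosity(dataset: GenotypeDataset, population: str):
    """Fraction of heterozygous individuals per locus, and the mean over loci.

    Loci with no typed individual are excluded from the mean and reported as
    NaN.
    """
    arr = _pop_array(dataset, population)
    per_locus: dict[str, float] = {}
    for j, loc in enumerate(dataset.loci):
        g = arr[:, j]
        typed = g[:, 0] != MISSING
        n = int(typed.sum())
        if n == 0:
            per_locus[loc.name] = float("nan")
            continue
        per_locus[loc.name] = float((g[typed, 0] != g[typed, 1]).mean())
    vals = [v for v in per_locus.values() if not math.isnan(v)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return per_locus, mean


def expected_heterozygosity(dataset: GenotypeDataset, population: str):
    """Unbiased gene diversity per locus (Nei), and the mean over loci.

    H_E = 2n/(2n-1) * (1 - sum p_i^2) with n diploid individuals typed at the
    locus.  Undefined (NaN) when n < 2.
    """
    arr = _pop_array(dataset, population)
    per_locus: dict[str, float] = {}
    for j, loc in enumerate(dataset.loci):
        counts = allele_counts(arr[:, j])
        ngenes = sum(counts.values())
        if ngenes < 4:  # fewer than two diploid individuals
            per_locus[loc.name] = float("nan")
            continue
        p = np.array(list(counts.values())) / ngenes
        per_locus[loc.name] = float(ngenes / (ngenes - 1) * (1 - np.sum(p ** 2)))
    vals = [v for v in per_locus.values() if not math.isnan(v)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return per_locus, mean


def allelic_richness(dataset: GenotypeDataset, population: str, g: int):
    """Allelic richness rarefied to g diploid individuals (2g gene copies).

    Hypergeometric rarefaction: A_R(g) = sum_i [1 - C(2N - N_i, 2g) / C(2N, 2g)]
    over alleles with N_i copies among the 2N typed gene copies.  Loci with
    fewer than g typed individuals are excluded (NaN).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    arr = _pop_array(dataset, population)
    k = 2 * g
    per_locus: dict[str, float] = {}
    for j, loc in enumerate(dataset.loci):
        counts = allele_counts(arr[:, j])
        ngenes = sum(counts.values())
        if ngenes < k:
            per_locus[loc.name] = float("nan")
            continue
        denom = math.comb(ngenes, k)
        ar = sum(1 - math.comb(ngenes - ni, k) / denom for ni in counts.values())
        per_locus[loc.name] = float(ar)
    vals = [v for v in per_locus.values() if not math.isnan(v)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return per_locus, mean


# -- Hardy-Weinberg exact test ---------------------------------------------


def _table_log_prob_stat(geno_counts: dict[tuple[int, int], int]) -> float:
    """Variable part of the log conditional probability of a genotype table.

    Conditional on allele counts, P(table) is proportional to
    2^h / prod(G_ab!) with h the heterozygote count; the rest is constant.
    """
    h = sum(c for (a, b), c in geno_counts.items() if a != b)
    s = h * math.log(2.0)
    for c in geno_counts.values():
        s -= math.lgamma(c + 1)
    return s


@dataclass
class HWEResult:
    p_value: float
    se: float
    n_steps: int


def hwe_exact_test(
    dataset: GenotypeDataset,
    population: str,
    locus: str,
    dememorization: int = 10_000,
    batches: int = 20,
    iterations_per_batch: int = 5_000,
    seed: int | None = None,
) -> HWEResult:
    """Markov-chain estimate of the exact Hardy-Weinberg test probability.

    The chain is a random walk on pairings of the 2n observed gene copies into
    n diploid individuals: each step swaps one allele between two random
    individuals.  The proposal is symmetric and every pairing is equally
    likely under the null, so no accept/reject step is needed; the induced
    distribution over genotype tables is exactly the conditional
    (allele-count-fixed) null.  The reported p-value uses the probability
    ordering (the fraction of visited tables no more probable than the
    observed one); its Monte-Carlo s.e. comes from batch means.

    Returns NaN for a monomorphic locus.
    """
    names = [l.name for l in dataset.loci]
    j = names.index(locus)
    arr = _pop_array(dataset, population)[:, j]
    arr = arr[arr[:, 0] != MISSING]
    if len(arr) < 3:
        raise ValueError("need at least 3 typed individuals")
    if len(np.unique(arr)) < 2:
        return HWEResult(float("nan"), float("nan"), 0)

    rng = np.random.default_rng(seed)
    genes = arr.copy()
    n = len(genes)

    def counts_of(a: np.ndarray) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for x, y in a:
            key = (x, y) if x <= y else (y, x)
            out[key] = out.get(key, 0) + 1
        return out

    geno = counts_of(genes)
    stat = _table_log_prob_stat(geno)
    obs_stat = stat
    LOG2 = math.log(2.0)

    # stat = h*log2 - sum(lgamma(G+1)); removing one copy from a cell with
    # count c changes it by +log(c) (and -log2 if the cell is heterozygous),
    # adding one copy to a cell with new count c by -log(c) (+log2 if het).
    def remove(key: tuple[int, int]) -> float:
        c = geno.pop(key)
        if c > 1:
            geno[key] = c - 1
        return math.log(c) - (LOG2 if key[0] != key[1] else 0.0)

    def add(key: tuple[int, int]) -> float:
        c = geno.get(key, 0) + 1
        geno[key] = c
        return -math.log(c) + (LOG2 if key[0] != key[1] else 0.0)

    def step(u: int, v: int, su: int, sv: int) -> None:
        nonlocal stat
        ku = tuple(sorted(genes[u]))
        kv = tuple(sorted(genes[v]))
        stat += remove(ku) + remove(kv)
        genes[u, su], genes[v, sv] = genes[v, sv], genes[u, su]
        stat += add(tuple(sorted(genes[u]))) + add(tuple(sorted(genes[v])))

    # block-draw randomness for speed
    def run(n_steps: int, record: bool) -> float:
        hits = 0
        uv = rng.integers(0, n, size=(n_steps, 2))
        sides = rng.integers(0, 2, size=(n_steps, 2))
        for t in range(n_steps):
            u, v = uv[t]
            if u == v:
                pass
            else:
                step(u, v, sides[t, 0], sides[t, 1])
            if record and stat <= obs_stat + 1e-9:
                hits += 1
        return hits / n_steps

    run(dememorization, record=False)
    batch_means = np.array(
        [run(iterations_per_batch, record=True) for _ in range(batches)]
    )
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    return HWEResult(p, se, batches * iterations_per_batch)


# -- linkage disequilibrium -------------------------------------------------


def _llr_statistic(g1: np.ndarray, g2: np.ndarray) -> float:
    """Log-likelihood-ratio (G) statistic of association between two genotype
    columns, treating each distinct diploid genotype as a category."""
    c1 = {g: i for i, g in enumerate(sorted({tuple(sorted(x)) for x in g1}))}
    c2 = {g: i for i, g in enumerate(sorted({tuple(sorted(x)) for x in g2}))}
    table = np.zeros((len(c1), len(c2)))
    for a, b in zip(g1, g2):
        table[c1[tuple(sorted(a))], c2[tuple(sorted(b))]] += 1
    n = table.sum()
    exp = np.outer(table.sum(1), table.sum(0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / exp), 0.0)
    return float(2 * terms.sum())


def ld_permutation_test(
    dataset: GenotypeDataset,
    population: str,
    locus_pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for genotypic association between two loci.

    Genotypes at the second locus are shuffled across individuals; the p-value
    is the fraction of permutations (including the observed arrangement) whose
    G statistic is at least the observed one.  Returns NaN if either locus is
    monomorphic in the population.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    names = [l.name for l in dataset.loci]
    j1, j2 = names.index(locus_pair[0]), names.index(locus_pair[1])
    arr = _pop_array(dataset, population)
    both = (arr[:, j1, 0] != MISSING) & (arr[:, j2, 0] != MISSING)
    if both.sum() < 5:
        raise ValueError("need >= 5 individuals typed at both loci")
    g1, g2 = arr[both, j1], arr[both, j2]
    if len(np.unique(g1)) < 2 or len(np.unique(g2)) < 2:
        return float("nan")
    obs = _llr_statistic(g1, g2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(g2))
        if _llr_statistic(g1, g2[perm]) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# -- multiple testing and partial correlation -------------------------------


def sequential_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down sequential Bonferroni: boolean rejection flags.

    Sort p-values ascending and reject while p_(i) <= alpha / (m - i + 1);
    the first failure stops all further rejections.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def partial_correlation(y, x, controls):
    """Partial Pearson correlation of y and x given control variables.

    Both y and x are regressed (OLS, with intercept) on the controls; the
    correlation of the residuals is returned with a two-sided p-value from
    t = r sqrt(df / (1 - r^2)), df = n - k - 2 for k controls.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    Z = np.atleast_2d(np.asarray(controls, float))
    if Z.shape[0] == len(y) and Z.ndim == 2 and Z.shape[1] != len(y):
        pass
    elif Z.shape[1] == len(y):
        Z = Z.T
    n, k = len(y), Z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} controls")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("constant or collinear control variable")
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance: variable collinear with controls")
    r = float(np.corrcoef(ry, rx)[0, 1])
    df = n - k - 2
    t = r * math.sqrt(df / max(1e-300, 1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def diversity_table(dataset: GenotypeDataset, g: int = 5):
    """Per-population summary: n, H_O, H_E (unbiased), A_R rarefied to g.

    Populations too small for an estimate carry NaN in that column, mirroring
    the usual practice of flagging rather than dropping them.
    """
    import pandas as pd

    rows = []
    for pop in dataset.population_ids:
        _, ho = observed_heterozygosity(dataset, pop)
        _, he = expected_heterozygosity(dataset, pop)
        _, ar = allelic_richness(dataset, pop, g)
        rows.append(
            {"population": pop, "n": dataset.sample_sizes()[pop],
             "H_O": ho, "H_E": he, f"A_R_{g}": ar}
        )
    return pd.DataFrame(rows).set_index("population")
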