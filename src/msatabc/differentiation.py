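"""Population differentiation: F-statistics, R_ST and distance statistics.

F_ST uses the Weir-Cockerham variance-component estimator (theta); R_ST is its
allele-size analogue (one-way ANOVA on repeat counts).  Comparing the observed
R_ST with R_ST recomputed after permuting allele sizes among allelic states
within a locus tests for a phylogeographic (stepwise-mutation) signal: the
permutation erases size memory but preserves allele-frequency differentiation,
so the permuted values approximate an F_ST-like baseline.

Loci are combined by summing variance components, never by averaging ratios;
negative component estimates are kept in the sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeDataset

__all__ = [
    "wc_fst",
    "rst",
    "allele_size_permutation_test",
    "rousset_distance",
    "delta_mu2",
    "garza_m",
    "shared_allele_distance",
    "PermutationTestResult",
]


# -- array-level kernels (also used by the ABC summary pipeline) ------------


def wc_locus_components(genotypes: np.ndarray, pops: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) for one locus.

    ``genotypes`` is (n, 2) allele identities (MISSING allowed), ``pops``
    integer population codes.  Components are summed over alleles.
    Populations with fewer than 2 typed individuals are excluded.
    """
    typed = genotypes[:, 0] != MISSING
    g, pc = genotypes[typed], pops[typed]
    labels, pc = np.unique(pc, return_inverse=True)
    r = len(labels)
    n_i = np.bincount(pc, minlength=r).astype(float)
    keep = n_i >= 2
    if keep.sum() < 2:
        return 0.0, 0.0, 0.0
    if not keep.all():
        sel = keep[pc]
        g, pc = g[sel], pc[sel]
        labels, pc = np.unique(pc, return_inverse=True)
        r = len(labels)
        n_i = np.bincount(pc, minlength=r).astype(float)

    alleles, codes = np.unique(g, return_inverse=True)
    codes = codes.reshape(g.shape)
    k = len(alleles)
    if k < 2:
        return 0.0, 0.0, 0.0
    # allele count per pop (r, k) and per-allele heterozygote count per pop
    cnt = np.zeros((r, k))
    np.add.at(cnt, (pc, codes[:, 0]), 1)
    np.add.at(cnt, (pc, codes[:, 1]), 1)
    het = codes[:, 0] != codes[:, 1]
    hcnt = np.zeros((r, k))
    np.add.at(hcnt, (pc[het], codes[het, 0]), 1)
    np.add.at(hcnt, (pc[het], codes[het, 1]), 1)

    p = cnt / (2 * n_i[:, None])
    h = hcnt / n_i[:, None]
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p).sum(0) / (r * nbar)
    s2 = (n_i[:, None] * (p - pbar) ** 2).sum(0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h).sum(0) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def rst_locus_components(sizes: np.ndarray, pops: np.ndarray) -> tuple[float, float]:
    """Within and among variance components of allele size for one locus.

    ``sizes`` is (n, 2) repeat counts (MISSING = -1 excluded); one-way ANOVA
    on the 2n gene copies with populations as groups.  Returns
    (sigma2_within, sigma2_among); either may be negative before truncation.
    """
    typed = sizes[:, 0] != MISSING
    x = sizes[typed].astype(float).ravel()
    pc = np.repeat(pops[typed], 2)
    labels, pc = np.unique(pc, return_inverse=True)
    r = len(labels)
    if r < 2 or len(x) < 3:
        return 0.0, 0.0
    N_i = np.bincount(pc).astype(float)
    N = N_i.sum()
    means = np.bincount(pc, weights=x) / N_i
    grand = x.mean()
    ssw = ((x - means[pc]) ** 2).sum()
    ssa = (N_i * (means - grand) ** 2).sum()
    msw = ssw / (N - r)
    msa = ssa / (r - 1)
    nc = (N - (N_i ** 2).sum() / N) / (r - 1)
    return float(msw), float((msa - msw) / nc)


def _dataset_grouping(dataset: GenotypeDataset, grouping: dict[str, str] | None):
    """Integer group code per individual; grouping maps population -> group."""
    pops = [r.population_id for r in dataset.records]
    if grouping is None:
        labels = sorted(set(pops))
        gmap = {p: p for p in labels}
    else:
        gmap = grouping
    groups = sorted(set(gmap[p] for p in set(pops)))
    code = {g: i for i, g in enumerate(groups)}
    return np.array([code[gmap[p]] for p in pops]), groups


@dataclass
class DifferentiationResult:
    global_value: float
    pairwise: np.ndarray
    labels: list[str]


def wc_fst(dataset: GenotypeDataset, grouping: dict[str, str] | None = None) -> DifferentiationResult:
    """Global and pairwise Weir-Cockerham theta, loci combined by components."""
    arr = dataset.allele_array()
    codes, labels = _dataset_grouping(dataset, grouping)

    def theta(mask: np.ndarray) -> float:
        A = B = C = 0.0
        for j in range(arr.shape[1]):
            a, b, c = wc_locus_components(arr[mask, j], codes[mask])
            A, B, C = A + a, B + b, C + c
        tot = A + B + C
        return A / tot if tot != 0 else float("nan")

    glob = theta(np.ones(len(codes), dtype=bool))
    k = len(labels)
    pw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mask = (codes == i) | (codes == j)
            pw[i, j] = pw[j, i] = theta(mask)
    return DifferentiationResult(glob, pw, labels)


def rst(dataset: GenotypeDataset, grouping: dict[str, str] | None = None) -> DifferentiationResult:
    """Global and pairwise R_ST (allele-size variance components)."""
    sizes = dataset.repeat_array()
    codes, labels = _dataset_grouping(dataset, grouping)
    glob = _rst_from_sizes(sizes, codes)
    k = len(labels)
    pw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mask = (codes == i) | (codes == j)
            pw[i, j] = pw[j, i] = _rst_from_sizes(sizes[mask], codes[mask])
    return DifferentiationResult(glob, pw, labels)


def _rst_from_sizes(sizes: np.ndarray, codes: np.ndarray) -> float:
    W = A = 0.0
    for j in range(sizes.shape[1]):
        w, a = rst_locus_components(sizes[:, j], codes)
        W, A = W + w, A + a
    tot = W + A
    return A / tot if tot != 0 else float("nan")


@dataclass
class PermutationTestResult:
    observed: float
    mean_permuted: float
    p_value: float
    n_perm: int
    seed: int | None


def allele_size_permutation_test(
    dataset: GenotypeDataset,
    grouping: dict[str, str] | None = None,
    n_perm: int = 20_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Observed R_ST against R_ST with allele sizes permuted within loci.

    Sizes are reassigned by a random bijection among the distinct allelic
    states observed at each locus, which preserves allele-frequency structure
    exactly while destroying the size ordering.  One-tailed
    p = Pr(R_STperm >= R_STobs), with the +1 correction.
    """
    import warnings as _w

    if n_perm < 100:
        _w.warn("n_perm < 100 gives an unstable permutation p-value")
    sizes = dataset.repeat_array()
    codes, _ = _dataset_grouping(dataset, grouping)
    L = sizes.shape[1]
    # factorize each locus into state indices + size lookup
    state_idx = np.zeros(sizes.shape, dtype=np.int64)
    lookups: list[np.ndarray] = []
    masks = []
    for j in range(L):
        typed = sizes[:, j, 0] != MISSING
        vals, inv = np.unique(sizes[typed, j], return_inverse=True)
        state_idx[typed, j] = inv.reshape(-1, 2)
        lookups.append(vals.astype(float))
        masks.append(typed)

    def rst_with(lk: list[np.ndarray]) -> float:
        W = A = 0.0
        for j in range(L):
            col = np.full(sizes.shape[:1] + (2,), float(MISSING))
            col[masks[j]] = lk[j][state_idx[masks[j], j]]
            w, a = rst_locus_components(col, codes)
            W, A = W + w, A + a
        tot = W + A
        return A / tot if tot != 0 else float("nan")

    observed = rst_with(lookups)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for t in range(n_perm):
        shuffled = [lk[rng.permutation(len(lk))] for lk in lookups]
        perms[t] = rst_with(shuffled)
    p = (np.sum(perms >= observed - 1e-12) + 1) / (n_perm + 1)
    return PermutationTestResult(observed, float(perms.mean()), float(p), n_perm, seed)


# -- distance statistics ----------------------------------------------------


def rousset_distance(fst):
    """Rousset's linearized distance F_ST / (1 - F_ST), elementwise."""
    f = np.asarray(fst, dtype=float)
    if np.any(f >= 1):
        raise ValueError("F_ST = 1 gives an infinite Rousset distance")
    return f / (1 - f)


def delta_mu2(dataset: GenotypeDataset, pop_pair: tuple[str, str]):
    """Goldstein's delta-mu^2 per locus and its mean over usable loci.

    The squared difference of mean allele size (repeat units) between the two
    populations; loci untyped in either population are skipped.
    """
    sizes = dataset.repeat_array()
    pops = np.array([r.population_id for r in dataset.records])
    per_locus: dict[str, float] = {}
    for j, loc in enumerate(dataset.loci):
        vals = []
        for p in pop_pair:
            x = sizes[pops == p, j]
            x = x[x[:, 0] != MISSING].ravel()
            vals.append(x)
        if any(len(v) == 0 for v in vals):
            continue
        per_locus[loc.name] = float((vals[0].mean() - vals[1].mean()) ** 2)
    mean = float(np.mean(list(per_locus.values()))) if per_locus else float("nan")
    return per_locus, mean


def garza_m(dataset: GenotypeDataset, population: str):
    """Garza-Williamson M = k / (r + 1) per locus and its mean.

    k is the number of distinct alleles, r the allele size range in repeat
    units; M near 1 indicates a full allele ladder, low M a bottleneck.
    """
    sizes = dataset.repeat_array()
    pops = np.array([r.population_id for r in dataset.records])
    per_locus: dict[str, float] = {}
    for j, loc in enumerate(dataset.loci):
        x = sizes[pops == population, j]
        x = x[x[:, 0] != MISSING].ravel()
        if len(x) == 0:
            continue
        k = len(np.unique(x))
        rng = x.max() - x.min()
        per_locus[loc.name] = float(k / (rng + 1))
    mean = float(np.mean(list(per_locus.values()))) if per_locus else float("nan")
    return per_locus, mean


def shared_allele_distance(dataset: GenotypeDataset, pop_pair: tuple[str, str]) -> float:
    """D_AS = 1 - mean proportion of alleles shared between cross-population
    individual pairs, averaged over loci and pairs."""
    arr = dataset.allele_array()
    pops = np.array([r.population_id for r in dataset.records])
    a1 = arr[pops == pop_pair[0]]
    a2 = arr[pops == pop_pair[1]]
    if len(a1) == 0 or len(a2) == 0:
        raise ValueError("both populations must be non-empty")
    props = []
    for x in a1:
        for y in a2:
            locus_props = []
            for j in range(arr.shape[1]):
                if x[j, 0] == MISSING or y[j, 0] == MISSING:
                    continue
                locus_props.append(_shared_pair(x[j], y[j]))
            if locus_props:
                props.append(np.mean(locus_props))
    return float(1 - np.mean(props))


def _shared_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    # proportion of shared alleles between two diploid genotypes (0, .5, 1)
    s = 0
    used = [False, False]
    for a in g1:
        for k in range(2):
            if not used[k] and g2[k] == a:
                used[k] = True
                s += 1
                break
    return s / 2
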