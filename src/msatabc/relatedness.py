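"""Lynch-Ritland pairwise relatedness and iterative kin pruning.

Open-pollinated seed collections from a clonal orchard necessarily contain
maternal sibships; population-genetic statistics computed on such samples are
biased by the overrepresented family alleles.  The standard remedy is to
estimate pairwise relatedness for every pair of individuals and iteratively
discard the most-connected individuals until no pair more related than
half-sibs (r > 0.25) remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeDataset

__all__ = ["lynch_ritland_matrix", "prune_related", "PruneResult"]


def _locus_estimates(ref: np.ndarray, pro: np.ndarray, freqs: dict[int, float]):
    """Per-pair Lynch-Ritland locus estimate and weight, reference -> proband.

    ref and pro are (m, 2) arrays of allele calls for m pairs at one locus.
    With reference alleles (a, b) and proband alleles (c, d):

        r = [p_a (d_bc + d_bd) + p_b (d_ac + d_ad) - 4 p_a p_b]
            / [(1 + d_ab)(p_a + p_b) - 4 p_a p_b]

    and the locus weight is the denominator divided by 2 p_a p_b (Lynch &
    Ritland's inverse-sampling-variance weight).
    """
    pa = np.array([freqs[a] for a in ref[:, 0]])
    pb = np.array([freqs[b] for b in ref[:, 1]])
    a, b = ref[:, 0], ref[:, 1]
    c, d = pro[:, 0], pro[:, 1]
    dab = (a == b).astype(float)
    num = (
        pa * ((b == c).astype(float) + (b == d).astype(float))
        + pb * ((a == c).astype(float) + (a == d).astype(float))
        - 4 * pa * pb
    )
    den = (1 + dab) * (pa + pb) - 4 * pa * pb
    weight = den / (2 * pa * pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den != 0, num / den, np.nan)
    return r, weight


def lynch_ritland_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Symmetric individual x individual Lynch-Ritland relatedness matrix.

    Allele frequencies are computed over the whole dataset (all populations
    combined).  Loci are combined with Lynch-Ritland weights, and the two
    directed estimates (each individual as reference) are averaged, as GenAlEx
    does.  The diagonal is NaN; pairs sharing no typed locus are NaN.
    """
    arr = dataset.allele_array()
    n, L, _ = arr.shape
    # population-wide allele frequencies per locus
    freqs: list[dict[int, float]] = []
    for j in range(L):
        flat = arr[:, j].ravel()
        flat = flat[flat != MISSING]
        vals, cnt = np.unique(flat, return_counts=True)
        freqs.append(dict(zip(vals.tolist(), (cnt / cnt.sum()).tolist())))

    iu, ju = np.triu_indices(n, k=1)
    m = len(iu)
    num_xy = np.zeros(m)  # x as reference
    den_xy = np.zeros(m)
    num_yx = np.zeros(m)
    den_yx = np.zeros(m)
    any_locus = np.zeros(m, dtype=bool)
    for j in range(L):
        gx, gy = arr[iu, j], arr[ju, j]
        typed = (gx[:, 0] != MISSING) & (gy[:, 0] != MISSING)
        if not typed.any():
            continue
        r1, w1 = _locus_estimates(gx[typed], gy[typed], freqs[j])
        r2, w2 = _locus_estimates(gy[typed], gx[typed], freqs[j])
        ok1 = np.isfinite(r1)
        ok2 = np.isfinite(r2)
        idx = np.flatnonzero(typed)
        num_xy[idx[ok1]] += (w1 * r1)[ok1]
        den_xy[idx[ok1]] += w1[ok1]
        num_yx[idx[ok2]] += (w2 * r2)[ok2]
        den_yx[idx[ok2]] += w2[ok2]
        any_locus[idx[ok1 | ok2]] = True

    with np.errstate(divide="ignore", invalid="ignore"):
        rxy = num_xy / den_xy
        ryx = num_yx / den_yx
    sym = np.where(
        np.isfinite(rxy) & np.isfinite(ryx), 0.5 * (rxy + ryx),
        np.where(np.isfinite(rxy), rxy, ryx),
    )
    sym = np.where(any_locus, sym, np.nan)
    out = np.full((n, n), np.nan)
    out[iu, ju] = sym
    out[ju, iu] = sym
    return out


@dataclass
class PruneResult:
    kept_ids: list[str]
    removal_log: list[tuple[str, int]]  # (individual_id, rank at removal)


def prune_related(
    matrix: np.ndarray,
    ids: list[str],
    threshold: float = 0.25,
    exempt_populations: set[str] | None = None,
    population_of: dict[str, str] | None = None,
    strict: bool = True,
) -> PruneResult:
    """Iteratively remove the individual involved in most above-threshold pairs.

    Individuals are ranked by the number of pairs with relatedness exceeding
    the threshold; the highest-ranked one is removed and ranks are recomputed,
    until no offending pair remains.  Pairs wholly within an exempt population
    are ignored (the small-isolate exception, where every within-grove pair
    exceeds the half-sib threshold and pruning would empty the sample).

    Ties are broken by higher mean relatedness over offending pairs, then by
    lexicographic individual id, so the procedure is deterministic.  With
    ``strict`` (default) a pair counts only when r > threshold, else r >=.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    if m.shape != (n, n) or len(ids) != n:
        raise ValueError("matrix must be square and match ids")
    exempt_populations = exempt_populations or set()
    with np.errstate(invalid="ignore"):
        over = (m > threshold) if strict else (m >= threshold)
    over = over & np.isfinite(m)
    np.fill_diagonal(over, False)
    if exempt_populations and population_of:
        pops = np.array([population_of[i] for i in ids])
        for pop in exempt_populations:
            inside = pops == pop
            over[np.ix_(inside, inside)] = False

    alive = np.ones(n, dtype=bool)
    removal_log: list[tuple[str, int]] = []
    while True:
        sub = over & alive[None, :] & alive[:, None]
        degree = sub.sum(axis=1)
        if degree.max(initial=0) == 0:
            break
        top = degree.max()
        cand = np.flatnonzero(degree == top)
        with np.errstate(invalid="ignore"):
            mean_r = np.array(
                [np.nanmean(np.where(sub[i], m[i], np.nan)) for i in cand]
            )
        best = cand[np.lexsort((np.array(ids, dtype=object)[cand], -mean_r))][0]
        alive[best] = False
        removal_log.append((ids[best], int(top)))
    kept = [ids[i] for i in range(n) if alive[i]]
    return PruneResult(kept, removal_log)
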