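"""Approximate Bayesian computation for demographic model choice.

The DIYABC-style workflow: draw parameters from the priors, simulate a
dataset per draw, reduce it to a fixed summary-statistic vector, and build a
reference table per scenario.  Scenario choice fits a multinomial logistic
regression of scenario identity on summary deviations among the simulations
closest to the observed vector; parameter estimation applies Beaumont's
local-linear regression adjustment to the retained parameter values.
Validation uses pseudo-observed datasets: type I/II error of scenario choice,
credible-interval coverage and relative median absolute error (RMAE) of
parameter estimates, and posterior-predictive checks on holdout statistics
never used for training.

Summary vector (fixed ordering contract for P demes): per-deme mean allele
count, mean genic diversity and mean allele-size variance (3P values), then
pairwise Weir-Cockerham F_ST and delta-mu^2 in lexicographic deme order
(2 * P(P-1)/2 values).  Holdout vector: per-deme Garza-Williamson M, then
pairwise pooled two-sample allele count, pooled allele-size variance and
shared-allele distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import (
    MutationPrior,
    PriorSpec,
    build_scenario,
    default_prior_spec,
    sample_priors,
    simulate_repeat_matrix,
)
from .io import MISSING, GenotypeDataset

__all__ = [
    "summary_stat_names",
    "holdout_stat_names",
    "summary_stats",
    "holdout_stats",
    "summary_vector",
    "ReferenceTable",
    "build_reference_table",
    "ModelChoiceResult",
    "model_choice_logistic",
    "ParameterEstimate",
    "estimate_parameters",
    "confidence_evaluation",
    "rmae",
    "model_check",
]


# -- summary statistics -----------------------------------------------------


def _pairs(P: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(P) for j in range(i + 1, P)]


def summary_stat_names(P: int) -> list[str]:
    names = [f"nal_{i}" for i in range(P)]
    names += [f"het_{i}" for i in range(P)]
    names += [f"vsz_{i}" for i in range(P)]
    names += [f"fst_{i}_{j}" for i, j in _pairs(P)]
    names += [f"dmu2_{i}_{j}" for i, j in _pairs(P)]
    return names


def holdout_stat_names(P: int) -> list[str]:
    names = [f"gwm_{i}" for i in range(P)]
    names += [f"nal2_{i}_{j}" for i, j in _pairs(P)]
    names += [f"vsz2_{i}_{j}" for i, j in _pairs(P)]
    names += [f"das_{i}_{j}" for i, j in _pairs(P)]
    return names


def _locus_tables(sizes: np.ndarray, pops: np.ndarray, P: int):
    """Per-locus allele-count bookkeeping shared by the stat functions.

    Yields (values, cnt, hcnt, n_i): distinct repeat sizes, (P, k) allele
    counts, (P, k) per-allele heterozygote-carrier counts and typed diploid
    counts per deme.
    """
    L = sizes.shape[1]
    for j in range(L):
        g = sizes[:, j]
        typed = g[:, 0] != MISSING
        gt, pc = g[typed], pops[typed]
        vals, codes = np.unique(gt, return_inverse=True)
        codes = codes.reshape(gt.shape)
        k = len(vals)
        cnt = np.zeros((P, k))
        np.add.at(cnt, (pc, codes[:, 0]), 1)
        np.add.at(cnt, (pc, codes[:, 1]), 1)
        het = codes[:, 0] != codes[:, 1]
        hcnt = np.zeros((P, k))
        np.add.at(hcnt, (pc[het], codes[het, 0]), 1)
        np.add.at(hcnt, (pc[het], codes[het, 1]), 1)
        n_i = np.bincount(pc, minlength=P).astype(float)
        yield vals.astype(float), cnt, hcnt, n_i


def _pairwise_theta_terms(cnt, hcnt, n_i, ii, jj):
    """Weir-Cockerham (a, a+b+c) summed over alleles for every deme pair."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = cnt / (2 * n_i[:, None])
        h = hcnt / n_i[:, None]
    ni, nj = n_i[ii], n_i[jj]
    nbar = (ni + nj) / 2
    nc = (2 * nbar - (ni ** 2 + nj ** 2) / (2 * nbar))
    pi, pj = p[ii], p[jj]
    hi, hj = h[ii], h[jj]
    pbar = (ni[:, None] * pi + nj[:, None] * pj) / (2 * nbar[:, None])
    s2 = (ni[:, None] * (pi - pbar) ** 2 + nj[:, None] * (pj - pbar) ** 2) / nbar[:, None]
    hbar = (ni[:, None] * hi + nj[:, None] * hj) / (2 * nbar[:, None])
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar[:, None] / nc[:, None]) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar[:, None] - 1)
        )
        b = (nbar[:, None] / (nbar[:, None] - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar[:, None] - 1) / (4 * nbar[:, None]) * hbar
        )
    c = hbar / 2
    return np.nansum(a, axis=1), np.nansum(a + b + c, axis=1)


def summary_stats(sizes: np.ndarray, pops: np.ndarray, P: int) -> np.ndarray:
    """Summary vector from an (n, L, 2) repeat-size array and deme codes."""
    L = sizes.shape[1]
    pairs = _pairs(P)
    ii = np.array([p[0] for p in pairs], dtype=np.int64)
    jj = np.array([p[1] for p in pairs], dtype=np.int64)
    nal = np.zeros(P)
    het = np.zeros(P)
    vsz = np.zeros(P)
    fst_num = np.zeros(len(pairs))
    fst_den = np.zeros(len(pairs))
    dmu2 = np.zeros(len(pairs))
    for vals, cnt, hcnt, n_i in _locus_tables(sizes, pops, P):
        ng = 2 * n_i
        nal += (cnt > 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            psum2 = ((cnt / ng[:, None]) ** 2).sum(axis=1)
            het += np.where(ng > 1, ng / (ng - 1) * (1 - psum2), 0.0)
            m1 = (cnt * vals).sum(axis=1) / ng
            m2 = (cnt * vals ** 2).sum(axis=1)
            vsz += np.where(ng > 1, (m2 - ng * m1 ** 2) / (ng - 1), 0.0)
        a, tot = _pairwise_theta_terms(cnt, hcnt, n_i, ii, jj)
        fst_num += a
        fst_den += tot
        dmu2 += (m1[ii] - m1[jj]) ** 2
    nal /= L
    het /= L
    vsz /= L
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(fst_den != 0, fst_num / fst_den, 0.0)
    dmu2 /= L
    return np.concatenate([nal, het, vsz, fst, dmu2])


def _shared_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """(n1, n2) shared-allele counts (0..2) between diploid genotype arrays."""
    a1 = g1[:, 0][:, None]
    a2 = g1[:, 1][:, None]
    b1 = g2[:, 0][None, :]
    b2 = g2[:, 1][None, :]
    m11 = a1 == b1
    m12 = a1 == b2
    m21 = a2 == b1
    m22 = a2 == b2
    hom = (g1[:, 0] == g1[:, 1])[:, None]
    shared_het = (m11 | m12).astype(np.int64) + (m21 | m22).astype(np.int64)
    shared_hom = m11.astype(np.int64) + m12.astype(np.int64)
    return np.where(hom, shared_hom, shared_het)


def holdout_stats(sizes: np.ndarray, pops: np.ndarray, P: int) -> np.ndarray:
    """Holdout vector: Garza-Williamson M per deme, pooled two-sample allele
    counts and size variances, and shared-allele distance per deme pair."""
    L = sizes.shape[1]
    pairs = _pairs(P)
    ii = np.array([p[0] for p in pairs], dtype=np.int64)
    jj = np.array([p[1] for p in pairs], dtype=np.int64)
    gwm = np.zeros(P)
    nal2 = np.zeros(len(pairs))
    vsz2 = np.zeros(len(pairs))
    das = np.zeros(len(pairs))
    for vals, cnt, _h, n_i in _locus_tables(sizes, pops, P):
        present = cnt > 0
        k = present.sum(axis=1).astype(float)
        span = np.where(
            present.any(axis=1),
            np.array([
                (vals[row].max() - vals[row].min()) if row.any() else 0.0
                for row in present
            ]),
            0.0,
        )
        gwm += np.where(k > 0, k / (span + 1), 1.0)
        cnt2 = cnt[ii] + cnt[jj]
        ng2 = 2 * (n_i[ii] + n_i[jj])
        nal2 += (cnt2 > 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            m1 = (cnt2 * vals).sum(axis=1) / ng2
            m2 = (cnt2 * vals ** 2).sum(axis=1)
            vsz2 += np.where(ng2 > 1, (m2 - ng2 * m1 ** 2) / (ng2 - 1), 0.0)
    # shared-allele distance needs genotypes, not counts
    for q, (i, j) in enumerate(pairs):
        g1 = sizes[pops == i]
        g2 = sizes[pops == j]
        props = np.zeros((len(g1), len(g2)))
        used = np.zeros((len(g1), len(g2)))
        for l in range(L):
            t1 = g1[:, l, 0] != MISSING
            t2 = g2[:, l, 0] != MISSING
            if not (t1.any() and t2.any()):
                continue
            sh = _shared_counts(g1[t1, l], g2[t2, l]) / 2.0
            props[np.ix_(t1, t2)] += sh
            used[np.ix_(t1, t2)] += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_prop = np.where(used > 0, props / used, np.nan)
        das[q] = 1 - np.nanmean(mean_prop)
    return np.concatenate([gwm / L, nal2 / L, vsz2 / L, das])


def summary_vector(
    dataset: GenotypeDataset,
    partition: dict[str, str] | None = None,
    deme_order: list[str] | None = None,
) -> np.ndarray:
    """Summary vector of an observed dataset.

    ``partition`` maps population -> analysis deme.  ``deme_order`` fixes the
    deme indexing; it must match the reference table's scenario deme order
    when the vector is compared against one.  Default: order of first
    appearance in the dataset (which for simulated data is scenario order).
    """
    sizes = dataset.repeat_array()
    sizes = np.where(sizes == MISSING, MISSING, np.round(sizes)).astype(np.int64)
    pops = [r.population_id for r in dataset.records]
    if partition:
        deme_of = {p: partition[p] for p in set(pops)}
    else:
        deme_of = {p: p for p in set(pops)}
    if deme_order is None:
        demes = list(dict.fromkeys(deme_of[p] for p in pops))
    else:
        demes = list(deme_order)
        missing_demes = {deme_of[p] for p in pops} - set(demes)
        if missing_demes:
            raise ValueError(f"demes not in deme_order: {sorted(missing_demes)}")
    code = {d: i for i, d in enumerate(demes)}
    pc = np.array([code[deme_of[p]] for p in pops])
    counts = np.bincount(pc, minlength=len(demes))
    if (counts == 0).any():
        raise ValueError("empty analysis deme")
    return summary_stats(sizes, pc, len(demes))


# -- reference table --------------------------------------------------------


@dataclass
class ReferenceTable:
    """Rows of (scenario, parameter vector, summary vector) from the priors."""

    scenario_names: list[str]
    scenario_idx: np.ndarray  # (N,) int
    stats: np.ndarray  # (N, S)
    params: list[pd.DataFrame]  # one frame per scenario, in row order
    stat_names: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.scenario_idx)

    def rows_of(self, scenario: int) -> np.ndarray:
        return np.flatnonzero(self.scenario_idx == scenario)

    def concat(self, other: "ReferenceTable") -> "ReferenceTable":
        assert self.scenario_names == other.scenario_names
        return ReferenceTable(
            self.scenario_names,
            np.concatenate([self.scenario_idx, other.scenario_idx]),
            np.vstack([self.stats, other.stats]),
            [
                pd.concat([a, b], ignore_index=True)
                for a, b in zip(self.params, other.params)
            ],
            self.stat_names,
            self.provenance,
        )

    def to_csv(self, stats_path, provenance_path=None) -> None:
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        df.insert(0, "scenario", [self.scenario_names[i] for i in self.scenario_idx])
        df.to_csv(stats_path, index=False)
        if provenance_path:
            with open(provenance_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2)


def build_reference_table(
    scenario_kinds: list[str],
    prior_specs: dict[str, PriorSpec] | None = None,
    n_per_scenario: int = 1000,
    seed: int = 0,
    sample_sizes: list[int] | None = None,
    mutation_prior: MutationPrior | None = None,
    max_failure_rate: float = 0.01,
) -> ReferenceTable:
    """Prior-predictive simulation: n_per_scenario rows for each scenario.

    Reproducible for a fixed seed.  Simulation failures (invalid parameter
    combinations that slip through rejection, numerical issues) abort the run
    when they exceed ``max_failure_rate``.
    """
    mp = mutation_prior or MutationPrior()
    specs = {
        k: (prior_specs or {}).get(k) or default_prior_spec(k)
        for k in scenario_kinds
    }
    rng = np.random.default_rng(seed)
    P = 5
    S = len(summary_stat_names(P))
    idx_list = []
    stats = np.empty((n_per_scenario * len(scenario_kinds), S))
    params_frames: list[pd.DataFrame] = []
    row = 0
    failures = 0
    for s_i, kind in enumerate(scenario_kinds):
        recs = []
        done = 0
        while done < n_per_scenario:
            try:
                theta = sample_priors(specs[kind], rng)
                scen = build_scenario(kind, theta, sample_sizes)
                mm = mp.draw(rng)
                sim_seed = int(rng.integers(0, 2 ** 31 - 1))
                sizes, pops = simulate_repeat_matrix(scen, mm, sim_seed)
                stats[row] = summary_stats(sizes, pops, P)
            except (ValueError, FloatingPointError):
                failures += 1
                if failures > max(10, max_failure_rate * n_per_scenario * len(scenario_kinds)):
                    raise RuntimeError(
                        f"simulation failure rate exceeded {max_failure_rate:.0%}"
                    )
                continue
            recs.append(theta)
            idx_list.append(s_i)
            row += 1
            done += 1
        params_frames.append(pd.DataFrame(recs))
    return ReferenceTable(
        list(scenario_kinds),
        np.array(idx_list),
        stats[:row],
        params_frames,
        summary_stat_names(P),
        provenance={
            "seed": seed,
            "n_per_scenario": n_per_scenario,
            "scenarios": list(scenario_kinds),
        },
    )


# -- model choice -----------------------------------------------------------


def _standardize(stats: np.ndarray):
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    mad = np.where(mad > 0, mad, 1.0)
    return med, mad


@dataclass
class ModelChoiceResult:
    scenario_names: list[str]
    posterior: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    tolerance: float
    n_retained: int
    method: str  # "logistic" | "rejection"

    @property
    def best(self) -> str:
        return self.scenario_names[int(np.argmax(self.posterior))]


def model_choice_logistic(
    table: ReferenceTable,
    observed: np.ndarray,
    tolerance: float = 0.01,
) -> ModelChoiceResult:
    """Posterior scenario probabilities by local multinomial logistic regression.

    Summaries are standardized by reference-table median/MAD; the
    ``tolerance`` fraction of simulations closest (Euclidean) to the observed
    vector is retained; scenario identity is regressed on summary deviations
    and the fitted probabilities are evaluated at the observed point (zero
    deviation).  95% CIs come from the delta method on the asymptotic
    covariance.  Falls back to rejection counts (with a binomial CI) when a
    scenario is absent from the retained set or the fit is degenerate.
    """
    K = len(table.scenario_names)
    med, mad = _standardize(table.stats)
    z = (table.stats - med) / mad
    z_obs = (np.asarray(observed) - med) / mad
    d = np.linalg.norm(z - z_obs, axis=1)
    n_keep = max(50, int(math.ceil(tolerance * table.n_rows)))
    n_keep = min(n_keep, table.n_rows)
    keep = np.argsort(d)[:n_keep]
    y = table.scenario_idx[keep]
    X = z[keep] - z_obs

    counts = np.bincount(y, minlength=K).astype(float)

    def rejection_result() -> ModelChoiceResult:
        p = counts / counts.sum()
        se = np.sqrt(p * (1 - p) / counts.sum())
        return ModelChoiceResult(
            table.scenario_names, p,
            np.clip(p - 1.96 * se, 0, 1), np.clip(p + 1.96 * se, 0, 1),
            tolerance, n_keep, "rejection",
        )

    if (counts == 0).any():
        return rejection_result()
    try:
        import warnings as _w

        import statsmodels.api as sm

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            exog = sm.add_constant(X, has_constant="add")
            fit = sm.MNLogit(y, exog).fit(method="lbfgs", maxiter=500, disp=False)
        beta = np.asarray(fit.params)  # (k_exog, K-1)
        eta = np.concatenate([[0.0], beta[0]])  # at zero deviation
        eta -= eta.max()
        p = np.exp(eta) / np.exp(eta).sum()
        if not np.all(np.isfinite(p)):
            return rejection_result()
        # delta method on the intercepts (covariance order: per-equation blocks)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cov = np.asarray(fit.cov_params())
        if not np.all(np.isfinite(cov)):
            return rejection_result()
        k_exog = exog.shape[1]
        grad = np.zeros((K, (K - 1) * k_exog))
        for m in range(1, K):  # d eta_m / d intercept_m
            col = (m - 1) * k_exog
            for j in range(K):
                grad[j, col] = p[j] * ((1.0 if j == m else 0.0) - p[m])
        var = np.einsum("ji,ik,jk->j", grad, cov, grad)
        se = np.sqrt(np.clip(var, 0, None))
        return ModelChoiceResult(
            table.scenario_names, p,
            np.clip(p - 1.96 * se, 0, 1), np.clip(p + 1.96 * se, 0, 1),
            tolerance, n_keep, "logistic",
        )
    except Exception:
        return rejection_result()


# -- parameter estimation ---------------------------------------------------


@dataclass
class ParameterEstimate:
    names: list[str]
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    adjusted: bool
    posterior_sample: pd.DataFrame

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.median, "q2.5": self.ci_low, "q97.5": self.ci_high},
            index=self.names,
        )


def _logit(x, lo, hi):
    z = np.clip((x - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(z / (1 - z))


def _inv_logit(z, lo, hi):
    return lo + (hi - lo) / (1 + np.exp(-z))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, x)


def estimate_parameters(
    table: ReferenceTable,
    observed: np.ndarray,
    scenario: str,
    tolerance: float = 0.01,
    prior_spec: PriorSpec | None = None,
) -> ParameterEstimate:
    """Beaumont local-linear regression posterior for one scenario's parameters.

    The closest ``tolerance`` fraction of that scenario's simulations is
    retained with Epanechnikov weights; each parameter is logit-transformed
    to its prior bounds, adjusted by weighted linear regression on the summary
    deviations, and back-transformed, which also guarantees the adjusted
    draws never escape the prior support.  Reported: weighted posterior
    median and 2.5/97.5% quantiles.
    """
    s_i = table.scenario_names.index(scenario)
    rows = table.rows_of(s_i)
    params = table.params[s_i]
    med, mad = _standardize(table.stats)
    z = (table.stats[rows] - med) / mad
    z_obs = (np.asarray(observed) - med) / mad
    d = np.linalg.norm(z - z_obs, axis=1)
    n_keep = min(len(rows), max(50, int(math.ceil(tolerance * table.n_rows))))
    keep = np.argsort(d)[:n_keep]
    dk = d[keep]
    dmax = dk.max() if dk.max() > 0 else 1.0
    w = 1 - (dk / dmax) ** 2
    w = np.where(w > 0, w, 1e-12)
    X = z[keep] - z_obs

    spec = prior_spec or default_prior_spec(scenario)
    names = list(params.columns)
    adj = np.empty((n_keep, len(names)))
    adjusted = True
    for q, name in enumerate(names):
        lo, hi = spec.bounds.get(name, (None, None))
        theta = params[name].to_numpy()[keep]
        if lo is None or hi <= lo:
            lo, hi = theta.min() - 1e-9, theta.max() + 1e-9
        t = _logit(theta, lo, hi)
        A = np.column_stack([np.ones(n_keep), X])
        Aw = A * np.sqrt(w)[:, None]
        tw = t * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Aw, tw, rcond=None)
        if not np.all(np.isfinite(coef)):
            adjusted = False
            adj[:, q] = theta
            continue
        resid = t - A @ coef
        adj[:, q] = _inv_logit(coef[0] + resid, lo, hi)
    qs = np.array([0.025, 0.5, 0.975])
    lo_q = np.empty(len(names))
    med_q = np.empty(len(names))
    hi_q = np.empty(len(names))
    for q in range(len(names)):
        lo_q[q], med_q[q], hi_q[q] = _weighted_quantile(adj[:, q], w, qs)
    post = pd.DataFrame(adj, columns=names)
    post["_weight"] = w
    return ParameterEstimate(names, med_q, lo_q, hi_q, adjusted, post)


# -- validation machinery ---------------------------------------------------


def _simulate_pseudo(kind, spec, rng, sample_sizes, mp):
    theta = sample_priors(spec, rng)
    scen = build_scenario(kind, theta, sample_sizes)
    mm = mp.draw(rng)
    sizes, pops = simulate_repeat_matrix(scen, mm, int(rng.integers(0, 2 ** 31 - 1)))
    return theta, sizes, pops


def confidence_evaluation(
    table: ReferenceTable,
    focal_scenario: str,
    n_pseudo: int = 500,
    seed: int = 0,
    tolerance: float = 0.01,
    sample_sizes: list[int] | None = None,
    prior_specs: dict[str, PriorSpec] | None = None,
    mutation_prior: MutationPrior | None = None,
    scenario_kinds: dict[str, str] | None = None,
) -> dict[str, float]:
    """Type I and type II error of scenario choice over pseudo-observed data.

    ``scenario_kinds`` maps a table scenario label to its builder kind when
    labels are not themselves kinds (e.g. two copies of one kind).

    Type I: fraction of datasets simulated under the focal scenario for which
    it does not attain the highest posterior probability.  Type II: fraction
    of datasets simulated under competing scenarios for which the focal
    scenario wins.  Pseudo-observed parameters are drawn from the priors.
    """
    import warnings as _w

    if n_pseudo < 20:
        _w.warn("n_pseudo < 20 gives very coarse error-rate estimates")
    rng = np.random.default_rng(seed)
    mp = mutation_prior or MutationPrior()
    kinds = {
        name: (scenario_kinds or {}).get(name, name)
        for name in table.scenario_names
    }
    specs = {
        name: (prior_specs or {}).get(name) or default_prior_spec(kinds[name])
        for name in table.scenario_names
    }
    P = 5
    n_focal_wrong = 0
    n_comp_sims = 0
    n_comp_focal_wins = 0
    per_scenario = max(1, n_pseudo // len(table.scenario_names))
    for name in table.scenario_names:
        for _ in range(per_scenario):
            _t, sizes, pops = _simulate_pseudo(
                kinds[name], specs[name], rng, sample_sizes, mp
            )
            obs = summary_stats(sizes, pops, P)
            best = model_choice_logistic(table, obs, tolerance).best
            if name == focal_scenario:
                if best != focal_scenario:
                    n_focal_wrong += 1
            else:
                n_comp_sims += 1
                if best == focal_scenario:
                    n_comp_focal_wins += 1
    return {
        "type_I": n_focal_wrong / per_scenario,
        "type_II": n_comp_focal_wins / n_comp_sims if n_comp_sims else float("nan"),
        "n_per_scenario": per_scenario,
    }


def rmae(truths: pd.DataFrame, estimates: pd.DataFrame) -> pd.Series:
    """Relative median absolute error per parameter over pseudo-observed fits.

    RMAE = median over datasets of |estimate - truth| / truth; datasets whose
    truth is zero for a parameter are excluded for that parameter.
    """
    out = {}
    for col in truths.columns:
        t = truths[col].to_numpy(float)
        e = estimates[col].to_numpy(float)
        ok = t != 0
        if not ok.any():
            out[col] = float("nan")
            continue
        out[col] = float(np.median(np.abs(e[ok] - t[ok]) / t[ok]))
    return pd.Series(out)


def model_check(
    fitted: ParameterEstimate,
    scenario_kind: str,
    observed_holdout: np.ndarray,
    n: int = 10_000,
    seed: int = 0,
    sample_sizes: list[int] | None = None,
    mutation_prior: MutationPrior | None = None,
) -> pd.Series:
    """Posterior-predictive tail probabilities for the holdout statistics.

    Parameter vectors are resampled (by weight) from the adjusted posterior
    sample, a dataset simulated from each, and for every holdout statistic
    the lower-tail probability Pr(simulated <= observed) is reported; values
    near 0 or 1 flag components of the data the fitted scenario cannot
    reproduce.
    """
    rng = np.random.default_rng(seed)
    mp = mutation_prior or MutationPrior()
    post = fitted.posterior_sample
    w = post["_weight"].to_numpy()
    w = w / w.sum()
    P = 5
    sims = np.empty((n, len(holdout_stat_names(P))))
    for t in range(n):
        row = post.iloc[rng.choice(len(post), p=w)]
        theta = {k: float(row[k]) for k in fitted.names}
        scen = build_scenario(scenario_kind, theta, sample_sizes)
        mm = mp.draw(rng)
        sizes, pops = simulate_repeat_matrix(scen, mm, int(rng.integers(0, 2 ** 31 - 1)))
        sims[t] = holdout_stats(sizes, pops, P)
    obs = np.asarray(observed_holdout)
    p = (np.sum(sims < obs, axis=0) + 0.5 * np.sum(sims == obs, axis=0) + 0.5) / (n + 1)
    return pd.Series(p, index=holdout_stat_names(P))
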