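"""Coalescent simulation of multi-deme divergence scenarios with bottlenecks
and generalized stepwise microsatellite mutation.

The model is the continuous-time n-coalescent with piecewise-constant diploid
deme sizes and no migration: within a deme holding k lineages, coalescences
occur at rate k(k-1)/(4N) per generation.  Demographic events, ordered
backward in time, are deme mergers (forward-time colonizations) and size
changes; a colonization bottleneck is a size change to a small founder size
for a fixed number of generations immediately after (forward-time) founding.

Mutations follow the generalized stepwise model (GSM): Poisson events on
branches change the repeat count by a geometrically distributed number of
motif units (parameter P; P = 0 is the strict one-step SMM), with reflecting
boundaries at the allele-size range limits.

Four competing scenarios describe the origin of disjunct northern groves from
a large southern population: sequential (stepping-stone) northward
colonization, simultaneous mass colonization, simultaneous divergence after a
late-Pleistocene range restriction, and ancient independent divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import GenotypeDataset, GenotypeRecord, LocusDef, PopulationMeta

__all__ = [
    "DemographicScenario",
    "Event",
    "MutationModel",
    "MutationPrior",
    "PriorSpec",
    "GenerationTimeParams",
    "SCENARIO_KINDS",
    "DEFAULT_DEMES",
    "build_scenario",
    "default_prior_spec",
    "sample_priors",
    "simulate_tree",
    "simulate_repeat_matrix",
    "simulate_genotypes",
    "generation_time",
    "generations_to_years",
]


# -- scenario data model ----------------------------------------------------

MERGE, SIZE_CHANGE = 0, 1


@dataclass(frozen=True)
class Event:
    """A backward-time demographic event.

    kind 'merge': lineages of deme ``a`` move into deme ``b`` (forward-time
    colonization of ``a`` from ``b``).  kind 'size_change': deme ``a`` takes
    diploid size ``size`` for all older times (until a later event).
    """

    time: float  # generations before present
    kind: str  # "merge" | "size_change"
    a: int
    b: int = -1
    size: float = -1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.kind not in ("merge", "size_change"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "size_change" and self.size < 2:
            raise ValueError("deme sizes must be >= 2")


@dataclass
class DemographicScenario:
    """Deme list with current sizes, sample sizes, and an ordered event list."""

    kind: str
    deme_names: list[str]
    deme_sizes: list[float]  # current diploid effective sizes
    sample_sizes: list[int]  # diploid individuals sampled per deme
    events: list[Event] = field(default_factory=list)
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.deme_sizes) < 2:
            raise ValueError("deme sizes must be >= 2")
        self.events = sorted(self.events, key=lambda e: e.time)
        self.validate()

    def validate(self) -> None:
        """Check that the merger sequence reduces all demes to one ancestor."""
        alive = set(range(len(self.deme_names)))
        for ev in self.events:
            if ev.kind == "merge":
                if ev.a not in alive:
                    raise ValueError(f"merge of inactive deme {ev.a}")
                if ev.b not in alive:
                    raise ValueError(f"merge into inactive deme {ev.b}")
                alive.discard(ev.a)
        if len(alive) != 1:
            raise ValueError(
                f"events leave {len(alive)} demes that never share an ancestor"
            )

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = np.array([e.time for e in self.events], dtype=np.float64)
        k = np.array(
            [MERGE if e.kind == "merge" else SIZE_CHANGE for e in self.events],
            dtype=np.int64,
        )
        a = np.array([e.a for e in self.events], dtype=np.int64)
        b = np.array(
            [e.b if e.kind == "merge" else e.size for e in self.events],
            dtype=np.float64,
        )
        return t, k, a, b


# -- mutation model ---------------------------------------------------------


@dataclass
class MutationModel:
    """Per-locus GSM parameters (repeat-unit space).

    ``rates`` are per-generation mutation rates; ``p_geom`` the geometric step
    parameter (0 = strict SMM); sizes are reflected into
    [range_lo, range_hi].
    """

    rates: np.ndarray
    p_geom: np.ndarray
    range_lo: np.ndarray
    range_hi: np.ndarray
    motif_lengths: np.ndarray

    def __post_init__(self) -> None:
        for name in ("rates", "p_geom", "range_lo", "range_hi", "motif_lengths"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if np.any(self.rates < 0):
            raise ValueError("mutation rates must be non-negative")
        if np.any((self.p_geom < 0) | (self.p_geom >= 1)):
            raise ValueError("P must lie in [0, 1)")
        if np.any(self.range_lo >= self.range_hi):
            raise ValueError("allele range must be non-degenerate")

    @property
    def n_loci(self) -> int:
        return len(self.rates)

    @classmethod
    def uniform(cls, n_loci: int = 11, rate: float = 5e-4, p_geom: float = 0.22,
                n_states: int = 40, n_tri: int = 1) -> "MutationModel":
        """Equal-rate model: ``n_loci - n_tri`` dinucleotide loci plus
        ``n_tri`` trinucleotide loci, 40 contiguous allelic states."""
        motifs = np.array([2] * (n_loci - n_tri) + [3] * n_tri)
        return cls(
            rates=np.full(n_loci, rate),
            p_geom=np.full(n_loci, p_geom),
            range_lo=np.full(n_loci, 5.0),
            range_hi=np.full(n_loci, 5.0 + n_states - 1),
            motif_lengths=motifs,
        )


@dataclass
class MutationPrior:
    """Hyperprior over mutation models, one draw per simulated dataset.

    Mean rate uniform on [rate_lo, rate_hi]; per-locus rates Gamma about the
    mean (shape ``gamma_shape``); P uniform on [p_lo, p_hi]; a fixed window of
    ``n_states`` contiguous allelic states.
    """

    n_loci: int = 11
    n_tri: int = 1
    rate_lo: float = 1e-4
    rate_hi: float = 1e-3
    gamma_shape: float = 2.0
    p_lo: float = 0.1
    p_hi: float = 0.3
    n_states: int = 40

    def draw(self, rng: np.random.Generator) -> MutationModel:
        mean = rng.uniform(self.rate_lo, self.rate_hi)
        rates = rng.gamma(self.gamma_shape, mean / self.gamma_shape, self.n_loci)
        p = rng.uniform(self.p_lo, self.p_hi, self.n_loci)
        motifs = np.array([2] * (self.n_loci - self.n_tri) + [3] * self.n_tri)
        return MutationModel(
            rates=np.clip(rates, 1e-8, None),
            p_geom=p,
            range_lo=np.full(self.n_loci, 5.0),
            range_hi=np.full(self.n_loci, 5.0 + self.n_states - 1),
            motif_lengths=motifs,
        )


# -- priors -----------------------------------------------------------------


@dataclass
class PriorSpec:
    """Independent uniform priors plus inequality conditions between them.

    ``bounds`` maps parameter name -> (min, max); ``conditions`` is a list of
    (greater, lesser) name pairs that every accepted draw must satisfy
    (rejection sampling).
    """

    bounds: dict[str, tuple[float, float]]
    conditions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"prior for {name}: min > max")
        for g, l in self.conditions:
            if g not in self.bounds or l not in self.bounds:
                raise ValueError(f"condition on unknown parameter: {g} > {l}")

    def satisfied(self, params: dict[str, float]) -> bool:
        return all(params[g] > params[l] for g, l in self.conditions)


def default_prior_spec(kind: str) -> PriorSpec:
    """Default uniform priors for each scenario kind.

    Ranges are wide enough to contain plausible grove-scale effective sizes
    and late-Quaternary event times (in generations); fully overridable.
    """
    bounds = {
        "N1": (100.0, 10_000.0),
        "N2": (10.0, 1_000.0),
        "N3": (10.0, 1_000.0),
        "N4": (10.0, 1_000.0),
        "N5": (10.0, 1_000.0),
        "N_anc": (100.0, 100_000.0),
        "t_anc": (100.0, 10_000.0),
        "founder_N": (2.0, 100.0),
        "duration": (1.0, 50.0),
    }
    conditions: list[tuple[str, str]] = []
    if kind == "stepping_stone":
        bounds.update({f"t_col{i}": (10.0, 1_000.0) for i in range(1, 5)})
        conditions += [("t_col1", "t_col2"), ("t_col2", "t_col3"),
                       ("t_col3", "t_col4"), ("t_anc", "t_col1")]
    elif kind == "mass_colonization":
        bounds["t_col1"] = (10.0, 1_000.0)
        conditions += [("t_anc", "t_col1")]
    elif kind == "simultaneous_divergence":
        bounds["t_div1"] = (10.0, 1_000.0)
        bounds["N_div"] = (100.0, 10_000.0)
        conditions += [("t_anc", "t_div1")]
    elif kind == "ancient_divergence":
        bounds["t_div2"] = (1_000.0, 10_000.0)
        bounds["N_div"] = (100.0, 10_000.0)
        conditions += [("t_anc", "t_div2")]
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    return PriorSpec(bounds, conditions)


def sample_priors(prior_spec: PriorSpec, rng: np.random.Generator,
                  max_rejections: int = 100_000) -> dict[str, float]:
    """Draw one parameter vector by rejection against the conditions."""
    names = list(prior_spec.bounds)
    for _ in range(max_rejections):
        draw = {
            n: rng.uniform(*prior_spec.bounds[n]) if prior_spec.bounds[n][0] < prior_spec.bounds[n][1]
            else prior_spec.bounds[n][0]
            for n in names
        }
        if prior_spec.satisfied(draw):
            return draw
    raise RuntimeError("prior conditions appear unsatisfiable (rejection limit hit)")


# -- scenario builder -------------------------------------------------------

DEFAULT_DEMES = ["South", "McKinley", "MariposaNelder", "TuolumneMerced", "Calaveras"]
SCENARIO_KINDS = (
    "stepping_stone",
    "mass_colonization",
    "simultaneous_divergence",
    "ancient_divergence",
)


def build_scenario(
    kind: str,
    params: dict[str, float],
    sample_sizes: list[int] | None = None,
    deme_names: list[str] | None = None,
) -> DemographicScenario:
    """Assemble the event list for one of the four competing scenarios.

    Demes (index order): 0 pooled southern groves (N1), 1 McKinley (N2),
    2 Mariposa+Nelder (N3), 3 Tuolumne+Merced (N4), 4 Calaveras pair (N5).

    stepping_stone: Calaveras founded from Tuolumne+Merced (t_col4), those
    from Mariposa+Nelder (t_col3), those from McKinley (t_col2), McKinley from
    the south (t_col1), t_col1 > ... > t_col4, each colonization followed by a
    founder bottleneck.  mass_colonization: all four northern demes founded
    from the south at t_col1, with bottlenecks.  simultaneous_divergence: all
    five demes split at t_div1 from a population of size N_div (the
    late-Pleistocene restriction).  ancient_divergence: the same split in the
    deep past at t_div2.  All scenarios change the ancestral deme to N_anc at
    t_anc, which must postdate (in backward time) every other event.
    """
    names = deme_names or list(DEFAULT_DEMES)
    sizes = [params[f"N{i}"] for i in range(1, 6)]
    samples = sample_sizes or [20, 10, 10, 10, 10]
    fN = params.get("founder_N", 10.0)
    dur = params.get("duration", 10.0)
    events: list[Event] = []

    def bottleneck(deme: int, t_found: float) -> None:
        t0 = max(0.0, t_found - dur)
        events.append(Event(t0, "size_change", deme, size=max(2.0, fN)))

    if kind == "stepping_stone":
        t1, t2, t3, t4 = (params[f"t_col{i}"] for i in range(1, 5))
        if not (t1 > t2 > t3 > t4):
            raise ValueError("stepping-stone colonization times must be ordered")
        for deme, t_found, dest in ((4, t4, 3), (3, t3, 2), (2, t2, 1), (1, t1, 0)):
            bottleneck(deme, t_found)
            events.append(Event(t_found, "merge", deme, b=dest))
        t_last = t1
    elif kind == "mass_colonization":
        t1 = params["t_col1"]
        for deme in (1, 2, 3, 4):
            bottleneck(deme, t1)
            events.append(Event(t1, "merge", deme, b=0))
        t_last = t1
    elif kind in ("simultaneous_divergence", "ancient_divergence"):
        t_div = params["t_div1" if kind == "simultaneous_divergence" else "t_div2"]
        for deme in (1, 2, 3, 4):
            events.append(Event(t_div, "merge", deme, b=0))
        events.append(Event(t_div, "size_change", 0, size=params["N_div"]))
        t_last = t_div
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")

    t_anc = params["t_anc"]
    if t_anc <= t_last:
        raise ValueError("t_anc must predate every divergence/colonization event")
    events.append(Event(t_anc, "size_change", 0, size=params["N_anc"]))
    return DemographicScenario(kind, names, sizes, samples, events, dict(params))


# -- numba kernels ----------------------------------------------------------


@njit(cache=True)
def _seed_kernel(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _coalescent_tree(samp, N0, ev_t, ev_k, ev_a, ev_b):
    """One genealogy: returns (parent, node_time) arrays of length 2n-1.

    Lineage bookkeeping uses flat arrays; parents are always created after
    their children, so node index order is also time order.
    """
    D = len(samp)
    n = 0
    for d in range(D):
        n += samp[d]
    ntot = 2 * n - 1
    parent = np.full(ntot, -1, dtype=np.int64)
    ntime = np.zeros(ntot, dtype=np.float64)
    act_id = np.empty(n, dtype=np.int64)
    act_deme = np.empty(n, dtype=np.int64)
    pos = 0
    for d in range(D):
        for _ in range(samp[d]):
            act_id[pos] = pos
            act_deme[pos] = d
            pos += 1
    k = n
    nxt = n
    t = 0.0
    N = N0.copy()
    ei = 0
    nev = len(ev_t)
    kd = np.zeros(D, dtype=np.int64)
    while k > 1:
        for d in range(D):
            kd[d] = 0
        for i in range(k):
            kd[act_deme[i]] += 1
        rate = 0.0
        for d in range(D):
            rate += kd[d] * (kd[d] - 1) / (4.0 * N[d])
        if rate <= 0.0:
            if ei >= nev:
                # should be unreachable for a validated scenario
                break
            t = ev_t[ei]
        else:
            dt = np.random.exponential(1.0 / rate)
            if ei < nev and t + dt >= ev_t[ei]:
                t = ev_t[ei]
            else:
                t = t + dt
                # choose deme proportional to its coalescence rate
                u = np.random.random() * rate
                acc = 0.0
                ch = 0
                for d in range(D):
                    acc += kd[d] * (kd[d] - 1) / (4.0 * N[d])
                    if u <= acc:
                        ch = d
                        break
                # pick two distinct active lineages in deme ch
                i1 = np.random.randint(0, kd[ch])
                i2 = np.random.randint(0, kd[ch] - 1)
                if i2 >= i1:
                    i2 += 1
                # map within-deme indices to positions in the active arrays
                c = -1
                p1 = -1
                p2 = -1
                for i in range(k):
                    if act_deme[i] == ch:
                        c += 1
                        if c == i1:
                            p1 = i
                        if c == i2:
                            p2 = i
                parent[act_id[p1]] = nxt
                parent[act_id[p2]] = nxt
                ntime[nxt] = t
                act_id[p1] = nxt
                act_id[p2] = act_id[k - 1]
                act_deme[p2] = act_deme[k - 1]
                nxt += 1
                k -= 1
                continue
        # at an event time: apply every event scheduled at this instant
        while ei < nev and ev_t[ei] <= t:
            if ev_k[ei] == 0:  # merge a -> b
                for i in range(k):
                    if act_deme[i] == ev_a[ei]:
                        act_deme[i] = np.int64(ev_b[ei])
            else:  # size change
                N[ev_a[ei]] = ev_b[ei]
            ei += 1
    return parent, ntime


@njit(cache=True)
def _drop_mutations(parent, ntime, n_leaves, mu, p_geom, lo, hi, root_allele):
    """Place GSM mutations on the genealogy; return leaf repeat counts."""
    ntot = len(parent)
    allele = np.empty(ntot, dtype=np.float64)
    allele[ntot - 1] = root_allele
    logp = math.log(p_geom) if p_geom > 0.0 else 0.0
    for i in range(ntot - 2, -1, -1):
        a = allele[parent[i]]
        blen = ntime[parent[i]] - ntime[i]
        nmut = np.random.poisson(mu * blen)
        for _ in range(nmut):
            if p_geom > 0.0:
                u = np.random.random()
                step = int(math.ceil(math.log(1.0 - u) / logp))
                if step < 1:
                    step = 1
            else:
                step = 1
            if np.random.random() < 0.5:
                step = -step
            a = a + step
            # reflect into [lo, hi]
            for _b in range(64):
                if a > hi:
                    a = 2.0 * hi - a
                elif a < lo:
                    a = 2.0 * lo - a
                else:
                    break
        allele[i] = a
    out = np.empty(n_leaves, dtype=np.int64)
    for i in range(n_leaves):
        out[i] = np.int64(round(allele[i]))
    return out


# -- public simulation API --------------------------------------------------


def simulate_tree(scenario: DemographicScenario, seed: int | None = None):
    """Simulate one genealogy; returns (parent, node_times) arrays.

    Node indices 0..n-1 are the sampled gene copies (2 per diploid individual,
    deme-blocked in scenario order); internal nodes follow in coalescence
    order, the root last.
    """
    if seed is not None:
        _seed_kernel(seed)
    samp = np.array([2 * s for s in scenario.sample_sizes], dtype=np.int64)
    N0 = np.array(scenario.deme_sizes, dtype=np.float64)
    return _coalescent_tree(samp, N0, *scenario.event_arrays())


def simulate_repeat_matrix(
    scenario: DemographicScenario,
    mutation_model: MutationModel,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate all loci; returns (repeats, pop_codes).

    ``repeats`` is (n_individuals, n_loci, 2) integer repeat counts;
    ``pop_codes`` the deme index of each individual.  Loci are independent
    genealogies under the same demography.
    """
    if seed is not None:
        _seed_kernel(seed)
    samp = np.array([2 * s for s in scenario.sample_sizes], dtype=np.int64)
    N0 = np.array(scenario.deme_sizes, dtype=np.float64)
    ev = scenario.event_arrays()
    n_genes = int(samp.sum())
    L = mutation_model.n_loci
    genes = np.empty((n_genes, L), dtype=np.int64)
    for j in range(L):
        parent, ntime = _coalescent_tree(samp, N0, *ev)
        lo, hi = mutation_model.range_lo[j], mutation_model.range_hi[j]
        root = float(round((lo + hi) / 2))
        genes[:, j] = _drop_mutations(
            parent, ntime, n_genes, mutation_model.rates[j],
            mutation_model.p_geom[j], lo, hi, root,
        )
    # pair consecutive gene copies into diploid individuals
    repeats = genes.reshape(n_genes // 2, 2, L).transpose(0, 2, 1)
    pop_codes = np.repeat(
        np.arange(len(scenario.sample_sizes)), scenario.sample_sizes
    )
    return np.ascontiguousarray(repeats), pop_codes


def simulate_genotypes(
    scenario: DemographicScenario,
    mutation_model: MutationModel | None = None,
    seed: int | None = None,
) -> GenotypeDataset:
    """Simulate a full :class:`GenotypeDataset` under a scenario.

    Allele sizes in bp are repeat count x motif length (offset 0), so the
    repeat-unit view recovers the simulated counts exactly.
    """
    mm = mutation_model or MutationModel.uniform()
    repeats, pops = simulate_repeat_matrix(scenario, mm, seed)
    loci = [
        LocusDef(f"L{j + 1}", motif_length=int(mm.motif_lengths[j]))
        for j in range(mm.n_loci)
    ]
    records = []
    for i in range(repeats.shape[0]):
        pop = scenario.deme_names[pops[i]]
        calls = tuple(
            (
                int(repeats[i, j, 0] * mm.motif_lengths[j]),
                int(repeats[i, j, 1] * mm.motif_lengths[j]),
            )
            for j in range(mm.n_loci)
        )
        records.append(GenotypeRecord(f"{pop}_{i}", pop, calls))
    meta = [
        PopulationMeta(name, 36.0 + 0.5 * d, -118.0 - 0.2 * d, 100.0, "sim")
        for d, name in enumerate(scenario.deme_names)
    ]
    return GenotypeDataset(loci, records, meta)


# -- generation time --------------------------------------------------------


@dataclass(frozen=True)
class GenerationTimeParams:
    """Lande's generation-time inputs for an age-structured perennial.

    alpha: age at sexual maturity (years); s: adult annual survival;
    lam: asymptotic population growth rate (about 1 for a stable population).
    """

    alpha: float
    s: float = 0.995
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= self.s:
            raise ValueError("lambda must exceed adult survival s")


def generation_time(params: GenerationTimeParams) -> float:
    """Lande's T = alpha + s / (lambda - s), in years."""
    return params.alpha + params.s / (params.lam - params.s)


def generations_to_years(g: float, t_gen_years: float) -> dict[str, float]:
    """Convert a time in generations to years / kya / Mya at T years/generation."""
    if g < 0:
        raise ValueError("generations must be non-negative")
    years = g * t_gen_years
    return {"years": years, "kya": years / 1e3, "mya": years / 1e6}
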