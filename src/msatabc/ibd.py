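"""Isolation by distance: distance matrices and (partial) Mantel tests.

An elongated, grove-structured range confounds isolation by distance with
discrete north/south grouping, so the genetic distance matrix is tested both
against geographic distance and against a binary like-group/unlike-group
indicator matrix, with each controlled for the other by partial Mantel tests
(residual permutation, Legendre & Legendre).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeDataset, PopulationMeta

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DistanceMatrix",
    "great_circle_matrix",
    "indicator_matrix",
    "mantel_test",
    "partial_mantel_test",
    "filter_small_populations",
    "MantelResult",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "generic"  # genetic | geographic | log-geographic | indicator

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v


def great_circle_matrix(meta: list[PopulationMeta]) -> DistanceMatrix:
    """Pairwise haversine distances (km) between population centroids."""
    lat = np.radians([m.latitude for m in meta])
    lon = np.radians([m.longitude for m in meta])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([m.population_id for m in meta], d, "geographic")


def indicator_matrix(meta: list[PopulationMeta], group_assignment: dict[str, str] | None = None) -> DistanceMatrix:
    """0/1 matrix: 0 for pairs from a like group, 1 for unlike-group pairs."""
    if group_assignment is None:
        group_assignment = {m.population_id: m.group_label for m in meta}
    labels = [m.population_id for m in meta]
    unassigned = [p for p in labels if not group_assignment.get(p)]
    if unassigned:
        raise ValueError(f"populations without a group: {unassigned}")
    g = np.array([group_assignment[p] for p in labels], dtype=object)
    v = (g[:, None] != g[None, :]).astype(float)
    return DistanceMatrix(labels, v, "indicator")


def _triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    tail: str
    seed: int | None


def _check_pair(A: DistanceMatrix, B: DistanceMatrix) -> None:
    if A.labels != B.labels:
        raise ValueError("matrices must share the same population ordering")


def _tail_p(perm_r: np.ndarray, obs: float, tail: str) -> float:
    if tail == "greater":
        hits = np.sum(perm_r >= obs - 1e-12)
    elif tail == "less":
        hits = np.sum(perm_r <= obs + 1e-12)
    elif tail == "two-sided":
        hits = np.sum(np.abs(perm_r) >= abs(obs) - 1e-12)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((hits + 1) / (len(perm_r) + 1))


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 30_000,
    seed: int | None = None,
    log_transform_B: bool = False,
    tail: str = "greater",
) -> MantelResult:
    """Mantel correlation of two distance matrices with permutation p-value.

    Pearson correlation of the off-diagonal upper triangles; significance by
    simultaneous row/column permutation of B.  ``tail`` is directional by
    default ('greater': observed r at least as large as permuted).
    """
    _check_pair(A, B)
    b = B.values
    if log_transform_B:
        tri = _triangle(b)
        if np.any(tri <= 0):
            raise ValueError("log transform requires strictly positive distances")
        b = np.where(np.eye(len(B.labels), dtype=bool), 0.0, np.log(b, where=b > 0))
    xa, xb = _triangle(A.values), _triangle(b)
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("zero-variance distance triangle: r undefined")
    obs = float(np.corrcoef(xa, xb)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(A.labels)
    perm_r = np.empty(n_perm)
    for t in range(n_perm):
        idx = rng.permutation(n)
        perm_r[t] = np.corrcoef(xa, _triangle(b[np.ix_(idx, idx)]))[0, 1]
    return MantelResult(obs, _tail_p(perm_r, obs, tail), n_perm, tail, seed)


def partial_mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 30_000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C (residual permutation).

    A and B triangles are each regressed on the C triangle; the correlation of
    the residuals is tested by permuting the rows/columns of A's residual
    matrix (Legendre's method).
    """
    _check_pair(A, B)
    _check_pair(A, C)
    xa, xb, xc = (_triangle(m.values) for m in (A, B, C))
    if xc.std() == 0:
        raise ValueError("control matrix has zero variance")

    def residuals(y: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(xc), xc])
        return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

    ra, rb = residuals(xa), residuals(xb)
    if rb.std() == 0:
        raise ValueError("B perfectly collinear with C")
    obs = float(np.corrcoef(ra, rb)[0, 1])
    # rebuild A-residuals as a symmetric matrix to permute rows/columns
    n = len(A.labels)
    ra_mat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    ra_mat[iu] = ra
    ra_mat = ra_mat + ra_mat.T
    rng = np.random.default_rng(seed)
    perm_r = np.empty(n_perm)
    for t in range(n_perm):
        idx = rng.permutation(n)
        perm_r[t] = np.corrcoef(ra_mat[np.ix_(idx, idx)][iu], rb)[0, 1]
    return MantelResult(obs, _tail_p(perm_r, obs, tail), n_perm, tail, seed)


def filter_small_populations(dataset: GenotypeDataset, min_n: int = 10):
    """Drop populations with fewer than min_n individuals; return (dataset, log)."""
    sizes = dataset.sample_sizes()
    dropped = sorted(p for p, n in sizes.items() if n < min_n)
    keep = [p for p in dataset.population_ids if p not in dropped]
    if not keep:
        raise ValueError("filter would remove every population")
    return dataset.subset_populations(keep), dropped
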