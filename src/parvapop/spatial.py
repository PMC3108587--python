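"""Population structure in space: MDS, Mantel IBD test, source regressions.

Under stepping-stone spread, differentiation grows with geographic distance
(isolation by distance) and diversity decays with distance from the source;
under long-distance (jump) spread neither pattern is expected.  The Mantel
test correlates the off-diagonal elements of a genetic and a geographic
distance matrix, with significance from simultaneous row/column permutation
of one matrix.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from parvapop.errors import InputError, ParameterError
from parvapop.popio import PopulationMap

EARTH_RADIUS_KM = 6371.0
FST_LOG_FLOOR = 1e-4


def geo_distance_matrix(
    popmap: PopulationMap,
    populations: list[str] | None = None,
    mode: str = "euclidean_degrees",
) -> pd.DataFrame:
    """Pairwise geographic distances between population sites.

    ``euclidean_degrees`` treats (lat, lon) as planar coordinates (the
    convention mirrored from the original analysis over Europe);
    ``haversine_km`` computes great-circle distances.
    """
    if populations is None:
        populations = popmap.populations
    coords = {}
    missing = []
    for p in populations:
        lat, lon = popmap.coords_of(p)
        if math.isnan(lat) or math.isnan(lon):
            missing.append(p)
        coords[p] = (lat, lon)
    if missing:
        raise InputError(f"missing coordinates for populations: {missing}")
    out = pd.DataFrame(0.0, index=populations, columns=populations)
    for a, b in itertools.combinations(populations, 2):
        la, lo = coords[a]
        lb, lo2 = coords[b]
        if mode == "euclidean_degrees":
            d = math.hypot(la - lb, lo - lo2)
        elif mode == "haversine_km":
            phi1, phi2 = math.radians(la), math.radians(lb)
            dphi = phi2 - phi1
            dlmb = math.radians(lo2 - lo)
            h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
            d = 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))
        else:
            raise ParameterError(f"unknown mode {mode!r}")
        out.loc[a, b] = out.loc[b, a] = d
    return out


@dataclass(frozen=True)
class MantelResult:
    r: float
    Z: float
    p: float
    permutations: int


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def mantel_test(
    genetic: pd.DataFrame,
    geographic: pd.DataFrame,
    transform: str = "log10_fst",
    nperm: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """One-sided Mantel test of genetic against geographic distance.

    ``r`` is the Pearson correlation of the upper-triangle elements; the
    null distribution permutes rows and columns of the genetic matrix
    simultaneously; ``p = (#{r_perm >= r_obs} + 1)/(nperm + 1)``.  The
    ``log10_fst`` transform floors FST at 1e-4 before taking logs (the
    conventional normalising transform for FST matrices that may contain
    zeros).  ``Z`` is the classical cross-product statistic over i < j.
    """
    if list(genetic.index) != list(geographic.index):
        common = [p for p in genetic.index if p in set(geographic.index)]
        if len(common) < 4:
            raise ParameterError("need >= 4 shared populations")
        genetic = genetic.loc[common, common]
        geographic = geographic.loc[common, common]
    if genetic.shape[0] < 4:
        raise ParameterError("need >= 4 populations")
    g = genetic.to_numpy(dtype=float).copy()
    if transform == "log10_fst":
        g = np.log10(np.maximum(g, FST_LOG_FLOOR))
        np.fill_diagonal(g, 0.0)
    elif transform != "none":
        raise ParameterError(f"unknown transform {transform!r}")
    e = geographic.to_numpy(dtype=float)
    x = _offdiag(g)
    y = _offdiag(e)
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    Z = float(np.sum(x * y))
    rng = np.random.default_rng(seed)
    n = g.shape[0]
    count = 0
    ys = (y - y.mean()) / y.std()
    for _ in range(nperm):
        perm = rng.permutation(n)
        xp = _offdiag(g[np.ix_(perm, perm)])
        r_perm = float(np.mean((xp - xp.mean()) / xp.std() * ys))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (nperm + 1)
    return MantelResult(r=r_obs, Z=Z, p=p, permutations=nperm)


@dataclass(frozen=True)
class IbdRegression:
    response: str
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray, response: str) -> IbdRegression:
    if len(x) < 3:
        raise ParameterError("regression needs >= 3 points")
    res = stats.linregress(x, y)
    return IbdRegression(
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
    )


def ibd_regressions(
    source_pop: str,
    fst: pd.DataFrame,
    records: pd.DataFrame,
    geo: pd.DataFrame,
    exclude=(),
) -> list[IbdRegression]:
    """Distance-from-source regressions discriminating spread models.

    Fits OLS of (1) FST(source, i), (2) haplotype diversity H_i and (3)
    nucleotide diversity pi_i against geographic distance from the source
    population.  ``exclude`` drops named populations (e.g. known
    recently-bottlenecked satellites) from all three fits.
    """
    if source_pop not in fst.index:
        raise InputError(f"source population {source_pop!r} not in FST matrix")
    targets = [
        p
        for p in fst.index
        if p != source_pop and p not in set(exclude) and p in geo.index and p in records.index
    ]
    dist = np.array([geo.loc[source_pop, p] for p in targets])
    out = [
        _ols(dist, np.array([fst.loc[source_pop, p] for p in targets]), "fst_from_source"),
        _ols(dist, np.array([records.loc[p, "H"] for p in targets]), "H"),
        _ols(dist, np.array([records.loc[p, "pi"] for p in targets]), "pi"),
    ]
    return out


def classical_mds(matrix: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS by double centering of squared distances.

    ``B = -1/2 J D^2 J``; coordinates come from the top positive eigenpairs.
    Negative eigenvalues (non-Euclidean input) are truncated with a warning;
    the output is centred at the origin.
    """
    labels = list(matrix.index)
    D = matrix.to_numpy(dtype=float)
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    if (~pos[: min(dims, n)]).any():
        warnings.warn("negative/zero eigenvalues truncated in classical MDS")
    avail = int(pos.sum())
    use = min(dims, avail)
    if use < dims:
        warnings.warn(f"only {use} positive dimensions available (requested {dims})")
    if use == 0:
        coords = np.zeros((n, dims))
        return pd.DataFrame(coords, index=labels, columns=[f"dim{i+1}" for i in range(dims)])
    coords = vecs[:, :use] * np.sqrt(vals[:use])
    if use < dims:
        coords = np.hstack([coords, np.zeros((n, dims - use))])
    coords = coords - coords.mean(axis=0)
    return pd.DataFrame(coords, index=labels, columns=[f"dim{i+1}" for i in range(dims)])
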