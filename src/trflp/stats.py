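"""Community ordination and correlation statistics.

Samples are compared by Bray-Curtis dissimilarity, embedded in two
dimensions by nonmetric multidimensional scaling (NMDS, Kruskal stress-1),
environmental variables are fitted as vectors onto the ordination with
Monte-Carlo permutation tests, and taxon/T-RF abundances are correlated
with process parameters by Spearman's rank coefficient.

Note that, as is conventional for fingerprint-correlation heatmaps, the
Spearman p-values carry **no multiple-testing correction**: the p < 0.01
and p < 0.001 flags are raw per-cell thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import isotonic_regression
from skbio import DistanceMatrix


@dataclass
class Ordination:
    """A 2-D NMDS solution: per-sample coordinates and final stress."""

    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    seed: int
    n_restarts: int
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coordinates,
                            index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=[f"NMDS{i+1}" for i in range(self.coordinates.shape[1])])


@dataclass
class VectorFit:
    """Least-squares fit of one variable onto ordination axes."""

    variable: str
    direction: np.ndarray  # unit vector
    r_squared: float
    p_perm: float
    n_used: int


@dataclass
class CorrelationCell:
    """One taxon/T-RF x parameter Spearman correlation."""

    taxon_or_trf: str
    parameter: str
    rho: float
    p_value: float
    n: int

    @property
    def flag(self) -> str:
        if self.p_value < 0.001:
            return "p<0.001"
        if self.p_value < 0.01:
            return "p<0.01"
        return "none"


def bray_curtis(abundance, sample_ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk).

    Accepts a samples x features array, a DataFrame (index = sample ids), or
    a TRFMatrix-like object with ``abundance``/``sample_ids`` attributes.
    A pair of all-zero rows has an undefined denominator and raises.
    """
    if hasattr(abundance, "abundance"):  # TRFMatrix
        sample_ids = list(abundance.sample_ids)
        x = np.asarray(abundance.abundance, dtype=float)
    elif isinstance(abundance, pd.DataFrame):
        sample_ids = [str(s) for s in abundance.index]
        x = abundance.to_numpy(dtype=float)
    else:
        x = np.asarray(abundance, dtype=float)
        if sample_ids is None:
            sample_ids = [str(i) for i in range(x.shape[0])]
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    off = ~np.eye(len(x), dtype=bool)
    if np.any(den[off] == 0):
        i, j = np.argwhere((den == 0) & off)[0]
        raise ValueError(f"samples {sample_ids[i]!r} and {sample_ids[j]!r} are both "
                         "all-zero: Bray-Curtis undefined")
    d = np.zeros_like(num)
    np.divide(num, den, out=d, where=off)
    return DistanceMatrix(d, ids=sample_ids)


def _stress1(config_d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((config_d ** 2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((dhat - config_d) ** 2).sum()) / denom)


def _pairdist(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def nmds(d: DistanceMatrix, dims: int = 2, n_restarts: int = 20,
         seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> Ordination:
    """Nonmetric multidimensional scaling minimizing Kruskal stress-1.

    Each restart starts from a random configuration and alternates isotonic
    regression of configuration distances on the rank order of the input
    dissimilarities (pool-adjacent-violators) with a Guttman-transform
    configuration update, damped by step halving so stress never increases
    within a restart. The best of ``n_restarts`` solutions is returned;
    the result is deterministic for a given seed. Coordinates are centered
    and principal-axis rotated.
    """
    delta = d.data
    n = delta.shape[0]
    if n < 4:
        raise ValueError("NMDS needs at least 4 samples")
    iu = np.triu_indices(n, 1)
    order = np.argsort(delta[iu], kind="stable")
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for _ in range(n_restarts):
        x = rng.standard_normal((n, dims))
        cd = _pairdist(x)
        dhat_vec = np.empty(len(order))
        dhat_vec[order] = isotonic_regression(cd[iu][order]).x
        stress = _stress1(cd[iu], dhat_vec)
        converged = False
        for _ in range(max_iter):
            # Guttman transform toward the monotone-regressed distances
            dhat = np.zeros_like(cd)
            dhat[iu] = dhat_vec
            dhat += dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cd > 0, dhat / np.where(cd > 0, cd, 1.0), 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x_new = b @ x / n
            step = 1.0
            while True:
                x_try = x + step * (x_new - x)
                cd_try = _pairdist(x_try)
                dv_try = np.empty(len(order))
                dv_try[order] = isotonic_regression(cd_try[iu][order]).x
                s_try = _stress1(cd_try[iu], dv_try)
                if s_try <= stress or step < 1e-4:
                    break
                step /= 2.0
            if s_try > stress:
                converged = True  # no downhill move left
                break
            x, cd, dhat_vec = x_try, cd_try, dv_try
            if stress - s_try < tol:
                stress = s_try
                converged = True
                break
            stress = s_try
        any_converged = any_converged or converged
        if best is None or stress < best[0]:
            best = (stress, x, converged)
    stress, x, converged = best
    if stress < 1e-3:
        warnings.warn("nearly zero stress: the rank order of the dissimilarities "
                      "is perfectly representable (often a sign of widely "
                      "separated sample groups); inspect the configuration for "
                      "degenerate clustering", stacklevel=2)
    if not converged:
        warnings.warn("NMDS best restart hit the iteration cap without "
                      f"stress change < {tol}; returning best-so-far", stacklevel=2)
    x = x - x.mean(axis=0)
    # principal-axis orientation for a reproducible frame
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    # sign convention: largest-magnitude loading positive per axis
    for j in range(x.shape[1]):
        i = np.argmax(np.abs(x[:, j]))
        if x[i, j] < 0:
            x[:, j] = -x[:, j]
    return Ordination(sample_ids=list(d.ids), coordinates=x, stress=stress,
                      seed=seed, n_restarts=n_restarts, converged=converged)


def _fit_r2(coords: np.ndarray, y: np.ndarray):
    """Least-squares projection of centered y on centered coordinates."""
    xc = coords - coords.mean(axis=0)
    yc = y - y.mean()
    b, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    sst = float(yc @ yc)
    if sst == 0:
        return b, 0.0
    fitted = xc @ b
    r2 = float(fitted @ fitted) / sst
    return b, r2


def fit_vectors(ordination: Ordination, table: pd.DataFrame, n_perm: int = 1000,
                seed: int = 0) -> list[VectorFit]:
    """Fit each column of *table* as a vector onto the ordination.

    Direction and r-squared come from least-squares projection of the
    centered variable onto the ordination coordinates; significance from a
    Monte-Carlo permutation test shuffling the variable across samples,
    p = (1 + #{permuted r2 >= observed}) / (n_perm + 1). Samples with
    missing values are dropped per variable; constant or nearly-empty
    variables are skipped with a warning.
    """
    table = table.loc[ordination.sample_ids]
    rng = np.random.default_rng(seed)
    fits = []
    for name in table.columns:
        col = pd.to_numeric(table[name], errors="coerce")
        mask = col.notna().to_numpy()
        if mask.sum() < 4:
            warnings.warn(f"variable {name!r}: fewer than 4 non-missing samples; skipped",
                          stacklevel=2)
            continue
        y = col.to_numpy(dtype=float)[mask]
        if np.ptp(y) == 0:
            warnings.warn(f"variable {name!r} is constant; skipped", stacklevel=2)
            continue
        coords = ordination.coordinates[mask]
        b, r2 = _fit_r2(coords, y)
        exceed = 0
        for _ in range(n_perm):
            _, r2p = _fit_r2(coords, rng.permutation(y))
            if r2p >= r2:
                exceed += 1
        norm = float(np.linalg.norm(b))
        direction = b / norm if norm > 0 else np.array([1.0] + [0.0] * (len(b) - 1))
        fits.append(VectorFit(variable=str(name), direction=direction, r_squared=r2,
                              p_perm=(1 + exceed) / (n_perm + 1), n_used=int(mask.sum())))
    return fits


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for small n (enumeration over y orders)."""
    n = len(xr)
    if n > 9:
        raise ValueError("exact permutation p supported for n <= 9")
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    obs = abs(rho)
    count = 0
    total = 0
    for perm in _permutations(range(n)):
        r = float(xc @ yc[list(perm)]) / denom
        total += 1
        if abs(r) >= obs - 1e-12:
            count += 1
    return count / total


def spearman_matrix(abund: pd.DataFrame, table: pd.DataFrame, min_pairs: int = 5,
                    p_method: str = "t") -> list[CorrelationCell]:
    """Spearman correlation of every abundance column against every parameter.

    Ranks are averaged over ties; the two-sided p-value uses the
    t-distribution approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2
    degrees of freedom (``p_method="t"``), or exact permutation enumeration
    for n <= 9 (``p_method="exact"``). Pairs are formed on the samples
    shared by both tables, pairwise-complete per cell; cells with fewer
    than ``min_pairs`` observations are omitted.
    """
    if p_method not in ("t", "exact"):
        raise ValueError(f"unknown p_method {p_method!r}")
    shared = [s for s in abund.index if s in set(table.index)]
    a = abund.loc[shared]
    t = table.loc[shared]
    cells = []
    for tax in a.columns:
        for par in t.columns:
            x = pd.to_numeric(a[tax], errors="coerce").to_numpy(dtype=float)
            y = pd.to_numeric(t[par], errors="coerce").to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            n = int(mask.sum())
            if n < min_pairs:
                continue
            xm, ym = x[mask], y[mask]
            if np.ptp(xm) == 0 or np.ptp(ym) == 0:
                continue
            xr = sps.rankdata(xm)
            yr = sps.rankdata(ym)
            rho = float(np.corrcoef(xr, yr)[0, 1])
            if p_method == "exact":
                p = _spearman_exact_p(xr, yr, rho)
            elif abs(rho) >= 1.0:
                p = 0.0
            else:
                tstat = rho * math.sqrt((n - 2) / (1 - rho ** 2))
                p = 2 * sps.t.sf(abs(tstat), n - 2)
            cells.append(CorrelationCell(taxon_or_trf=str(tax), parameter=str(par),
                                         rho=rho, p_value=float(p), n=n))
    return cells


def correlation_frame(cells: list[CorrelationCell]) -> pd.DataFrame:
    """Long-format correlation table (taxon, parameter, rho, p, flag, n)."""
    return pd.DataFrame(
        [{"taxon_or_trf": c.taxon_or_trf, "parameter": c.parameter, "rho": c.rho,
          "p_value": c.p_value, "flag": c.flag, "n": c.n} for c in cells],
        columns=["taxon_or_trf", "parameter", "rho", "p_value", "flag", "n"])


def vector_fit_frame(fits: list[VectorFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variable": f.variable, "dir_x": f.direction[0], "dir_y": f.direction[1],
          "r_squared": f.r_squared, "p_perm": f.p_perm, "n": f.n_used} for f in fits],
        columns=["variable", "dir_x", "dir_y", "r_squared", "p_perm", "n"])
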