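"""Relating dissimilarity matrices to attribute-difference matrices.

Pairwise dissimilarities are not independent observations, so ordinary
regression p-values are invalid. The tools here use the standard
distance-matrix machinery: Mantel and partial Mantel permutation tests
(correlating unfolded upper triangles, with the site label as the
exchangeable unit) and multiple regression on distance matrices (MRM: OLS on
unfolded triangles with permutation-based coefficient significance).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .community import DistanceMatrix, ValidationError


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool = False
    covariate: str | None = None
    n_sites: int = 0


@dataclass(frozen=True)
class MrmResult:
    intercept: float
    slopes: tuple[float, ...]
    predictor_names: tuple[str, ...]
    r_squared: float
    p_intercept: float
    p_slopes: tuple[float, ...]
    n_perm: int
    n_sites: int = 0

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.slopes])


def attribute_distance(
    values, labels=None, transform: str = "none"
) -> DistanceMatrix:
    """One-dimensional Euclidean distance matrix |t(x_i) - t(x_j)| of an
    island attribute, optionally log10-transformed first."""
    import pandas as pd

    if isinstance(values, pd.Series) and labels is None:
        labels = values.index
    x = np.asarray(values, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(x))]
    if transform == "log10":
        if (x <= 0).any():
            raise ValidationError("log10 transform requires positive values")
        x = np.log10(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(tuple(map(str, labels)), d)


EARTH_RADIUS_KM = 6371.0088


def geo_distance(lat, lon, labels=None) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between site coordinates
    given in decimal degrees."""
    import pandas as pd

    if isinstance(lat, pd.Series) and labels is None:
        labels = lat.index
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValidationError("coordinates outside valid ranges")
    if labels is None:
        labels = [str(i) for i in range(len(lat))]
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    return DistanceMatrix(tuple(map(str, labels)), d)


def _aligned_condensed(*mats: DistanceMatrix) -> list[np.ndarray]:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValidationError("distance matrices have mismatched labels")
    return [m.condensed() for m in mats]


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise ValidationError("Mantel r undefined: constant distance triangle")
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Mantel permutation test: Pearson r between the unfolded upper
    triangles of two distance matrices, with a two-sided p from
    simultaneous row/column permutations of ``dx``."""
    x, y = _aligned_condensed(dx, dy)
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    n = dx.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(squareform(dx.permuted(perm), checks=False), y)
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=(count + 1) / (n_perm + 1), n_perm=n_perm,
                        n_sites=n)


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    r_xy = _pearson(x, y)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    denom = (1 - r_xz ** 2) * (1 - r_yz ** 2)
    if denom <= 0:
        raise ValidationError(
            "partial Mantel r undefined: covariate collinear with an input"
        )
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def partial_mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    dz: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    covariate_name: str | None = None,
) -> MantelResult:
    """Partial Mantel test of dx vs dy controlling for dz (first-order
    partial correlation of triangles); the null permutes dx's labels and
    recomputes the partial r. Two-sided p."""
    x, y, z = _aligned_condensed(dx, dy, dz)
    r_obs = _partial_r(x, y, z)
    rng = np.random.default_rng(seed)
    n = dx.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = squareform(dx.permuted(perm), checks=False)
        try:
            r_p = _partial_r(xp, y, z)
        except ValidationError:
            continue
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(r=float(r_obs), p=(count + 1) / (n_perm + 1),
                        n_perm=n_perm, partial=True, covariate=covariate_name,
                        n_sites=n)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValidationError("collinear predictor matrices in MRM")
    resid = y - X @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else np.nan
    return coef, float(r2)


def mrm(
    response: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    predictor_names: list[str] | None = None,
) -> MrmResult:
    """Multiple regression on distance matrices: OLS of the response
    triangle on predictor triangles. Coefficient p-values come from
    permuting the response matrix's labels (two-sided on |coefficient|)."""
    y = _aligned_condensed(response, *predictors)[0]
    Xcols = [p.condensed() for p in predictors]
    X = np.column_stack([np.ones_like(y)] + Xcols)
    coef, r2 = _ols(X, y)
    rng = np.random.default_rng(seed)
    n = response.n
    counts = np.zeros(len(coef), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = squareform(response.permuted(perm), checks=False)
        coef_p, _ = _ols(X, yp)
        counts += np.abs(coef_p) >= np.abs(coef) - 1e-12
    pvals = (counts + 1) / (n_perm + 1)
    names = tuple(predictor_names or [f"x{i+1}" for i in range(len(predictors))])
    return MrmResult(
        intercept=float(coef[0]), slopes=tuple(float(c) for c in coef[1:]),
        predictor_names=names, r_squared=r2, p_intercept=float(pvals[0]),
        p_slopes=tuple(float(v) for v in pvals[1:]), n_perm=n_perm, n_sites=n,
    )
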