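"""Parameterizing the canonical morphospace region with (density, SOX2
stability) simulations.

A grid of simulations over cell density d and SOX2 stability C_s is decoded
to phenotypes and projected into morphospace with a parametric embedding.
Polynomials fitted through each iso-density and iso-stability contour define
two interpretable axes; the SOX2 stability of an experimental centroid is
interpolated from its position between stability contours, and the closed
loop re-simulates patterning from (measured density, inferred C_s) to check
that the mechanistic model lands back on the centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .embedding import EmbeddingNet, project
from .fates import simulated_phenotype
from .pde import ModelParams, simulate
from .records import PhenotypeVector


@dataclass
class ParameterGrid:
    """Complete (density x C_s) grid of simulated phenotypes + projections."""

    densities: np.ndarray
    stabilities: np.ndarray
    phenotypes: dict[tuple[float, float], PhenotypeVector]
    projections: dict[tuple[float, float], np.ndarray]

    def projection_matrix(self) -> np.ndarray:
        """(n_d, n_cs, 2) array of projected coordinates."""
        out = np.empty((self.densities.size, self.stabilities.size, 2))
        for i, d in enumerate(self.densities):
            for j, cs in enumerate(self.stabilities):
                out[i, j] = self.projections[(float(d), float(cs))]
        return out


def simulate_grid(
    densities,
    stabilities,
    params: ModelParams,
    net: EmbeddingNet,
) -> ParameterGrid:
    """Simulate + decode + project every (d, C_s) cell of the grid."""
    densities = np.asarray(densities, float)
    stabilities = np.asarray(stabilities, float)
    phen: dict[tuple[float, float], PhenotypeVector] = {}
    proj: dict[tuple[float, float], np.ndarray] = {}
    for d in densities:
        for cs in stabilities:
            try:
                p = replace(params, d=float(d), C_s=float(cs))
                res = simulate(p)
                fp = simulated_phenotype(res, p)
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(f"simulation failed at (d={d}, C_s={cs}): {exc}") from exc
            phen[(float(d), float(cs))] = fp.vector
            proj[(float(d), float(cs))] = np.atleast_2d(project(net, fp.vector.values))[0]
    return ParameterGrid(densities=densities, stabilities=stabilities,
                         phenotypes=phen, projections=proj)


@dataclass
class _Contour:
    """Polynomial curve through one contour's projected grid points."""

    value: float  # the d or C_s this contour holds fixed
    points: np.ndarray  # (n, 2) projected coordinates
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    t: np.ndarray  # chord-length parameters of the grid points

    def evaluate(self, ts: np.ndarray) -> np.ndarray:
        return np.column_stack([np.polyval(self.coeffs_x, ts), np.polyval(self.coeffs_y, ts)])

    def dense(self, n: int = 400) -> np.ndarray:
        ts = np.union1d(np.linspace(self.t[0], self.t[-1], n), self.t)
        return self.evaluate(ts)

    def distance(self, point: np.ndarray) -> float:
        return float(np.min(np.linalg.norm(self.dense() - point, axis=1)))

    def residual(self) -> float:
        return float(np.mean(np.linalg.norm(self.evaluate(self.t) - self.points, axis=1)))


def _fit_contour(points: np.ndarray, value: float, degree: int) -> _Contour:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise ValueError("contour points are coincident; the projections are degenerate "
                         "— retrain the embedding")
    t = t / total
    deg = min(degree, points.shape[0] - 1)
    cx = np.polyfit(t, points[:, 0], deg)
    cy = np.polyfit(t, points[:, 1], deg)
    return _Contour(value=value, points=points, coeffs_x=cx, coeffs_y=cy, t=t)


@dataclass
class AxesModel:
    """Fitted density and stability axes plus grid-node interpolators."""

    grid: ParameterGrid
    density_contours: list[_Contour]  # fixed d, varying C_s
    stability_contours: list[_Contour]  # fixed C_s, varying d
    degree: int
    _interp_cs: object = field(default=None, repr=False)
    _interp_d: object = field(default=None, repr=False)
    _nearest_cs: object = field(default=None, repr=False)
    _nearest_d: object = field(default=None, repr=False)

    def mean_contour_residual(self) -> float:
        cs = self.density_contours + self.stability_contours
        return float(np.mean([c.residual() for c in cs]))

    def interpolate_params(self, point: np.ndarray) -> tuple[float, float]:
        """(d, C_s) at a morphospace point via the grid-node interpolator."""
        p = np.asarray(point, float).ravel()
        d = self._interp_d(p[0], p[1])
        cs = self._interp_cs(p[0], p[1])
        if np.isnan(d) or np.isnan(cs):
            warnings.warn("point outside the simulated grid hull; nearest-node "
                          "extrapolation used", stacklevel=2)
            d = self._nearest_d(p[0], p[1])
            cs = self._nearest_cs(p[0], p[1])
        return float(d), float(cs)


def fit_axes(grid: ParameterGrid, degree: int = 2) -> AxesModel:
    """Fit polynomial axes through the projected grid contours."""
    mat = grid.projection_matrix()
    if not np.all(np.isfinite(mat)):
        raise ValueError("grid projections contain non-finite values")
    density_contours = [
        _fit_contour(mat[i, :, :], float(d), degree) for i, d in enumerate(grid.densities)
    ]
    stability_contours = [
        _fit_contour(mat[:, j, :], float(cs), degree) for j, cs in enumerate(grid.stabilities)
    ]
    pts = mat.reshape(-1, 2)
    dd = np.repeat(grid.densities, grid.stabilities.size)
    ss = np.tile(grid.stabilities, grid.densities.size)
    model = AxesModel(
        grid=grid,
        density_contours=density_contours,
        stability_contours=stability_contours,
        degree=degree,
    )
    model._interp_d = LinearNDInterpolator(pts, dd)
    model._interp_cs = LinearNDInterpolator(pts, ss)
    model._nearest_d = NearestNDInterpolator(pts, dd)
    model._nearest_cs = NearestNDInterpolator(pts, ss)
    return model


def infer_sox2_stability(axes: AxesModel, point: np.ndarray) -> float:
    """Interpolate C_s at a morphospace point.

    Inverse-distance weighting between the two nearest fitted stability
    contours; a point at a grid node recovers that node's C_s.  Points
    outside the grid hull trigger an extrapolation warning.
    """
    p = np.asarray(point, float).ravel()
    if axes._interp_cs is not None and np.isnan(float(axes._interp_cs(p[0], p[1]))):
        warnings.warn("point outside the simulated grid hull; C_s extrapolated",
                      stacklevel=2)
    dists = np.array([c.distance(p) for c in axes.stability_contours])
    order = np.argsort(dists)
    i, j = order[0], order[1] if order.size > 1 else order[0]
    d_i, d_j = dists[i], dists[j]
    if d_i < 1e-9:
        return float(axes.stability_contours[i].value)
    w_i, w_j = 1.0 / d_i, 1.0 / d_j if d_j > 0 else 0.0
    return float(
        (w_i * axes.stability_contours[i].value + w_j * axes.stability_contours[j].value)
        / (w_i + w_j)
    )


def contour_angle_stats(axes: AxesModel, n_samples: int = 50) -> float:
    """Mean absolute angle (degrees) between local density- and
    stability-contour tangents, sampled across the grid region."""
    angles = []
    for dc in axes.density_contours:
        for sc in axes.stability_contours:
            # tangent of each contour near their closest approach
            td = _tangent_at_nearest(dc, sc)
            ts = _tangent_at_nearest(sc, dc)
            cosang = abs(np.dot(td, ts))
            angles.append(np.degrees(np.arccos(np.clip(cosang, 0, 1))))
    return float(np.mean(angles))


def _tangent_at_nearest(c: "_Contour", other: "_Contour") -> np.ndarray:
    ts = np.linspace(c.t[0], c.t[-1], 100)
    pts = c.evaluate(ts)
    od = other.dense(100)
    d2 = ((pts[:, None, :] - od[None, :, :]) ** 2).sum(axis=2)
    tstar = ts[np.argmin(d2.min(axis=1))]
    dx = np.polyval(np.polyder(c.coeffs_x), tstar)
    dy = np.polyval(np.polyder(c.coeffs_y), tstar)
    v = np.array([dx, dy])
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def closed_loop_predict(
    axes: AxesModel,
    centroid: np.ndarray,
    measured_density: float,
    params: ModelParams,
    net: EmbeddingNet,
    experimental_profile: PhenotypeVector | None = None,
) -> dict:
    """Mechanistic round trip: infer C_s, re-simulate, re-project, compare.

    Returns the recovered phenotype, its morphospace coordinate, the
    Euclidean distance to the input centroid, the inferred C_s, and
    RMSE/cosine against an experimental profile when one is given.
    """
    if measured_density <= 0:
        raise ValueError("measured_density must be positive")
    d_lo, d_hi = axes.grid.densities.min(), axes.grid.densities.max()
    if not (d_lo <= measured_density <= d_hi):
        warnings.warn("measured density outside the simulated range; extrapolating",
                      stacklevel=2)
    cs = infer_sox2_stability(axes, centroid)
    p = replace(params, d=float(measured_density), C_s=float(cs))
    res = simulate(p)
    fp = simulated_phenotype(res, p)
    coord = np.atleast_2d(project(net, fp.vector.values))[0]
    out = {
        "phenotype": fp.vector,
        "coordinate": coord,
        "inferred_C_s": cs,
        "distance_to_centroid": float(np.linalg.norm(coord - np.asarray(centroid, float))),
    }
    if experimental_profile is not None:
        diff = fp.vector.values - experimental_profile.values
        out["rmse"] = float(np.sqrt(np.mean(diff**2)))
        denom = np.linalg.norm(fp.vector.values) * np.linalg.norm(experimental_profile.values)
        out["cosine"] = float(fp.vector.values @ experimental_profile.values / denom)
    return out
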