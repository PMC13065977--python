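"""Density-dependent BMP/Wnt/Nodal reaction-diffusion model on a 2-D disc.

Model summary (explicit forward-Euler, 5-point Laplacian, disc mask):

* BMP ``b``: held at 1 everywhere until the localization time ``t_loc``;
  afterwards BMP signalling is restricted to the outer ring ``|r| > r_loc``
  where it stays at 1 (Dirichlet), while the interior is reset to 0 and
  evolves by pure diffusion fed from that ring.  The localization radius
  grows with cell density, ``r_loc = r_rad (1 - exp(-a d))``: denser
  colonies confine active BMP to a thinner peripheral ring.

* Wnt ``u``: du/dt = D_u Δu + h(d) (f(u) + k_b b + c_u) - k_u u, with
  autocatalysis f(u) = s_u u² / (1 + K_u u⁴) and the density factor
  h(d) = 1 - c_m (d/c_d - 1), which linearly reduces every Wnt source as
  density rises.  The BMP ring ignites an autocatalytic Wnt front that
  travels inward — faster and deeper at low density.

* Nodal ``v``: dv/dt = D_v Δv + g(u, v) - k_v v + c_v, relay production
  g(u, v) = s_v v u / (1 + K_v v²) (not autocatalytic); the constant basal
  source c_v nucleates the relay where Wnt is active.

Zero-flux (mirror) boundaries confine Wnt and Nodal to the colony.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .records import N_BINS


@dataclass
class ModelParams:
    """All coefficients of the morphogen and fate equations plus numerics.

    Times are in hours, lengths in µm, concentrations in arbitrary units,
    density ``d`` in cells per colony.  Defaults were calibrated so the
    canonical pattern (edge GATA3, interior BRA ring, central SOX2) emerges
    at the reference density ``d = c_d`` and the density orderings of Wnt,
    Nodal and BRA hold across 750-1150 cells.
    """

    # diffusion (µm²/h)
    D_b: float = 30.0
    D_u: float = 60.0
    D_v: float = 80.0
    # BMP localization
    t_loc: float = 4.0
    r_rad: float = 250.0
    a: float = 1.4e-3  # density scaling inside r_loc
    d: float = 950.0  # cells per colony
    # Wnt density factor h(d)
    c_m: float = 1.0
    c_d: float = 950.0
    # Wnt reaction
    s_u: float = 1.2
    K_u: float = 1.0
    k_b: float = 0.08
    c_u: float = 0.002
    k_u: float = 0.35
    # Nodal reaction
    s_v: float = 6.0
    K_v: float = 1.0
    c_v: float = 0.1
    k_v: float = 0.8
    # fate decoding
    k_1: float = 0.08  # GATA3 edge steepness (1/µm)
    k_2: float = 12.0  # BRA Wnt-gate steepness
    Wnt_thresh: float = 1.2
    C_s: float = 1.0  # SOX2 stability
    c_1: float = 1.0  # initial SOX2 level
    c_2: float = 0.8
    c_3: float = 0.8
    # initial conditions (uniform over the disc)
    u0: float = 0.0
    v0: float = 0.0
    # numerics
    T: float = 48.0
    grid_n: int = 101
    dt: float | None = None  # None -> 0.2 dx²/max(D)
    dt_snapshot: float = 0.5
    h_floor: float = 0.0
    bmp_interior_reset: bool = True

    def validate(self) -> None:
        for name in ("r_rad", "k_u", "k_v", "c_d", "a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.D_b, self.D_u, self.D_v) < 0 or max(self.D_b, self.D_u, self.D_v) <= 0:
            raise ValueError("diffusivities must be >= 0 with at least one positive")
        if self.d <= 0:
            raise ValueError("density d must be positive")
        if not (0 < self.t_loc < self.T):
            raise ValueError("t_loc must lie in (0, T)")
        if self.K_u < 0 or self.K_v < 0:
            raise ValueError("saturation constants must be >= 0")
        if self.dt is not None and self.dt > self.stability_bound():
            raise ValueError(
                f"dt = {self.dt} exceeds the diffusion stability bound "
                f"dx²/(4 max(D)) = {self.stability_bound():.4g}"
            )

    @property
    def dx(self) -> float:
        return 2 * self.r_rad / (self.grid_n - 1)

    def stability_bound(self) -> float:
        return self.dx**2 / (4.0 * max(self.D_b, self.D_u, self.D_v))

    def resolved_dt(self) -> float:
        return self.dt if self.dt is not None else 0.8 * self.stability_bound()

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ModelParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def r_loc(params: ModelParams) -> float:
    """Density-dependent BMP localization radius, in (0, r_rad)."""
    return params.r_rad * (1.0 - np.exp(-params.a * params.d))


def h(params: ModelParams) -> float:
    """Density factor on Wnt sources: 1 at the reference density, clamped
    below at ``h_floor``."""
    val = 1.0 - params.c_m * (params.d / params.c_d - 1.0)
    return max(val, params.h_floor)


def f(u: np.ndarray, params: ModelParams) -> np.ndarray:
    """Autocatalytic Wnt production with quartic saturation."""
    u2 = u * u
    return params.s_u * u2 / (1.0 + params.K_u * u2 * u2)


def g(u: np.ndarray, v: np.ndarray, params: ModelParams) -> np.ndarray:
    """Wnt-driven Nodal relay production with saturation (not autocatalytic)."""
    return params.s_v * v * u / (1.0 + params.K_v * v * v)


@dataclass
class SimulationResult:
    """Sampled fields and radial kymographs of one simulation run."""

    times: np.ndarray  # (n_snap,)
    b: np.ndarray  # (n_snap, n, n)
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray  # disc mask (n, n)
    r: np.ndarray  # radius of each grid pixel (µm)
    params: ModelParams
    kymographs: dict[str, np.ndarray] = field(default_factory=dict)

    def field(self, species: str) -> np.ndarray:
        try:
            return {"bmp": self.b, "wnt": self.u, "nodal": self.v}[species]
        except KeyError:
            raise KeyError(f"unknown species {species!r}; use bmp/wnt/nodal") from None


def _masked_laplacian(field: np.ndarray, mask: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with mirror (zero-flux) conditions at the mask edge."""
    up = np.where(np.roll(mask, 1, 0), np.roll(field, 1, 0), field)
    dn = np.where(np.roll(mask, -1, 0), np.roll(field, -1, 0), field)
    lf = np.where(np.roll(mask, 1, 1), np.roll(field, 1, 1), field)
    rt = np.where(np.roll(mask, -1, 1), np.roll(field, -1, 1), field)
    return (up + dn + lf + rt - 4.0 * field) / dx**2


def radial_profile(field: np.ndarray, mask: np.ndarray, r: np.ndarray, r_rad: float,
                   n_bins: int = N_BINS) -> np.ndarray:
    """Mean field value over 50 annuli, edge -> center, on the disc mask."""
    edge_dist = r_rad - r[mask]
    bins = np.clip((edge_dist / (r_rad / n_bins)).astype(int), 0, n_bins - 1)
    sums = np.bincount(bins, weights=field[mask], minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    good = counts > 0
    if not good.all():
        idx = np.arange(n_bins)
        means[~good] = np.interp(idx[~good], idx[good], means[good])
    return means


def simulate(params: ModelParams) -> SimulationResult:
    """Integrate the BMP/Wnt/Nodal system and record snapshots + kymographs."""
    params.validate()
    n = params.grid_n
    dx = params.dx
    dt = params.resolved_dt()
    if dt > params.stability_bound() * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt} exceeds the diffusion stability bound dx²/(4 max D) = "
            f"{params.stability_bound():.4g}"
        )
    ax = np.linspace(-params.r_rad, params.r_rad, n)
    X, Y = np.meshgrid(ax, ax)
    r = np.hypot(X, Y)
    mask = r <= params.r_rad
    rl = r_loc(params)
    interior = mask & (r <= rl)
    ring = mask & (r > rl)
    hd = h(params)

    b = np.where(mask, 1.0, 0.0)
    u = np.where(mask, float(params.u0), 0.0)
    v = np.where(mask, float(params.v0), 0.0)

    n_steps = int(np.ceil(params.T / dt))
    snap_every = max(1, int(round(params.dt_snapshot / dt)))
    times, bs, us, vs = [], [], [], []

    def record(t: float) -> None:
        times.append(t)
        bs.append(b.copy())
        us.append(u.copy())
        vs.append(v.copy())

    record(0.0)
    localized = False
    for step in range(1, n_steps + 1):
        t = step * dt
        if not localized and t >= params.t_loc:
            localized = True
            if params.bmp_interior_reset:
                b[interior] = 0.0
        if localized:
            lap_b = _masked_laplacian(b, mask, dx)
            b_new = b + dt * params.D_b * lap_b
            b_new[ring] = 1.0  # BMP held active on the peripheral ring
            b_new[~mask] = 0.0
            b = b_new
        lap_u = _masked_laplacian(u, mask, dx)
        lap_v = _masked_laplacian(v, mask, dx)
        du = params.D_u * lap_u + hd * (f(u, params) + params.k_b * b + params.c_u) - params.k_u * u
        dv = params.D_v * lap_v + g(u, v, params) - params.k_v * v + params.c_v
        u = u + dt * du
        v = v + dt * dv
        u[~mask] = 0.0
        v[~mask] = 0.0
        if step % 50 == 0 or step == n_steps:
            for name, fld in (("b", b), ("u", u), ("v", v)):
                vals = fld[mask]
                if not np.all(np.isfinite(vals)):
                    raise FloatingPointError(f"{name} became non-finite at t = {t:.3f}")
                if vals.min() < -1e-9:
                    raise FloatingPointError(f"{name} became negative at t = {t:.3f}")
        if step % snap_every == 0 or step == n_steps:
            record(t)

    result = SimulationResult(
        times=np.array(times),
        b=np.stack(bs),
        u=np.stack(us),
        v=np.stack(vs),
        mask=mask,
        r=r,
        params=replace(params),
    )
    for sp in ("bmp", "wnt", "nodal"):
        result.kymographs[sp] = signaling_kymograph(result, sp)
    return result


def signaling_kymograph(result: SimulationResult, species: str) -> np.ndarray:
    """Time x 50-bin radial kymograph of one species (edge -> center)."""
    stack = result.field(species)
    return np.stack(
        [radial_profile(frame, result.mask, result.r, result.params.r_rad) for frame in stack]
    )


def wavefront_arrival(result: SimulationResult, bin_index: int, threshold: float | None = None
                      ) -> float:
    """First snapshot time at which the Wnt kymograph exceeds ``threshold``
    in the given radial bin; inf if it never does."""
    thr = threshold if threshold is not None else result.params.Wnt_thresh
    kymo = result.kymographs["wnt"]
    above = kymo[:, bin_index] > thr
    if not above.any():
        return float("inf")
    return float(result.times[int(np.argmax(above))])


def total_auc(result: SimulationResult, species: str) -> float:
    """Final-time area under the radial profile (sum over 50 bins)."""
    return float(result.kymographs[species][-1].sum())
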