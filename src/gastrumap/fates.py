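"""Decode morphogen histories into GATA3/BRA/SOX2 fate maps and a 150-d
simulated phenotype vector.

* GATA3 integrates BMP exposure over time, attenuated toward the colony
  interior by a logistic factor centered at the BMP localization radius
  (TGF-β receptors are preferentially available at the colony edge).
* BRA integrates the rate of change of Nodal, gated by a logistic switch
  that opens only where Wnt exceeds a threshold — mesoderm needs both a Wnt
  level and a rising Nodal signal.
* SOX2 starts from a basal level and is suppressed linearly by GATA3 and
  BRA, scaled by the stability constant C_s; it is clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pde import ModelParams, SimulationResult, r_loc, radial_profile
from .records import N_BINS, PhenotypeVector


@dataclass
class FatePhenotype:
    """Decoded fate maps plus the binned 150-d simulated phenotype."""

    gata3: np.ndarray
    bra: np.ndarray
    sox2: np.ndarray
    vector: PhenotypeVector
    normalization: dict[str, float]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def decode_gata3(result: SimulationResult, params: ModelParams | None = None) -> np.ndarray:
    """GATA3 map: time-integral of BMP / (1 + exp(-k_1 (r - r_loc)))."""
    p = params or result.params
    if result.times.size < 1:
        raise ValueError("no snapshots recorded")
    integral = np.trapezoid(result.b, x=result.times, axis=0)
    denom = 1.0 + np.exp(-p.k_1 * (result.r - r_loc(p)))
    out = np.where(result.mask, integral / denom, 0.0)
    return out


def _dvdt(result: SimulationResult) -> np.ndarray:
    """∂v/∂t per snapshot: centered differences, one-sided at the ends."""
    return np.gradient(result.v, result.times, axis=0)


def decode_bra(result: SimulationResult, params: ModelParams | None = None) -> np.ndarray:
    """BRA map: ∫ σ(k_2 (u - Wnt_thresh)) ∂v/∂t dt."""
    p = params or result.params
    if result.times.size < 2:
        raise ValueError("need at least 2 snapshots to differentiate Nodal")
    gate = _sigmoid(p.k_2 * (result.u - p.Wnt_thresh))
    integrand = gate * _dvdt(result)
    out = np.trapezoid(integrand, x=result.times, axis=0)
    return np.where(result.mask, out, 0.0)


def decode_sox2(
    gata3_map: np.ndarray,
    bra_map: np.ndarray,
    params: ModelParams,
    normalized_inputs: bool = True,
    clamp: bool = True,
) -> np.ndarray:
    """SOX2 map: C_s (c_1 - c_2 GATA3 - c_3 BRA), clamped at 0.

    With ``normalized_inputs`` (default) the GATA3/BRA maps are first
    rescaled to [0, 1] by their own maxima so c_2 and c_3 are scale-free.
    """
    if gata3_map.shape != bra_map.shape:
        raise ValueError("GATA3 and BRA maps must share a shape")
    G, B = gata3_map, bra_map
    if normalized_inputs:
        G = _normalize(G)
        B = _normalize(B)
    out = params.C_s * (params.c_1 - params.c_2 * G - params.c_3 * B)
    if clamp:
        out = np.clip(out, 0.0, None)
    return out


def _normalize(m: np.ndarray) -> np.ndarray:
    mx = float(np.max(m))
    return m / mx if mx > 0 else m


def simulated_phenotype(
    result: SimulationResult, params: ModelParams | None = None
) -> FatePhenotype:
    """Decode all three fate maps and radially bin them into a 150-d vector.

    GATA3 and BRA are rescaled to [0, 1] by their own maxima before binning.
    SOX2 is instead divided by its fixed basal ceiling ``c_1`` (the level at
    C_s = 1 with no suppression): dividing SOX2 by its own maximum would
    cancel the stability constant C_s out of the profile, flattening the
    SOX2-stability axis that downstream parameter analysis depends on.
    The normalization factors are recorded.
    """
    p = params or result.params
    g_map = decode_gata3(result, p)
    b_map = decode_bra(result, p)
    s_map = decode_sox2(g_map, b_map, p)
    norms = {}
    profiles = []
    for name, m in (("gata3", g_map), ("bra", b_map), ("sox2", s_map)):
        if name == "sox2":
            mx = float(p.c_1) if p.c_1 > 0 else 1.0
        else:
            mx = float(np.max(m))
        norms[name] = mx
        mm = m / mx if mx > 0 else m
        profiles.append(radial_profile(mm, result.mask, result.r, p.r_rad, N_BINS))
    vec = PhenotypeVector(np.concatenate(profiles), provenance="simulated")
    return FatePhenotype(gata3=g_map, bra=b_map, sox2=s_map, vector=vec, normalization=norms)
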