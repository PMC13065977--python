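"""Radial phenotype vectorization, per-plate robust scaling, cytotoxicity flags.

A colony is reduced to a 150-d vector by averaging each marker's nuclear
intensity over 50 concentric annular bins (~5 µm wide for a 250 µm-radius
colony), ordered from the colony edge inward.  Vectors are normalized per
plate with robust (25th-75th percentile) scaling before embedding, and
treatments whose mean viable nucleus count falls below half the untreated
control are flagged cytotoxic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .records import MARKERS, N_BINS, ColonyRecord, PhenotypeVector


def _fill_empty_bins(means: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Fill empty annuli by linear interpolation between non-empty neighbours.

    Edge bins with no non-empty bin on one side are extrapolated flat.
    """
    filled = means.copy()
    good = counts > 0
    if good.all():
        return filled
    if not good.any():
        return np.zeros_like(means)
    idx = np.arange(means.size)
    filled[~good] = np.interp(idx[~good], idx[good], means[good])
    return filled


def radial_bin(colony: ColonyRecord, n_bins: int = N_BINS) -> PhenotypeVector:
    """Average marker intensities over ``n_bins`` concentric annuli.

    Annuli are half-open, measured from the colony edge inward: bin ``i``
    (1-indexed) collects nuclei whose distance-from-edge lies in
    ``[(i-1)w, i·w)`` with ``w = radius/n_bins``; a nucleus exactly at the
    center lands in the innermost bin.  Nuclei outside the nominal radius are
    clamped into the outermost bin with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    r = colony.radii()
    w = colony.radius_um / n_bins
    edge_dist = colony.radius_um - r
    if (edge_dist < 0).any():
        warnings.warn(
            f"{int((edge_dist < 0).sum())} nuclei outside radius {colony.radius_um} µm "
            "clamped to the outermost bin",
            stacklevel=2,
        )
    bins = np.clip(np.floor(edge_dist / w).astype(int), 0, n_bins - 1)

    out = np.empty(len(MARKERS) * n_bins)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    for mi, m in enumerate(MARKERS):
        if m not in colony.intensities:
            raise KeyError(f"colony {colony.colony_id!r} missing marker {m!r}")
        sums = np.bincount(bins, weights=colony.intensities[m], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[mi * n_bins : (mi + 1) * n_bins] = _fill_empty_bins(means, counts)
    return PhenotypeVector(out, provenance=colony.colony_id)


def bin_width_um(radius_um: float, n_bins: int = N_BINS) -> float:
    """Width of one annular bin (µm)."""
    return radius_um / n_bins


@dataclass
class PlateScaler:
    """Per-feature robust scaler fit within one plate.

    Transforms x -> (x - p25) / (p75 - p25); features with p75 == p25 are
    centered only (denominator 1).
    """

    p25: np.ndarray
    p75: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.p75 < self.p25):
            raise ValueError("p75 must be >= p25 featurewise")

    @property
    def scale(self) -> np.ndarray:
        iqr = self.p75 - self.p25
        return np.where(iqr > 0, iqr, 1.0)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, float) - self.p25) / self.scale

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, float) * self.scale + self.p25


def robust_scale(
    vectors: list[PhenotypeVector], plate_ids: list[str]
) -> tuple[list[PhenotypeVector], dict[str, PlateScaler]]:
    """Robust-scale phenotype vectors within each plate.

    Returns the scaled vectors (same order) and the per-plate scalers for
    reuse on held-out colonies.
    """
    if len(vectors) != len(plate_ids):
        raise ValueError("vectors and plate_ids must be aligned")
    plate_ids = list(plate_ids)
    scalers: dict[str, PlateScaler] = {}
    mat = np.stack([v.values for v in vectors])
    out = np.empty_like(mat)
    for plate in sorted(set(plate_ids)):
        rows = np.array([i for i, p in enumerate(plate_ids) if p == plate])
        if rows.size < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 colonies")
        sub = mat[rows]
        p25 = np.percentile(sub, 25, axis=0)
        p75 = np.percentile(sub, 75, axis=0)
        if np.any(p75 == p25):
            warnings.warn(
                f"plate {plate!r}: {int((p75 == p25).sum())} constant features centered only",
                stacklevel=2,
            )
        scaler = PlateScaler(p25=p25, p75=p75)
        scalers[plate] = scaler
        out[rows] = scaler.transform(sub)
    scaled = [
        PhenotypeVector(out[i], provenance=vectors[i].provenance) for i in range(len(vectors))
    ]
    return scaled, scalers


def flag_cytotoxic(
    treatment_counts: dict[str, float], control_count: float, threshold: float = 0.5
) -> dict[str, bool]:
    """Flag treatments whose mean nucleus count is below ``threshold`` x control.

    The boundary is strict: a treatment at exactly the threshold is not
    flagged.
    """
    if control_count <= 0:
        raise ValueError("control_count must be positive")
    return {t: (c / control_count) < threshold for t, c in treatment_counts.items()}
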