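"""Morphospace construction: t-SNE embedding, KDE + watershed clustering,
failure-mode labelling, and fixed-boundary region assignment.

The 2-D embedding of the scaled 150-d profiles is convolved with a Gaussian
kernel density estimate; watershed segmentation of the (negated) density,
seeded at its pruned local maxima, partitions the plane into contiguous
regions without pre-specifying a cluster count.  The watershed boundaries
are then frozen: any new projected point (simulated or structure-predicted)
is classified by the region containing it, giving consistent, data-driven
classification across experimental and in-silico phenotypes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from sklearn.manifold import TSNE

from .records import MARKERS, N_BINS, ColonyRecord, PhenotypeVector


def embed_tsne(
    vectors: np.ndarray, perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """Embed scaled phenotype vectors into 2-D with t-SNE (seeded)."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D matrix")
    if X.shape[0] < 3 * perplexity:
        raise ValueError(
            f"t-SNE needs at least 3*perplexity = {int(3 * perplexity)} rows, got {X.shape[0]}"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return ts.fit_transform(X)


def kde_watershed(
    coords: np.ndarray,
    bandwidth_factor: float = 1.0,
    grid_size: int = 512,
    pad_frac: float = 0.05,
    prominence_frac: float = 0.05,
    knn: int = 10,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Partition the embedding plane by KDE + watershed.

    An isotropic Gaussian KDE is evaluated on a ``grid_size``² grid over the
    padded bounding box.  The bandwidth is ``bandwidth_factor`` x the median
    distance to the ``knn``-th nearest neighbour — a robust local scale that,
    unlike a global Scott's rule, is not inflated by widely separated cluster
    groups.  Maxima shallower than ``prominence_frac`` x the peak density are
    suppressed (h-maxima transform) and the surviving maxima seed a watershed
    of the negated density.  Every grid pixel receives a region label.

    Returns (kde_grid, label_map, (grid_x, grid_y), point_labels).
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth must be positive")

    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - pad_frac * span
    hi = hi + pad_frac * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)

    from sklearn.neighbors import KernelDensity, NearestNeighbors

    k = min(knn, pts.shape[0] - 1)
    nn_dist, _ = NearestNeighbors(n_neighbors=k + 1).fit(pts).kneighbors(pts)
    h_bw = bandwidth_factor * float(np.median(nn_dist[:, -1]))
    if h_bw <= 0:
        h_bw = bandwidth_factor * float(span.mean()) / 20.0
    kde = KernelDensity(bandwidth=h_bw).fit(pts)
    mx, my = np.meshgrid(gx, gy)
    density = np.exp(
        kde.score_samples(np.column_stack([mx.ravel(), my.ravel()]))
    ).reshape(grid_size, grid_size)

    h = prominence_frac * density.max()
    peaks = morphology.h_maxima(density, h)
    markers = measure.label(peaks)
    # collapse plateau maxima to single seeds
    if markers.max() == 0:
        markers[np.unravel_index(np.argmax(density), density.shape)] = 1
    label_map = segmentation.watershed(-density, markers)
    point_labels = assign_points(label_map, gx, gy, pts)
    return density, label_map, (gx, gy), point_labels


def assign_points(
    label_map: np.ndarray, gx: np.ndarray, gy: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Label each point by the watershed region of its nearest grid pixel."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ix = np.clip(np.searchsorted(gx, pts[:, 0]), 1, gx.size - 1)
    ix = np.where(np.abs(gx[ix] - pts[:, 0]) < np.abs(gx[ix - 1] - pts[:, 0]), ix, ix - 1)
    iy = np.clip(np.searchsorted(gy, pts[:, 1]), 1, gy.size - 1)
    iy = np.where(np.abs(gy[iy] - pts[:, 1]) < np.abs(gy[iy - 1] - pts[:, 1]), iy, iy - 1)
    return label_map[iy, ix]


@dataclass
class MorphospaceModel:
    """Frozen morphospace: embedding, density, watershed partition, clusters."""

    coords: np.ndarray
    kde_grid: np.ndarray
    label_map: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    labels: np.ndarray  # per-colony region label
    colony_ids: list[str]
    composites: dict[int, PhenotypeVector] = field(default_factory=dict)
    raw_composites: dict[int, PhenotypeVector] = field(default_factory=dict)
    failure_set: set[int] = field(default_factory=set)
    rng_seed: int = 0

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(np.unique(self.labels).tolist())

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_id)[0]


def build_morphospace(
    vectors: list[PhenotypeVector],
    colony_ids: list[str] | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
    bandwidth_factor: float = 1.0,
    grid_size: int = 512,
    prominence_frac: float = 0.05,
    raw_vectors: list[PhenotypeVector] | None = None,
) -> MorphospaceModel:
    """Embed, density-estimate, watershed, and compute cluster composites.

    ``vectors`` are the (robust-scaled) profiles fed to t-SNE; passing the
    corresponding ``raw_vectors`` additionally stores unscaled composites,
    which the failure-mode rules rely on (marker loss is only meaningful on
    the raw intensity scale).
    """
    mat = np.stack([v.values for v in vectors])
    ids = colony_ids if colony_ids is not None else [v.provenance for v in vectors]
    coords = embed_tsne(mat, perplexity=perplexity, seed=seed)
    kde_grid, label_map, (gx, gy), labels = kde_watershed(
        coords,
        bandwidth_factor=bandwidth_factor,
        grid_size=grid_size,
        prominence_frac=prominence_frac,
    )
    model = MorphospaceModel(
        coords=coords,
        kde_grid=kde_grid,
        label_map=label_map,
        grid_x=gx,
        grid_y=gy,
        labels=labels,
        colony_ids=list(ids),
        rng_seed=seed,
    )
    for cid in model.cluster_ids:
        model.composites[cid] = composite(model, cid, vectors)
        if raw_vectors is not None:
            model.raw_composites[cid] = composite(model, cid, raw_vectors)
    return model


def composite(
    model: MorphospaceModel, cluster_id: int, vectors: list[PhenotypeVector]
) -> PhenotypeVector:
    """Featurewise mean phenotype over a cluster's member colonies."""
    members = model.members(cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} has no members")
    vals = np.mean([vectors[i].values for i in members], axis=0)
    return PhenotypeVector(vals, provenance=f"cluster{cluster_id}:composite")


def angular_asymmetry(
    colony: ColonyRecord, marker: str = "bra", n_sectors: int = 12, band_bins: int = 5
) -> float:
    """Circular asymmetry of a marker's ring: resultant length over sectors.

    The marker's peak radius is located from its radial profile; nuclei in an
    annular band around it are split into ``n_sectors`` angular sectors and
    the length of the resultant vector of sector-mean intensities is
    returned.  0 = perfectly radially symmetric; a one-sided crescent gives
    values well above 0.3.
    """
    from .phenotype import radial_bin

    prof = radial_bin(colony).marker_profile(marker)
    peak_bin = int(np.argmax(prof))
    w = colony.radius_um / N_BINS
    cx, cy = colony.centroid
    r = colony.radii()
    edge_dist = colony.radius_um - r
    lo = max(0, peak_bin - band_bins) * w
    hi = min(N_BINS, peak_bin + band_bins + 1) * w
    in_band = (edge_dist >= lo) & (edge_dist < hi)
    if in_band.sum() < n_sectors:
        return 0.0
    theta = np.arctan2(colony.y_um[in_band] - cy, colony.x_um[in_band] - cx)
    vals = colony.intensities[marker][in_band]
    sector = np.clip(((theta + np.pi) / (2 * np.pi) * n_sectors).astype(int), 0, n_sectors - 1)
    sums = np.bincount(sector, weights=vals, minlength=n_sectors)
    counts = np.bincount(sector, minlength=n_sectors).astype(float)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        return 0.0
    ang = (np.arange(n_sectors) + 0.5) / n_sectors * 2 * np.pi - np.pi
    resultant = np.abs(np.sum(means * np.exp(1j * ang))) / total
    return float(resultant)


@dataclass
class FailureCriteria:
    """Thresholds for calling a cluster a failure mode."""

    marker_peak_frac: float = 0.5  # fraction of screen-wide canonical peak
    asymmetry_threshold: float = 0.25
    required_markers: tuple[str, ...] = ("sox2", "bra")


def label_failure_modes(
    model: MorphospaceModel,
    colonies: list[ColonyRecord] | None = None,
    criteria: FailureCriteria | None = None,
) -> set[int]:
    """Mark clusters lacking a required marker and/or radial symmetry.

    A cluster is a failure mode iff its composite's peak SOX2 or BRA falls
    below ``marker_peak_frac`` of the screen-wide peak for that marker, or
    (when colonies are supplied) its members' mean angular asymmetry exceeds
    the configured threshold.  Raw (unscaled) composites are used when
    available — marker loss is defined on the raw intensity scale.  The
    result is stored on the model.
    """
    crit = criteria or FailureCriteria()
    composites = model.raw_composites or model.composites
    if not composites:
        raise ValueError("composites must be computed before labelling failure modes")
    ref = {
        m: max(c.marker_profile(m).max() for c in composites.values())
        for m in crit.required_markers
    }
    failure: set[int] = set()
    for cid, comp in composites.items():
        for m in crit.required_markers:
            if comp.marker_profile(m).max() < crit.marker_peak_frac * ref[m]:
                failure.add(cid)
        if colonies is not None and cid not in failure:
            members = model.members(cid)
            asym = np.mean([angular_asymmetry(colonies[i]) for i in members])
            if asym > crit.asymmetry_threshold:
                failure.add(cid)
    model.failure_set = failure
    return failure


def assign_region(model: MorphospaceModel, point: np.ndarray) -> int:
    """Region label of the grid pixel nearest ``point`` (frozen boundaries).

    Points outside the grid are snapped to the nearest border pixel with a
    warning.
    """
    p = np.asarray(point, dtype=float).ravel()
    if p.size != 2 or not np.all(np.isfinite(p)):
        raise ValueError("point must be a finite 2-D coordinate")
    if not (
        model.grid_x[0] <= p[0] <= model.grid_x[-1]
        and model.grid_y[0] <= p[1] <= model.grid_y[-1]
    ):
        warnings.warn("point outside morphospace grid; snapped to border", stacklevel=2)
        p = np.array(
            [np.clip(p[0], model.grid_x[0], model.grid_x[-1]),
             np.clip(p[1], model.grid_y[0], model.grid_y[-1])]
        )
    return int(assign_points(model.label_map, model.grid_x, model.grid_y, p[None, :])[0])


def call_teratogen(model: MorphospaceModel, point: np.ndarray) -> bool:
    """True iff the point falls inside a failure-mode region."""
    return assign_region(model, point) in model.failure_set


def save_morphospace(model: MorphospaceModel, path: str) -> None:
    """Serialize a MorphospaceModel to an .npz bundle with a JSON sidecar."""
    np.savez_compressed(
        path if path.endswith(".npz") else path + ".npz",
        coords=model.coords,
        kde_grid=model.kde_grid,
        label_map=model.label_map,
        grid_x=model.grid_x,
        grid_y=model.grid_y,
        labels=model.labels,
        composites=np.stack([model.composites[c].values for c in model.cluster_ids])
        if model.composites
        else np.zeros((0, len(MARKERS) * N_BINS)),
        composite_ids=np.array(model.cluster_ids),
    )
    meta = {
        "colony_ids": model.colony_ids,
        "failure_set": sorted(model.failure_set),
        "rng_seed": model.rng_seed,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(meta, fh)


def load_morphospace(path: str) -> MorphospaceModel:
    base = path[:-4] if path.endswith(".npz") else path
    data = np.load(base + ".npz")
    with open(base + ".json") as fh:
        meta = json.load(fh)
    model = MorphospaceModel(
        coords=data["coords"],
        kde_grid=data["kde_grid"],
        label_map=data["label_map"],
        grid_x=data["grid_x"],
        grid_y=data["grid_y"],
        labels=data["labels"],
        colony_ids=list(meta["colony_ids"]),
        failure_set=set(meta["failure_set"]),
        rng_seed=int(meta["rng_seed"]),
    )
    for cid, vals in zip(data["composite_ids"], data["composites"]):
        model.composites[int(cid)] = PhenotypeVector(vals, provenance=f"cluster{int(cid)}:composite")
    return model
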