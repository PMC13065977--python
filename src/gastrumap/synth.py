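"""Synthetic colony, screen, and compound-library generation.

The generator emulates the statistical structure of BMP4-treated
micropatterned gastruloid screens: radially ordered marker bands
(edge GATA3, interior BRA ring, central SOX2), the recurrent failure
modes (loss of SOX2, loss of BRA, loss of radial symmetry), cell-density
variation between ~750 and ~1150 nuclei per colony, replicate noise, and
per-plate batch effects.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .records import DEFAULT_RADIUS_UM, MARKERS, ColonyRecord, CompoundRecord, PhenotypeVector

PATTERN_CLASSES = ("canonical", "loss_sox2", "loss_bra", "asymmetric", "undifferentiated")

#: density span of the screen: ~10th to ~90th percentile of nuclei per colony
DENSITY_RANGE = (750, 1150)
REFERENCE_DENSITY = 950


@dataclass
class PatternSpec:
    """Recipe for one synthetic colony.

    ``domain_radii`` are fractional radii (of the colony radius) ordered
    edge -> center: inner edge of the GATA3 band, center of the BRA ring,
    and outer edge of the SOX2 domain.
    """

    pattern_class: str = "canonical"
    domain_radii: tuple[float, float, float] = (0.80, 0.55, 0.35)
    density: int = REFERENCE_DENSITY
    noise_sd: float = 5.0
    asymmetry_angle: float = 0.0
    asymmetry_offset: float = 0.25  # pattern-center displacement, fraction of R
    seed: int = 0
    amplitude: float = 100.0
    baseline: float = 2.0
    steepness: float = 12.0
    bra_halfwidth: float = 0.15

    def __post_init__(self) -> None:
        if self.pattern_class not in PATTERN_CLASSES:
            raise ValueError(
                f"unknown pattern_class {self.pattern_class!r}; allowed: {PATTERN_CLASSES}"
            )
        r = self.domain_radii
        if not (0 <= r[2] <= r[1] <= r[0] <= 1):
            raise ValueError("domain_radii must be fractions in [0,1] ordered edge->center")
        if self.density <= 0:
            raise ValueError("density must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _place_nuclei(n: int, radius: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Jittered-grid placement of exactly ``n`` points inside a disc.

    A square grid slightly denser than needed is laid over the disc, each
    point jittered by a fraction of the spacing, points outside the disc
    dropped, and the excess removed at random.  The result is quasi-uniform
    (Poisson-disc-like), so low density reads directly as fewer nuclei.
    """
    spacing = np.sqrt(np.pi * radius**2 / n)
    grow = 1.0
    while True:
        half = int(np.ceil(radius / spacing * grow)) + 2
        ax = np.arange(-half, half + 1) * spacing / grow
        gx, gy = np.meshgrid(ax, ax)
        gx = gx.ravel() + rng.uniform(-0.35, 0.35, gx.size) * spacing / grow
        gy = gy.ravel() + rng.uniform(-0.35, 0.35, gy.size) * spacing / grow
        inside = gx**2 + gy**2 <= radius**2
        if inside.sum() >= n:
            break
        grow *= 1.1
    gx, gy = gx[inside], gy[inside]
    keep = rng.choice(gx.size, size=n, replace=False)
    x, y = gx[keep], gy[keep]
    # recenter so the nucleus centroid (the colony's reference point) is the
    # disc center, then pull the few strays back inside the rim
    x = x - x.mean()
    y = y - y.mean()
    r = np.hypot(x, y)
    out = r > radius * 0.999
    if out.any():
        shrink = radius * 0.999 / r[out]
        x[out] *= shrink
        y[out] *= shrink
        x = x - x.mean()
        y = y - y.mean()
    return x, y


def band_profiles(
    rho: np.ndarray, theta: np.ndarray, spec: PatternSpec
) -> dict[str, np.ndarray]:
    """Noise-free marker intensities at fractional radius ``rho``, angle ``theta``.

    Bands use logistic edges with steepness ``spec.steepness`` so the ground
    truth is smooth and differentiable.
    """
    k = spec.steepness
    r_g, r_b, r_s = spec.domain_radii
    w = spec.bra_halfwidth
    cls = spec.pattern_class
    if cls == "asymmetric":
        # symmetry loss: the whole fate pattern is displaced off-center, so
        # every radially averaged profile smears
        e = spec.asymmetry_offset
        phi = spec.asymmetry_angle
        rho = np.hypot(rho * np.cos(theta) - e * np.cos(phi),
                       rho * np.sin(theta) - e * np.sin(phi))
    gata3 = _sigmoid(k * (rho - r_g))
    bra = _sigmoid(k * (rho - (r_b - w))) * _sigmoid(k * ((r_b + w) - rho))
    sox2 = _sigmoid(k * (r_s - rho))

    if cls == "loss_sox2":
        sox2 = np.zeros_like(rho)
    elif cls == "loss_bra":
        bra = np.zeros_like(rho)
    elif cls == "asymmetric":
        # and the surviving mesoderm forms a one-sided crescent
        bra = bra * _sigmoid(6.0 * (np.cos(theta - spec.asymmetry_angle) - 0.2))
    elif cls == "undifferentiated":
        # no-BMP4 control: colony stays epiblast-like (SOX2 everywhere)
        gata3 = np.zeros_like(rho)
        bra = np.zeros_like(rho)
        sox2 = np.ones_like(rho)

    amp, base = spec.amplitude, spec.baseline
    return {
        "gata3": base + amp * gata3,
        "bra": base + amp * bra,
        "sox2": base + amp * sox2,
    }


def gen_colony(
    spec: PatternSpec,
    colony_id: str = "synthetic",
    plate_id: str = "plate0",
    treatment: str = "",
    radius_um: float = DEFAULT_RADIUS_UM,
) -> ColonyRecord:
    """Generate one synthetic colony with exactly ``spec.density`` nuclei."""
    rng = np.random.default_rng(spec.seed)
    x, y = _place_nuclei(spec.density, radius_um, rng)
    rho = np.hypot(x, y) / radius_um
    theta = np.arctan2(y, x)
    clean = band_profiles(rho, theta, spec)
    intens = {
        m: np.clip(clean[m] + rng.normal(0.0, spec.noise_sd, x.size), 0.0, None)
        for m in MARKERS
    }
    return ColonyRecord(
        colony_id=colony_id,
        plate_id=plate_id,
        treatment=treatment,
        x_um=x,
        y_um=y,
        intensities=intens,
        radius_um=radius_um,
    )


@dataclass
class SyntheticScreen:
    """A multi-plate synthetic drug screen."""

    colonies: list[ColonyRecord]
    treatment_map: dict[str, PatternSpec]
    batch_offsets: dict[str, tuple[float, float]]  # plate -> (gain, offset)

    @property
    def plate_ids(self) -> list[str]:
        return sorted({c.plate_id for c in self.colonies})

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([c.to_frame() for c in self.colonies], ignore_index=True)


def gen_screen(
    n_treatments: int,
    reps: int = 10,
    seed: int = 0,
    n_plates: int | None = None,
    density_range: tuple[int, int] = DENSITY_RANGE,
    noise_sd: float = 5.0,
    pattern_cycle: tuple[str, ...] = ("canonical", "loss_sox2", "loss_bra", "asymmetric"),
    batch_gain_range: tuple[float, float] = (0.85, 1.15),
    batch_offset_range: tuple[float, float] = (0.0, 8.0),
    radii_jitter_sd: float = 0.005,
    amplitude_jitter_sd: float = 0.03,
) -> SyntheticScreen:
    """Generate a screen of ``n_treatments`` treatments x ``reps`` replicates.

    The first two treatments are always the BMP4-only control (canonical
    patterning at the reference density) and the no-BMP4 control
    (undifferentiated, SOX2 everywhere).  Remaining treatments cycle through
    ``pattern_cycle`` with densities drawn across the screen's density span.
    Replicates of one treatment vary biologically: band radii are jittered
    by ``radii_jitter_sd`` (fractional radius) and the staining amplitude by
    a log-normal factor, on top of per-nucleus noise.  Per-plate affine
    intensity batch effects are applied.
    """
    if n_treatments < 1:
        raise ValueError("n_treatments must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_plates = n_plates or max(2, n_treatments // 6)
    plates = [f"plate{p}" for p in range(n_plates)]
    batch = {
        p: (float(rng.uniform(*batch_gain_range)), float(rng.uniform(*batch_offset_range)))
        for p in plates
    }

    treatment_map: dict[str, PatternSpec] = {}
    cycle = itertools.cycle(pattern_cycle)
    for i in range(n_treatments):
        if i == 0:
            name, cls, dens = "BMP4_control", "canonical", REFERENCE_DENSITY
        elif i == 1 and n_treatments > 1:
            name, cls, dens = "no_BMP4", "undifferentiated", REFERENCE_DENSITY
        else:
            name, cls = f"drug_{i - 2:03d}", next(cycle)
            dens = int(rng.integers(density_range[0], density_range[1] + 1))
        treatment_map[name] = PatternSpec(
            pattern_class=cls,
            density=dens,
            noise_sd=noise_sd,
            asymmetry_angle=float(rng.uniform(0, 2 * np.pi)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    colonies: list[ColonyRecord] = []
    for t_idx, (name, spec) in enumerate(treatment_map.items()):
        for r in range(reps):
            plate = plates[(t_idx * reps + r) % n_plates]
            rr = np.sort(
                np.clip(np.asarray(spec.domain_radii)
                        + rng.normal(0.0, radii_jitter_sd, 3), 0.0, 1.0)
            )[::-1]
            rep_spec = replace(
                spec,
                seed=int(rng.integers(0, 2**31 - 1)),
                domain_radii=(float(rr[0]), float(rr[1]), float(rr[2])),
                amplitude=float(spec.amplitude * rng.lognormal(0.0, amplitude_jitter_sd)),
            )
            col = gen_colony(
                rep_spec,
                colony_id=f"{name}_rep{r}",
                plate_id=plate,
                treatment=name,
            )
            gain, off = batch[plate]
            col.intensities = {m: v * gain + off for m, v in col.intensities.items()}
            colonies.append(col)
    return SyntheticScreen(colonies=colonies, treatment_map=treatment_map, batch_offsets=batch)


# ---------------------------------------------------------------------------
# compound libraries

_SMILES_TOKENS = ("C", "CC", "N", "O", "C(=O)", "c1ccccc1", "Cl", "F", "S", "C(N)", "CO")


def _synthetic_smiles(rng: np.random.Generator) -> str:
    n = int(rng.integers(3, 9))
    return "".join(rng.choice(_SMILES_TOKENS) for _ in range(n))


def gen_compound_library(
    n_compounds: int,
    n_clusters: int,
    sep: float,
    seed: int = 0,
    reps: int = 10,
    pheno_noise: float = 0.05,
    n_failure_clusters: int = 2,
) -> tuple[list[CompoundRecord], dict[int, PhenotypeVector], set[int]]:
    """Generate a synthetic compound library with cluster structure.

    Molecular embeddings are drawn from cluster-specific 768-d Gaussians
    (unit within-cluster SD) whose centers sit ``sep`` SDs from the origin in
    near-orthogonal random directions; ``sep = 0`` collapses all clusters.
    Each cluster's phenotype template is the 50-bin radial profile of a
    distinct synthetic colony pattern; the last ``n_failure_clusters``
    clusters use failure-mode patterns.

    Returns (records, cluster_templates, failure_cluster_ids).
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_compounds < n_clusters:
        raise ValueError("n_compounds must be >= n_clusters")
    if sep < 0:
        raise ValueError("sep must be >= 0")
    from .phenotype import radial_bin  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_clusters, 768))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = sep * dirs

    failure_ids = set(range(n_clusters - n_failure_clusters, n_clusters)) if n_failure_clusters else set()
    templates: dict[int, PhenotypeVector] = {}
    for k in range(n_clusters):
        if k in failure_ids:
            cls = ("loss_sox2", "loss_bra", "asymmetric")[k % 3]
        else:
            cls = "canonical"
        shift = 0.06 * (k % 4)  # distinct band geometry per canonical cluster
        spec = PatternSpec(
            pattern_class=cls,
            domain_radii=(0.80 - shift, 0.55 - shift, 0.35 - shift / 2),
            density=850 + 40 * (k % 5),
            noise_sd=0.0,
            seed=1000 + k,
        )
        vec = radial_bin(gen_colony(spec)).values / spec.amplitude
        templates[k] = PhenotypeVector(vec, provenance=f"cluster{k}:template")

    records: list[CompoundRecord] = []
    labels = np.concatenate([np.arange(n_clusters), rng.integers(0, n_clusters, n_compounds - n_clusters)])
    for i in range(n_compounds):
        k = int(labels[i])
        emb = centers[k] + rng.normal(size=768)
        phen = [
            PhenotypeVector(
                templates[k].values + rng.normal(0.0, pheno_noise, templates[k].values.size),
                provenance=f"cmpd{i}:rep{r}",
            )
            for r in range(reps)
        ]
        records.append(
            CompoundRecord(
                compound_id=f"cmpd_{i:04d}",
                smiles=_synthetic_smiles(rng),
                embedding=emb,
                cluster_label=k,
                replicate_phenotypes=phen,
            )
        )
    return records, templates, failure_ids


# ---------------------------------------------------------------------------
# image rendering (for the nuclei-detection pipeline)

def render_colony(
    colony: ColonyRecord,
    pixel_size_um: float = 2.0,
    nucleus_radius_um: float = 4.0,
    pad_um: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Rasterize a colony into a (1 + n_markers, H, W) image stack.

    Channel 0 is a DAPI-like nuclear channel (uniform discs); the remaining
    channels carry each nucleus's marker intensity painted over its disc.
    Returns (stack, pixel_size_um).
    """
    cx, cy = colony.centroid
    half = colony.radius_um + pad_um
    n_px = int(np.ceil(2 * half / pixel_size_um))
    stack = np.zeros((1 + len(colony.intensities), n_px, n_px), dtype=float)
    markers = list(colony.intensities)
    rr = int(np.ceil(nucleus_radius_um / pixel_size_um))
    ax = np.arange(-rr, rr + 1)
    dx, dy = np.meshgrid(ax, ax)
    disc = (dx**2 + dy**2) * pixel_size_um**2 <= nucleus_radius_um**2
    for i in range(colony.n_nuclei):
        px = int(round((colony.x_um[i] - cx + half) / pixel_size_um))
        py = int(round((colony.y_um[i] - cy + half) / pixel_size_um))
        ys, xs = np.nonzero(disc)
        ys = ys + py - rr
        xs = xs + px - rr
        ok = (ys >= 0) & (ys < n_px) & (xs >= 0) & (xs < n_px)
        ys, xs = ys[ok], xs[ok]
        stack[0, ys, xs] = np.maximum(stack[0, ys, xs], 100.0)
        for c, m in enumerate(markers, start=1):
            stack[c, ys, xs] = np.maximum(stack[c, ys, xs], colony.intensities[m][i])
    return stack, pixel_size_um


def save_render_tiff(path: str, stack: np.ndarray) -> None:
    """Write a rendered colony stack as a multichannel 32-bit TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
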