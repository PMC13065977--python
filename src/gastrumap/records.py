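"""Core data containers shared across the pipeline.

A micropatterned colony is represented by nucleus positions (µm, relative to
the image frame) and per-nucleus immunofluorescence intensities for the three
germ-layer markers GATA3 (amniotic ectoderm), BRA/Brachyury (mesoderm) and
SOX2 (epiblast).  Every downstream stage speaks 150-dimensional radial
phenotype vectors: 3 markers x 50 concentric bins ordered edge -> center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical marker order used in every 150-d vector
MARKERS: tuple[str, str, str] = ("gata3", "bra", "sox2")

#: default colony radius in µm (500 µm diameter micropatterns)
DEFAULT_RADIUS_UM: float = 250.0

#: default number of concentric annular bins
N_BINS: int = 50


@dataclass
class NucleusRecord:
    """A single detected nucleus."""

    x: float
    y: float
    intensities: dict[str, float]
    colony_id: str = ""
    plate_id: str = ""
    treatment: str = ""


@dataclass
class ColonyRecord:
    """One colony: nucleus positions plus per-nucleus marker intensities.

    Positions are stored as flat arrays for speed; ``intensities`` maps each
    marker name to an array aligned with ``x_um``/``y_um``.
    """

    colony_id: str
    plate_id: str
    treatment: str
    x_um: np.ndarray
    y_um: np.ndarray
    intensities: dict[str, np.ndarray]
    radius_um: float = DEFAULT_RADIUS_UM

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.x_um.size < 1:
            raise ValueError("colony must contain at least one nucleus")
        for m, v in self.intensities.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != self.x_um.shape:
                raise ValueError(f"intensity array for {m!r} misaligned with positions")
            self.intensities[m] = arr

    @property
    def n_nuclei(self) -> int:
        return int(self.x_um.size)

    @property
    def centroid(self) -> tuple[float, float]:
        """Colony center: the mean of all nucleus positions."""
        return float(self.x_um.mean()), float(self.y_um.mean())

    def radii(self) -> np.ndarray:
        """Distance of every nucleus from the colony centroid (µm)."""
        cx, cy = self.centroid
        return np.hypot(self.x_um - cx, self.y_um - cy)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "colony_id": self.colony_id,
                "plate_id": self.plate_id,
                "treatment": self.treatment,
                "x_um": self.x_um,
                "y_um": self.y_um,
            }
        )
        for m in self.intensities:
            df[m] = self.intensities[m]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM) -> "ColonyRecord":
        markers = [c for c in df.columns if c in MARKERS] or [
            c for c in df.columns if c not in ("colony_id", "plate_id", "treatment", "x_um", "y_um")
        ]
        return cls(
            colony_id=str(df["colony_id"].iloc[0]),
            plate_id=str(df["plate_id"].iloc[0]),
            treatment=str(df["treatment"].iloc[0]),
            x_um=df["x_um"].to_numpy(float),
            y_um=df["y_um"].to_numpy(float),
            intensities={m: df[m].to_numpy(float) for m in markers},
            radius_um=radius_um,
        )

    @classmethod
    def from_nuclei(
        cls,
        nuclei: list[NucleusRecord],
        colony_id: str = "",
        plate_id: str = "",
        treatment: str = "",
        radius_um: float = DEFAULT_RADIUS_UM,
    ) -> "ColonyRecord":
        markers = sorted({m for n in nuclei for m in n.intensities})
        return cls(
            colony_id=colony_id,
            plate_id=plate_id,
            treatment=treatment,
            x_um=np.array([n.x for n in nuclei]),
            y_um=np.array([n.y for n in nuclei]),
            intensities={m: np.array([n.intensities.get(m, np.nan) for n in nuclei]) for m in markers},
            radius_um=radius_um,
        )


@dataclass
class PhenotypeVector:
    """150-d radial profile: [GATA3 bins 1..50, BRA 1..50, SOX2 1..50].

    Bin 1 is the outermost annulus (colony edge), bin 50 the innermost
    (center).  ``provenance`` records whether the vector came from a measured
    colony, a simulation, or a structure-based prediction.
    """

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != len(MARKERS) * N_BINS:
            raise ValueError(
                f"phenotype vector must have {len(MARKERS) * N_BINS} entries, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype vector contains non-finite values")

    def marker_profile(self, marker: str) -> np.ndarray:
        i = MARKERS.index(marker)
        return self.values[i * N_BINS : (i + 1) * N_BINS]

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class CompoundRecord:
    """A screened compound: structure, molecular embedding, and phenotypes."""

    compound_id: str
    smiles: str
    embedding: np.ndarray
    cluster_label: int | None = None
    replicate_phenotypes: list[PhenotypeVector] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float).ravel()
        if self.embedding.size != 768:
            raise ValueError(f"molecular embedding must be 768-d, got {self.embedding.size}")

    @property
    def centroid_phenotype(self) -> PhenotypeVector:
        if not self.replicate_phenotypes:
            raise ValueError("no replicate phenotypes recorded")
        vals = np.mean([p.values for p in self.replicate_phenotypes], axis=0)
        return PhenotypeVector(vals, provenance=f"{self.compound_id}:centroid")


def vectors_to_frame(
    vectors: list[PhenotypeVector],
    colony_ids: list[str] | None = None,
    plate_ids: list[str] | None = None,
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate phenotype vectors as colony_id/plate_id/treatment/f_000..f_149."""
    n = len(vectors)
    df = pd.DataFrame(
        {
            "colony_id": colony_ids if colony_ids is not None else [v.provenance for v in vectors],
            "plate_id": plate_ids if plate_ids is not None else [""] * n,
            "treatment": treatments if treatments is not None else [""] * n,
        }
    )
    mat = np.stack([v.values for v in vectors])
    for j in range(mat.shape[1]):
        df[f"f_{j:03d}"] = mat[:, j]
    return df
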