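"""Expression energy volumes, the region ontology and spatial statistics.

The atlas quantifies expression per 200-µm voxel as *expression energy*,
the product of ISH signal intensity and the density of expressing cells in
the voxel.  Regions form a two-level hierarchy (coarse neuroanatomical
regions subdivided into fine regions) that partitions the voxel lattice.

The spatial-enrichment score of a brain domain d against the whole brain b,

    ( v_d(E >= e_min) / v_d ) / ( v_b(E >= e_min) / v_b ),

compares the domain's fraction of voxels expressing above ``e_min``
(default 2) to the brain-wide fraction; values > 1 flag high spatial
expression in that domain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Label value for voxels outside every annotated region.
BACKGROUND = -1


@dataclass
class RegionOntology:
    """Two-level region hierarchy over a voxel lattice.

    ``labels`` assigns every voxel a fine-region id; ``tree`` maps each
    coarse-region id to the list of fine-region ids nested inside it.
    """

    tree: dict[int, list[int]]
    labels: np.ndarray  # int array, lattice shape, fine-region ids
    names: dict[int, str] = field(default_factory=dict)        # fine ids
    coarse_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fine_in_tree = [f for fs in self.tree.values() for f in fs]
        if len(fine_in_tree) != len(set(fine_in_tree)):
            raise ValueError("a fine region appears under two coarse regions")
        present = set(np.unique(self.labels)) - {BACKGROUND}
        if not present <= set(fine_in_tree):
            raise ValueError("labels contain fine-region ids absent from the tree")

    @property
    def lattice_shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def fine_ids(self) -> list[int]:
        return sorted(f for fs in self.tree.values() for f in fs)

    @property
    def coarse_ids(self) -> list[int]:
        return sorted(self.tree)

    def mask(self, region_id: int | str, level: str = "fine") -> np.ndarray:
        """Boolean voxel mask of a region (or of the whole brain)."""
        if region_id == "brain":
            return self.labels != BACKGROUND
        if level == "coarse":
            fine = self.tree[int(region_id)]
            return np.isin(self.labels, fine)
        return self.labels == int(region_id)

    def coarse_labels(self) -> np.ndarray:
        """Voxel array of coarse-region ids (BACKGROUND outside the brain)."""
        out = np.full(self.labels.shape, BACKGROUND, dtype=int)
        for c, fines in self.tree.items():
            out[np.isin(self.labels, fines)] = c
        return out


@dataclass
class ExpressionVolume:
    """Per-probe dense voxel grid of non-negative expression energies."""

    probe_id: str
    energy: np.ndarray

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        if not np.all(np.isfinite(self.energy)):
            raise ValueError(f"non-finite energies in volume {self.probe_id}")
        if np.any(self.energy < 0):
            raise ValueError(f"negative energies in volume {self.probe_id}")

    @property
    def lattice_shape(self) -> tuple[int, ...]:
        return self.energy.shape


def expression_energy(intensity: np.ndarray, density: np.ndarray,
                      probe_id: str = "") -> ExpressionVolume:
    """Expression energy = ISH intensity x expressing-cell density."""
    intensity = np.asarray(intensity, dtype=float)
    density = np.asarray(density, dtype=float)
    if intensity.shape != density.shape:
        raise ValueError("intensity and density shapes differ")
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    if np.any((density < 0) | (density > 1)):
        raise ValueError("density must lie in [0, 1]")
    return ExpressionVolume(probe_id, intensity * density)


def region_mean(volume: ExpressionVolume, ontology: RegionOntology,
                region_id: int | str, level: str = "fine") -> float:
    """Mean expression energy over one region's voxels."""
    m = ontology.mask(region_id, level)
    if not m.any():
        raise ValueError(f"region {region_id!r} is empty")
    return float(volume.energy[m].mean())


def region_mean_table(volumes: list[ExpressionVolume], ontology: RegionOntology,
                      level: str = "fine") -> "pd.DataFrame":
    """Probes x regions matrix of mean energies (rows indexed by probe_id)."""
    import pandas as pd

    labels = ontology.labels if level == "fine" else ontology.coarse_labels()
    ids = ontology.fine_ids if level == "fine" else ontology.coarse_ids
    flat = labels.ravel()
    rows = {}
    for v in volumes:
        e = v.energy.ravel()
        rows[v.probe_id] = [e[flat == rid].mean() for rid in ids]
    return pd.DataFrame.from_dict(rows, orient="index", columns=ids)


def spatial_enrichment(volume: ExpressionVolume, ontology: RegionOntology,
                       region_id: int | str, e_min: float = 2.0,
                       level: str = "fine") -> float:
    """Domain-vs-brain enrichment of the fraction of voxels with E >= e_min.

    Returns NaN (with a warning) when no brain voxel reaches ``e_min``.
    Background voxels are excluded from both domain and brain counts.
    """
    brain = ontology.mask("brain")
    dom = ontology.mask(region_id, level) & brain
    if not dom.any() or not brain.any():
        raise ValueError("empty region or empty brain")
    above = volume.energy >= e_min
    b_frac = above[brain].mean()
    if b_frac == 0:
        warnings.warn(
            f"no voxel reaches E >= {e_min}; enrichment undefined", stacklevel=2
        )
        return float("nan")
    return float(above[dom].mean() / b_frac)


def spatial_divergence(region_means) -> float:
    """Sample SD (ddof=1) of per-region mean energies: spatial divergence.

    Transcripts whose expression varies strongly across regions (localized
    expression) score high; uniformly expressed transcripts score ~0.
    """
    x = np.asarray(region_means, dtype=float)
    if x.size < 2:
        raise ValueError("need means for at least 2 regions")
    return float(np.std(x, ddof=1))


def qc_filter(volumes: list[ExpressionVolume],
              flags: dict[str, bool]) -> list[ExpressionVolume]:
    """Drop probes whose QC flag is set (True = has artifacts, exclude).

    Emulates the atlas practice of removing image series with manually
    detected processing artifacts before quantitative analysis.
    """
    missing = [v.probe_id for v in volumes if v.probe_id not in flags]
    if missing:
        raise ValueError(f"missing QC flags for probes: {missing[:5]}")
    kept = [v for v in volumes if not flags[v.probe_id]]
    logger.info("qc_filter: removed %d of %d probes", len(volumes) - len(kept),
                len(volumes))
    return kept
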