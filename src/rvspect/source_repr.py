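"""Source-distribution representations: cuboid voxels, regional voxels, or
a mixture, with dual internal/emulated resolution.

A regional-voxel (r.v.) source is the combination of a fine 3D matrix and a
region map: the map defines the geometry of the regions and the matrix
carries the activity concentration, constant within each labelled region.
The projector, however, sees the source at a coarser *emulated* voxel size
(an exact integer multiple of the internal size), so the same projection
routines serve cuboid and regional sources.  Down-sampling averages over
integer blocks and up-sampling partitions voxels, so total activity is
conserved exactly in both directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volume import VolumeGrid, load_volume, save_volume

__all__ = [
    "RegionMap",
    "SourceModel",
    "RegionalEstimates",
    "build_region_map",
    "downsample_to_emulated",
    "upsample_to_internal",
    "region_average",
    "extract_estimates",
]


@dataclass
class RegionMap:
    """Integer-labelled volume defining regional-voxel geometry and VOIs.

    Label 0 is reserved for unlabelled voxels (updated voxel-wise at the
    emulated size rather than as a region).  ``unlabeled_slices`` gives the
    number of first and last transversal (z) slices forced to label 0 —
    used to keep zero-valued projection rows from a detector smaller than
    the matrix out of any region.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=dict)
    background_label: int = 1
    unlabeled_slices: tuple[int, int] = (0, 0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("region labels must be integers")
        if np.any(self.labels < 0):
            raise ValueError("region labels must be non-negative")
        n0, n1 = self.unlabeled_slices
        nz = self.labels.shape[2]
        if n0 + n1 > nz:
            raise ValueError("unlabeled slices exceed the matrix extent")
        if n0 and np.any(self.labels[:, :, :n0] != 0):
            raise ValueError("first unlabeled slices must carry only label 0")
        if n1 and np.any(self.labels[:, :, nz - n1 :] != 0):
            raise ValueError("last unlabeled slices must carry only label 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_labels(self) -> np.ndarray:
        """Sorted positive labels present in the map."""
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def name_of(self, label: int) -> str:
        return self.label_names.get(int(label), f"region_{int(label)}")

    def as_grid(self) -> VolumeGrid:
        return VolumeGrid(self.labels, self.voxel_size, self.origin)

    def save(self, nifti_path: str, sidecar_path: str) -> None:
        save_volume(VolumeGrid(self.labels.astype(np.int32), self.voxel_size, self.origin), nifti_path)
        meta = {
            "label_names": {str(k): v for k, v in self.label_names.items()},
            "background_label": self.background_label,
            "unlabeled_slices": list(self.unlabeled_slices),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, nifti_path: str, sidecar_path: str) -> "RegionMap":
        vol = load_volume(nifti_path, dtype=np.int32)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            labels=vol.data,
            voxel_size=vol.voxel_size,
            origin=vol.origin,
            label_names={int(k): v for k, v in meta["label_names"].items()},
            background_label=int(meta["background_label"]),
            unlabeled_slices=tuple(meta["unlabeled_slices"]),
        )


def build_region_map(
    voi_masks: list[tuple[int, np.ndarray]],
    voxel_size: tuple[float, float, float],
    background_label: int = 1,
    unlabeled_slices: tuple[int, int] = (25, 25),
    label_names: dict[int, str] | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    shape: tuple[int, int, int] | None = None,
) -> RegionMap:
    """Paint VOI masks into a region map over a background region.

    Voxels covered by a mask get its label, later masks overwriting earlier
    ones; every remaining voxel gets ``background_label``; the first/last
    ``unlabeled_slices`` transversal slices are forced to 0.  The default of
    25 unlabeled slices at each end follows common practice for 128-slice
    matrices imaged with a smaller camera; scale it to the matrix at hand.
    With no masks everything is background (``shape`` is then required).
    """
    if voi_masks:
        shapes = {tuple(np.asarray(m).shape) for _, m in voi_masks}
        if len(shapes) != 1:
            raise ValueError("all VOI masks must share one grid")
        shape = voi_masks[0][1].shape
    elif shape is None:
        raise ValueError("shape is required when no masks are given")
    labels_seen = [lab for lab, _ in voi_masks]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValueError("VOI labels must be unique")
    labels = np.full(shape, background_label, dtype=np.int32)
    for lab, mask in voi_masks:
        if lab <= 0:
            raise ValueError("VOI labels must be positive")
        labels[np.asarray(mask, dtype=bool)] = lab
    n0, n1 = unlabeled_slices
    nz = shape[2]
    if n0:
        labels[:, :, :n0] = 0
    if n1:
        labels[:, :, nz - n1 :] = 0
    return RegionMap(
        labels=labels,
        voxel_size=voxel_size,
        label_names=label_names or {},
        background_label=background_label,
        unlabeled_slices=unlabeled_slices,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# Activity-conserving resampling
# ---------------------------------------------------------------------------

def downsample_to_emulated(internal: VolumeGrid, factor: tuple[int, int, int]) -> VolumeGrid:
    """Block-average to the emulated voxel size (integer factor, exact).

    Each emulated voxel is the arithmetic mean of its factor-block, so
    concentration units are preserved and total activity (concentration
    times voxel volume) is conserved exactly.
    """
    fx, fy, fz = (int(f) for f in factor)
    if min(fx, fy, fz) < 1:
        raise ValueError("factors must be >= 1")
    nx, ny, nz = internal.shape
    if nx % fx or ny % fy or nz % fz:
        raise ValueError(
            f"shape {internal.shape} not divisible by factor {(fx, fy, fz)}"
        )
    data = internal.data.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz)
    out = data.mean(axis=(1, 3, 5))
    vx, vy, vz = internal.voxel_size
    return VolumeGrid(out, (vx * fx, vy * fy, vz * fz), internal.origin)


def upsample_to_internal(emulated: VolumeGrid, factor: tuple[int, int, int]) -> VolumeGrid:
    """Partition emulated voxels into internal ones (inverse of averaging).

    Each internal voxel inherits its parent's concentration; total activity
    is conserved exactly.
    """
    fx, fy, fz = (int(f) for f in factor)
    if min(fx, fy, fz) < 1:
        raise ValueError("factors must be >= 1")
    out = np.repeat(np.repeat(np.repeat(emulated.data, fx, axis=0), fy, axis=1), fz, axis=2)
    vx, vy, vz = emulated.voxel_size
    return VolumeGrid(out, (vx / fx, vy / fy, vz / fz), emulated.origin)


def region_average(
    volume: VolumeGrid | np.ndarray,
    region_map: RegionMap,
    expected_labels: list[int] | None = None,
) -> tuple[dict[int, float], np.ndarray]:
    """Per-region arithmetic means and their broadcast back onto the grid.

    Label-0 voxels pass through unchanged (they are not part of any
    region).  ``expected_labels`` asserts that those regions are non-empty;
    an empty one has an undefined mean and is reported as an error listing
    the label.
    """
    data = volume.data if isinstance(volume, VolumeGrid) else np.asarray(volume)
    if data.shape != region_map.shape:
        raise ValueError("volume and region map must share a grid")
    labels = region_map.labels
    if expected_labels:
        present = set(np.unique(labels).tolist())
        missing = [int(l) for l in expected_labels if l not in present]
        if missing:
            raise ValueError(f"empty regions with undefined means: labels {missing}")
    flat = labels.ravel()
    n = int(flat.max()) + 1
    counts = np.bincount(flat, minlength=n)
    sums = np.bincount(flat, weights=data.ravel(), minlength=n)
    means = np.zeros(n)
    present = counts > 0
    means[present] = sums[present] / counts[present]
    out = means[labels]
    zero = labels == 0
    out[zero] = data[zero]
    per_label = {int(lab): float(means[lab]) for lab in np.nonzero(present)[0] if lab > 0}
    return per_label, out


# ---------------------------------------------------------------------------
# Source model
# ---------------------------------------------------------------------------

@dataclass
class SourceModel:
    """A source distribution with dual internal/emulated resolution.

    ``internal`` holds activity concentration (MBq/mL) on the fine grid
    that conforms to the region map; the projector sees the source after
    block-averaging by ``emulated_factor``.  Without a region map the model
    is pure cuboid voxels (``mode == "cuv"``); with a map covering the
    whole field it is pure regional voxels; a map with label-0 voxels
    inside the field yields the mixed mode, where unlabelled voxels behave
    as cuboid voxels at the emulated size.
    """

    internal: VolumeGrid
    region_map: RegionMap | None = None
    emulated_factor: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        self.emulated_factor = tuple(int(f) for f in self.emulated_factor)
        if min(self.emulated_factor) < 1:
            raise ValueError("emulated factor components must be >= 1")
        nx, ny, nz = self.internal.shape
        fx, fy, fz = self.emulated_factor
        if nx % fx or ny % fy or nz % fz:
            raise ValueError("internal shape must be divisible by the emulated factor")
        if self.region_map is not None and self.region_map.shape != self.internal.shape:
            raise ValueError("region map must live on the internal grid")
        if np.any(self.internal.data < 0):
            raise ValueError("activity concentrations must be non-negative")

    @property
    def mode(self) -> str:
        if self.region_map is None:
            return "cuv"
        if np.any(self.region_map.labels == 0):
            return "mixed"
        return "rv"

    @property
    def emulated_voxel_size(self) -> tuple[float, float, float]:
        v = self.internal.voxel_size
        f = self.emulated_factor
        return (v[0] * f[0], v[1] * f[1], v[2] * f[2])

    def emulated_grid(self) -> VolumeGrid:
        """The source as the projector sees it."""
        return downsample_to_emulated(self.internal, self.emulated_factor)

    def with_internal(self, data: np.ndarray) -> "SourceModel":
        return SourceModel(
            internal=self.internal.copy(data=data),
            region_map=self.region_map,
            emulated_factor=self.emulated_factor,
        )

    def enforce_regional_uniformity(self) -> "SourceModel":
        """Replace labelled-region values by their region means."""
        if self.region_map is None:
            return self
        _, broadcast = region_average(self.internal, self.region_map)
        return self.with_internal(broadcast)

    def save(self, nifti_path: str, sidecar_path: str) -> None:
        save_volume(self.internal, nifti_path)
        meta = {"mode": self.mode, "emulated_factor": list(self.emulated_factor)}
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


@dataclass
class RegionalEstimates:
    """Per-region activity-concentration estimates at one iteration count."""

    labels: list[int]
    names: list[str]
    volumes_ml: list[float]
    concentrations: list[float]
    n_iterations: int = 0

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.labels, self.concentrations))

    def concentration(self, label: int) -> float:
        return self.as_dict()[label]


def extract_estimates(source: SourceModel, n_iterations: int = 0) -> RegionalEstimates:
    """Read out per-region volumes and concentrations from an r.v. solution."""
    if source.region_map is None:
        raise ValueError("extract_estimates requires an r.v. or mixed source model")
    rmap = source.region_map
    voxel_ml = source.internal.voxel_volume_ml
    means, _ = region_average(source.internal, rmap)
    labels = sorted(means)
    volumes = [float((rmap.labels == lab).sum()) * voxel_ml for lab in labels]
    return RegionalEstimates(
        labels=labels,
        names=[rmap.name_of(lab) for lab in labels],
        volumes_ml=volumes,
        concentrations=[means[lab] for lab in labels],
        n_iterations=n_iterations,
    )
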