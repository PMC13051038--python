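"""Physics engine: attenuation, collimator response, scatter, and the
matched rotation-based forward/back projector.

The projector follows the classical rotation-based design for parallel-hole
SPECT: for each view the source (and attenuation map) is rotated into the
detector frame with bilinear in-plane interpolation, each plane parallel to
the detector is attenuated and convolved with a distance-dependent point
spread function, and the planes are summed toward the detector.  The
back-projector is the exact algebraic adjoint (scatter excluded), which the
EM reconstruction relies on.

Conventions (fixed, so results are bit-reproducible):

* volumes are indexed ``[x, y, z]``; the rotation axis is ``z``;
* the detector lies along ``+y`` of the rotated frame, i.e. planes with a
  larger ``y`` index are closer to the detector;
* a view at angle ``theta`` gathers the source at
  ``p_src = c + R(theta) (p_dst - c)`` where ``c`` is the matrix center
  ``(n-1)/2`` and ``R`` is the standard 2D rotation matrix acting on
  ``(x, y)``; out-of-field values are zero;
* attenuation is accumulated plane-by-plane: the photon path from plane
  ``j`` to the detector crosses half of plane ``j`` and all planes beyond
  it, each contributing ``mu * dy`` (``dy`` in cm);
* the PSF distance of plane ``j`` is ``orbit_radius + (y_c - y_j) * dy``
  (planes behind the rotation axis see a larger distance), clamped at 0;
* multi-bed acquisitions project/back-project the same source once per bed
  with the bed's axial (z) offset applied to the detector window; frames
  are ordered bed-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import sparse
from scipy.ndimage import convolve1d

from .volume import VolumeGrid

__all__ = [
    "AcquisitionGeometry",
    "AttenuationModel",
    "ResolutionModel",
    "ScatterModel",
    "ProjectionSet",
    "hu_to_density",
    "density_to_attenuation",
    "psf_kernel",
    "scatter_source",
    "forward_project",
    "back_project",
    "SpectProjector",
    "save_projections",
    "load_projections",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Acquisition geometry
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionGeometry:
    """Orbit and detector description for one SPECT acquisition.

    ``angles`` are view angles in degrees within [0, 360); ``orbit_radius``
    (mm, detector face to rotation axis) may be a scalar or one value per
    view.  ``bed_axial_offsets`` lists one axial offset (mm) per bed
    position; a single-bed study uses ``[0.0]``.  ``detector_mask`` marks
    valid detector pixels (the physical camera can be smaller than the
    projection matrix).
    """

    angles: np.ndarray
    orbit_radius: np.ndarray
    pixel_size: tuple[float, float]
    detector_shape: tuple[int, int]
    time_per_view: float
    bed_axial_offsets: tuple[float, ...] = (0.0,)
    detector_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if np.any(self.angles < 0.0) or np.any(self.angles >= 360.0):
            raise ValueError("view angles must lie in [0, 360)")
        self.orbit_radius = np.broadcast_to(
            np.asarray(self.orbit_radius, dtype=float), self.angles.shape
        ).copy()
        if np.any(self.orbit_radius <= 0):
            raise ValueError("orbit radii must be positive")
        if self.time_per_view <= 0:
            raise ValueError("time_per_view must be positive")
        self.pixel_size = (float(self.pixel_size[0]), float(self.pixel_size[1]))
        self.detector_shape = (int(self.detector_shape[0]), int(self.detector_shape[1]))
        self.bed_axial_offsets = tuple(float(o) for o in self.bed_axial_offsets)
        if self.detector_mask is not None:
            self.detector_mask = np.asarray(self.detector_mask, dtype=bool)
            if self.detector_mask.shape != self.detector_shape:
                raise ValueError("detector_mask must match detector_shape")

    @property
    def n_views(self) -> int:
        return len(self.angles)

    @property
    def n_beds(self) -> int:
        return len(self.bed_axial_offsets)

    @property
    def n_frames(self) -> int:
        """Total projection frames, bed-major: frame = bed * n_views + view."""
        return self.n_beds * self.n_views

    def frame_index(self, bed: int, view: int) -> int:
        return bed * self.n_views + view

    def frame_bed_view(self, frame: int) -> tuple[int, int]:
        return divmod(frame, self.n_views)

    @classmethod
    def circular(
        cls,
        n_views: int = 60,
        orbit_radius: float = 250.0,
        pixel_size: tuple[float, float] = (4.42, 4.42),
        detector_shape: tuple[int, int] = (128, 128),
        time_per_view: float = 45.0,
        bed_axial_offsets: tuple[float, ...] = (0.0,),
        detector_mask: np.ndarray | None = None,
    ) -> "AcquisitionGeometry":
        """Evenly spaced views over 360 degrees on a circular orbit."""
        angles = np.arange(n_views) * (360.0 / n_views)
        return cls(
            angles=angles,
            orbit_radius=orbit_radius,
            pixel_size=pixel_size,
            detector_shape=detector_shape,
            time_per_view=time_per_view,
            bed_axial_offsets=bed_axial_offsets,
            detector_mask=detector_mask,
        )

    def to_dict(self) -> dict:
        d = {
            "angles": self.angles.tolist(),
            "orbit_radius": self.orbit_radius.tolist(),
            "pixel_size": list(self.pixel_size),
            "detector_shape": list(self.detector_shape),
            "time_per_view": self.time_per_view,
            "bed_axial_offsets": list(self.bed_axial_offsets),
        }
        if self.detector_mask is not None:
            d["detector_mask"] = self.detector_mask.astype(int).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        mask = d.get("detector_mask")
        return cls(
            angles=np.asarray(d["angles"], dtype=float),
            orbit_radius=np.asarray(d["orbit_radius"], dtype=float),
            pixel_size=tuple(d["pixel_size"]),
            detector_shape=tuple(d["detector_shape"]),
            time_per_view=float(d["time_per_view"]),
            bed_axial_offsets=tuple(d["bed_axial_offsets"]),
            detector_mask=None if mask is None else np.asarray(mask, dtype=bool),
        )


@dataclass
class ProjectionSet:
    """Per-frame count images plus the geometry that produced them.

    ``counts`` has shape ``(n_frames, nu, nv)`` with frames ordered
    bed-major (all views of bed 0, then bed 1, ...).  Values are expected
    counts for noise-free data or integer observed counts.
    """

    counts: np.ndarray
    geometry: AcquisitionGeometry
    is_noisy: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.geometry.n_frames, *self.geometry.detector_shape)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with geometry "
                f"(expected {expected})"
            )
        if np.any(self.counts < 0):
            raise ValueError("projection counts must be non-negative")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def copy(self, counts: np.ndarray | None = None, is_noisy: bool | None = None) -> "ProjectionSet":
        return ProjectionSet(
            counts=self.counts.copy() if counts is None else np.asarray(counts),
            geometry=self.geometry,
            is_noisy=self.is_noisy if is_noisy is None else is_noisy,
        )


def save_projections(projections: ProjectionSet, nifti_path: str, geometry_path: str) -> None:
    """Write projections as a multi-frame NIfTI plus a JSON geometry sidecar.

    The round-trip through :func:`load_projections` is bit-exact.
    """
    # NIfTI spatial axes first: store as (nu, nv, n_frames)
    arr = np.moveaxis(np.asarray(projections.counts, dtype=np.float64), 0, -1)
    img = nib.Nifti1Image(arr, np.eye(4))
    nib.save(img, nifti_path)
    meta = {"geometry": projections.geometry.to_dict(), "is_noisy": projections.is_noisy}
    with open(geometry_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_projections(nifti_path: str, geometry_path: str) -> ProjectionSet:
    with open(geometry_path) as fh:
        meta = json.load(fh)
    arr = np.asarray(nib.load(nifti_path).dataobj, dtype=np.float64)
    counts = np.moveaxis(arr, -1, 0)
    return ProjectionSet(
        counts=counts,
        geometry=AcquisitionGeometry.from_dict(meta["geometry"]),
        is_noisy=bool(meta.get("is_noisy", False)),
    )


# ---------------------------------------------------------------------------
# CT -> density -> attenuation
# ---------------------------------------------------------------------------

@dataclass
class AttenuationModel:
    """Piecewise-linear HU-to-density map and material attenuation table.

    The default segment table anchors air (-1000 HU -> 0 g/cm^3) and water
    (0 HU -> 1 g/cm^3) and rises more slowly through the bone range, the
    usual bilinear CT calibration.  Densities above ``material_threshold``
    (g/cm^3) are treated as bone, below as soft tissue; the mass attenuation
    coefficients (cm^2/g) default to approximate values at the 208 keV
    photopeak of Lu-177.
    """

    hu_to_density_segments: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.0),
        (0.0, 1.0),
        (1000.0, 1.6),
        (3000.0, 2.8),
    )
    material_threshold: float = 1.15
    mass_attenuation: dict = field(
        default_factory=lambda: {"soft_tissue": 0.136, "bone": 0.150}
    )

    def __post_init__(self) -> None:
        hu = np.array([p[0] for p in self.hu_to_density_segments])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if any(v <= 0 for v in self.mass_attenuation.values()):
            raise ValueError("mass attenuation coefficients must be positive")


def hu_to_density(ct: VolumeGrid, model: AttenuationModel | None = None) -> VolumeGrid:
    """Convert a CT-like HU volume to mass density (g/cm^3).

    Voxel-wise piecewise-linear interpolation of the model's segment table,
    held constant beyond the outermost breakpoints and clamped at zero.
    """
    model = model or AttenuationModel()
    if not np.all(np.isfinite(ct.data)):
        raise ValueError("CT volume contains non-finite values")
    hu = np.array([p[0] for p in model.hu_to_density_segments])
    rho = np.array([p[1] for p in model.hu_to_density_segments])
    density = np.interp(ct.data, hu, rho)
    return ct.copy(data=np.maximum(density, 0.0))


def density_to_attenuation(density: VolumeGrid, model: AttenuationModel | None = None) -> VolumeGrid:
    """Convert density (g/cm^3) to linear attenuation (cm^-1).

    Voxels are thresholded into soft tissue and bone by density and scaled
    by the material's mass attenuation coefficient.
    """
    model = model or AttenuationModel()
    if np.any(density.data < 0):
        raise ValueError("density must be non-negative")
    coeff = np.where(
        density.data > model.material_threshold,
        model.mass_attenuation["bone"],
        model.mass_attenuation["soft_tissue"],
    )
    return density.copy(data=density.data * coeff)


# ---------------------------------------------------------------------------
# Collimator-detector response
# ---------------------------------------------------------------------------

@dataclass
class ResolutionModel:
    """Distance-dependent Gaussian collimator-detector response.

    The geometric collimator resolution grows linearly with source-to-
    collimator distance ``d``:

        FWHM(d)^2 = intrinsic_fwhm^2 + (hole_diameter * (L + d) / L)^2

    with ``L`` the effective hole length.  Defaults approximate a
    medium-energy parallel-hole collimator.  Kernels are truncated at
    ``kernel_truncation`` sigma and renormalized to sum exactly 1.
    """

    hole_diameter: float = 3.0
    effective_hole_length: float = 50.0
    intrinsic_fwhm: float = 3.8
    kernel_truncation: float = 4.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.effective_hole_length <= 0:
            raise ValueError("effective hole length must be positive")

    def fwhm(self, distance: float) -> float:
        """Total system FWHM (mm) at source-to-collimator distance (mm)."""
        d = max(float(distance), 0.0)
        geo = self.hole_diameter * (self.effective_hole_length + d) / self.effective_hole_length
        return float(np.hypot(self.intrinsic_fwhm, geo))


def _gaussian_kernel_1d(sigma_px: float, truncation: float) -> np.ndarray:
    """Symmetric 1D Gaussian, truncated at ``truncation * sigma``, sum 1."""
    if sigma_px <= 1e-6:
        return np.ones(1)
    radius = max(int(np.ceil(truncation * sigma_px)), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_px) ** 2)
    return k / k.sum()


def psf_kernel(distance: float, model: ResolutionModel, pixel_size: tuple[float, float]) -> np.ndarray:
    """Discrete 2D PSF at a given source-to-collimator distance (mm).

    Separable Gaussian (outer product of two 1D kernels), normalized to sum
    exactly 1; a disabled model yields the identity kernel.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if not model.enabled:
        return np.ones((1, 1))
    sigma_mm = model.fwhm(distance) * FWHM_TO_SIGMA
    ku = _gaussian_kernel_1d(sigma_mm / pixel_size[0], model.kernel_truncation)
    kv = _gaussian_kernel_1d(sigma_mm / pixel_size[1], model.kernel_truncation)
    return np.outer(ku, kv)


# ---------------------------------------------------------------------------
# Effective scatter source
# ---------------------------------------------------------------------------

@dataclass
class ScatterModel:
    """Effective-scatter-source model.

    The scatter contribution is modeled by convolving the activity with a
    normalized 3D kernel, scaling by ``amplitude`` (scatter-to-primary
    ratio), and projecting the result like an ordinary source.  The default
    kernel is an isotropic mono-exponential, ``exp(-r / decay_length)``.

    ``mean_scatter_energy_mode`` selects, for the projection of the scatter
    source, an attenuation map scaled to the mean energy of the scattered
    photons instead of the photopeak map.  The energy bookkeeping behind
    that mean is represented by the single factor
    ``scatter_energy_mu_scale`` (ratio of mu at the mean scatter energy to
    mu at the photopeak; scattered photons are softer, so > 1).  This mode
    is a simplified two-energy weighting and is not validated.
    """

    amplitude: float = 0.3
    decay_length: float = 30.0
    kernel: np.ndarray | None = None
    mean_scatter_energy_mode: bool = False
    scatter_energy_mu_scale: float = 1.1
    enabled: bool = True

    def kernel_for(self, voxel_size: tuple[float, float, float]) -> np.ndarray:
        """The normalized 3D scatter kernel sampled on the given grid."""
        if self.kernel is not None:
            k = np.asarray(self.kernel, dtype=float)
            if np.any(k < 0):
                raise ValueError("scatter kernel must be non-negative")
            return k / k.sum()
        radius_mm = 4.0 * self.decay_length
        half = [max(int(np.ceil(radius_mm / v)), 1) for v in voxel_size]
        axes = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size)]
        r = np.sqrt(
            axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
        )
        k = np.exp(-r / self.decay_length)
        return k / k.sum()


def scatter_source(
    activity: VolumeGrid, model: ScatterModel
) -> tuple[VolumeGrid, VolumeGrid | None]:
    """Effective scatter source: activity convolved with the scatter kernel.

    Returns the scaled effective source and, in mean-scatter-energy mode,
    the voxel-wise multiplicative weight applied to the photopeak
    attenuation map when the scatter source is projected.
    """
    if np.any(activity.data < 0):
        raise ValueError("activity must be non-negative")
    if not model.enabled:
        return activity.copy(data=np.zeros_like(activity.data)), None
    from scipy.signal import fftconvolve

    k = model.kernel_for(activity.voxel_size)
    eff = model.amplitude * fftconvolve(activity.data, k, mode="same")
    eff = np.maximum(eff, 0.0)
    weight = None
    if model.mean_scatter_energy_mode:
        weight = activity.copy(
            data=np.full_like(activity.data, model.scatter_energy_mu_scale)
        )
    return activity.copy(data=eff), weight


# ---------------------------------------------------------------------------
# Rotation operator (exact adjoint pair via a sparse matrix)
# ---------------------------------------------------------------------------

_ROTATION_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _rotation_matrix(shape_xy: tuple[int, int], angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear-interpolation rotation acting on flattened (x, y) planes.

    ``out = R @ flat`` gathers the input at ``c + R2(angle) (p - c)``; the
    transpose is the exact adjoint (splatting with the same weights).
    Out-of-field samples contribute nothing.
    """
    key = (shape_xy, round(float(angle_deg) % 360.0, 9))
    cached = _ROTATION_CACHE.get(key)
    if cached is not None:
        return cached
    nx, ny = shape_xy
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    th = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(th), np.sin(th)
    tx, ty = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx, dy = tx - cx, ty - cy
    sx = cx + cos_t * dx - sin_t * dy
    sy = cy + sin_t * dx + cos_t * dy
    x0 = np.floor(sx).astype(int)
    y0 = np.floor(sy).astype(int)
    fx = sx - x0
    fy = sy - y0
    rows, cols, vals = [], [], []
    target = (tx * ny + ty).ravel()
    for ox, wx in ((0, 1 - fx), (1, fx)):
        for oy, wy in ((0, 1 - fy), (1, fy)):
            xi = x0 + ox
            yi = y0 + oy
            w = (wx * wy).ravel()
            inside = ((xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)).ravel()
            keep = inside & (w > 0)
            rows.append(target[keep])
            cols.append((xi.ravel() * ny + yi.ravel())[keep])
            vals.append(w[keep])
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    )
    if len(_ROTATION_CACHE) > 512:
        _ROTATION_CACHE.clear()
    _ROTATION_CACHE[key] = mat
    return mat


def rotate_volume(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a volume about the z axis into the frame at ``angle_deg``."""
    nx, ny, nz = vol.shape
    mat = _rotation_matrix((nx, ny), angle_deg)
    out = mat @ vol.reshape(nx * ny, nz)
    return out.reshape(nx, ny, nz)


def rotate_volume_adjoint(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    nx, ny, nz = vol.shape
    mat = _rotation_matrix((nx, ny), angle_deg)
    out = mat.T @ vol.reshape(nx * ny, nz)
    return out.reshape(nx, ny, nz)


# ---------------------------------------------------------------------------
# The projector
# ---------------------------------------------------------------------------

class SpectProjector:
    """Matched rotation-based forward/back projector on the emulated grid.

    Precomputes per-view rotation matrices, attenuation weight volumes and
    PSF kernels; ``forward`` and ``back`` are exact algebraic adjoints of
    each other (scatter, an additive forward term, excluded).

    Parameters
    ----------
    grid
        A :class:`~rvspect.volume.VolumeGrid` defining the emulated source
        grid (its data are ignored; shape/voxel size matter).
    mu
        Photopeak linear-attenuation map (cm^-1) on the same grid, or None
        to disable attenuation.
    geometry, resolution, scatter
        Acquisition geometry and physics models.
    calibration
        System sensitivity in counts * mL / (MBq * s): expected counts per
        second from 1 MBq/mL in 1 mL, attenuation-free.
    """

    def __init__(
        self,
        grid: VolumeGrid,
        mu: VolumeGrid | None,
        geometry: AcquisitionGeometry,
        resolution: ResolutionModel | None = None,
        scatter: ScatterModel | None = None,
        calibration: float = 1.0,
    ) -> None:
        nx, ny, nz = grid.shape
        nu, nv = geometry.detector_shape
        if nu != nx:
            raise ValueError(
                f"detector u-size {nu} must equal transaxial matrix size {nx}"
            )
        if abs(grid.voxel_size[0] - grid.voxel_size[1]) > 1e-9:
            raise ValueError("in-plane voxels must be square for the rotation-based projector")
        if abs(geometry.pixel_size[0] - grid.voxel_size[0]) > 1e-6 or abs(
            geometry.pixel_size[1] - grid.voxel_size[2]
        ) > 1e-6:
            raise ValueError("detector pixel size must match the emulated voxel size")
        if mu is not None:
            if mu.shape != grid.shape:
                raise ValueError("attenuation map shape must match the source grid")
            if np.any(mu.data < 0):
                raise ValueError("attenuation coefficients must be non-negative")
        self.grid = grid
        self.mu = mu
        self.geometry = geometry
        self.resolution = resolution or ResolutionModel(enabled=False)
        self.scatter = scatter or ScatterModel(enabled=False)
        self.calibration = float(calibration)
        self.shape = (nx, ny, nz)
        self._scale = self.calibration * geometry.time_per_view * grid.voxel_volume_ml
        self._dy_cm = grid.voxel_size[1] / 10.0
        self._att_cache: dict[int, np.ndarray | None] = {}
        self._att_scatter_cache: dict[int, np.ndarray | None] = {}
        self._kernel_cache: dict[float, list] = {}
        # bed z-window start indices, center-aligned at zero offset
        dz = grid.voxel_size[2]
        self._bed_z0 = [
            (nz - nv) // 2 + int(round(off / dz)) for off in geometry.bed_axial_offsets
        ]
        self._mask = geometry.detector_mask

    # -- per-view pieces ---------------------------------------------------

    def _attenuation_weights(self, view: int, mu_scale: float = 1.0) -> np.ndarray | None:
        """exp(-sum mu dy) from each voxel to the detector, in the rotated frame."""
        if self.mu is None:
            return None
        cache = self._att_cache if mu_scale == 1.0 else self._att_scatter_cache
        w = cache.get(view)
        if w is None:
            m = rotate_volume(self.mu.data * mu_scale, self.geometry.angles[view])
            # path length: half of own plane plus all planes nearer the detector
            s = np.cumsum(m[:, ::-1, :], axis=1)[:, ::-1, :]
            w = np.exp(-self._dy_cm * (s - 0.5 * m))
            cache[view] = w
        return w

    def _plane_kernels(self, view: int) -> list | None:
        """(ku, kv) 1D kernels per y-plane, or None when resolution is off."""
        if not self.resolution.enabled:
            return None
        radius = float(self.geometry.orbit_radius[view])
        kernels = self._kernel_cache.get(radius)
        if kernels is None:
            ny = self.shape[1]
            dy = self.grid.voxel_size[1]
            yc = (ny - 1) / 2.0
            kernels = []
            for j in range(ny):
                d = max(radius + (yc - j) * dy, 0.0)
                sigma_mm = self.resolution.fwhm(d) * FWHM_TO_SIGMA
                ku = _gaussian_kernel_1d(
                    sigma_mm / self.grid.voxel_size[0], self.resolution.kernel_truncation
                )
                kv = _gaussian_kernel_1d(
                    sigma_mm / self.grid.voxel_size[2], self.resolution.kernel_truncation
                )
                kernels.append((ku, kv))
            self._kernel_cache[radius] = kernels
        return kernels

    # -- single-frame kernels ----------------------------------------------

    def _forward_frame(self, emulated: np.ndarray, frame: int, mu_scale: float = 1.0) -> np.ndarray:
        bed, view = self.geometry.frame_bed_view(frame)
        nx, ny, nz = self.shape
        nu, nv = self.geometry.detector_shape
        rot = rotate_volume(emulated, self.geometry.angles[view])
        att = self._attenuation_weights(view, mu_scale)
        if att is not None:
            rot = rot * att
        kernels = self._plane_kernels(view)
        if kernels is None:
            acc = rot.sum(axis=1)
        else:
            acc = np.zeros((nx, nz))
            for j in range(ny):
                plane = rot[:, j, :]
                ku, kv = kernels[j]
                if len(ku) > 1:
                    plane = convolve1d(plane, ku, axis=0, mode="constant")
                if len(kv) > 1:
                    plane = convolve1d(plane, kv, axis=1, mode="constant")
                acc += plane
        proj = np.zeros((nu, nv))
        z0 = self._bed_z0[bed]
        lo, hi = max(z0, 0), min(z0 + nv, nz)
        if lo < hi:
            proj[:, lo - z0 : hi - z0] = acc[:, lo:hi]
        proj *= self._scale
        if self._mask is not None:
            proj = proj * self._mask
        return proj

    def _back_frame(self, proj: np.ndarray, frame: int) -> np.ndarray:
        bed, view = self.geometry.frame_bed_view(frame)
        nx, ny, nz = self.shape
        nu, nv = self.geometry.detector_shape
        if self._mask is not None:
            proj = proj * self._mask
        y_emb = np.zeros((nx, nz))
        z0 = self._bed_z0[bed]
        lo, hi = max(z0, 0), min(z0 + nv, nz)
        if lo < hi:
            y_emb[:, lo:hi] = proj[:, lo - z0 : hi - z0]
        y_emb = y_emb * self._scale
        att = self._attenuation_weights(view)
        kernels = self._plane_kernels(view)
        rot = np.empty((nx, ny, nz))
        if kernels is None:
            rot[:] = y_emb[:, None, :]
        else:
            for j in range(ny):
                plane = y_emb
                ku, kv = kernels[j]
                # symmetric kernels: correlation == convolution
                if len(ku) > 1:
                    plane = convolve1d(plane, ku, axis=0, mode="constant")
                if len(kv) > 1:
                    plane = convolve1d(plane, kv, axis=1, mode="constant")
                rot[:, j, :] = plane
        if att is not None:
            rot *= att
        return rotate_volume_adjoint(rot, self.geometry.angles[view])

    # -- public API ---------------------------------------------------------

    def forward(
        self,
        emulated: np.ndarray,
        frames: list[int] | None = None,
        include_scatter: bool = True,
    ) -> np.ndarray:
        """Expected counts for the given frames (default: all frames).

        ``emulated`` is the activity concentration (MBq/mL) on the emulated
        grid.  The scatter term, when enabled and requested, adds the
        projected effective scatter source.
        """
        if emulated.shape != self.shape:
            raise ValueError("source shape must match the projector grid")
        frames = list(range(self.geometry.n_frames)) if frames is None else list(frames)
        nu, nv = self.geometry.detector_shape
        out = np.zeros((len(frames), nu, nv))
        for i, f in enumerate(frames):
            out[i] = self._forward_frame(emulated, f)
        if include_scatter and self.scatter.enabled:
            eff, weight = scatter_source(self.grid.copy(data=emulated), self.scatter)
            mu_scale = (
                self.scatter.scatter_energy_mu_scale
                if self.scatter.mean_scatter_energy_mode
                else 1.0
            )
            for i, f in enumerate(frames):
                out[i] += self._forward_frame(eff.data, f, mu_scale=mu_scale)
        return out

    def back(self, counts: np.ndarray, frames: list[int] | None = None) -> np.ndarray:
        """Adjoint of :meth:`forward` (without the scatter term)."""
        frames = list(range(self.geometry.n_frames)) if frames is None else list(frames)
        if counts.shape[0] != len(frames):
            raise ValueError("counts first dimension must match the frame list")
        out = np.zeros(self.shape)
        for i, f in enumerate(frames):
            out += self._back_frame(counts[i], f)
        return out

    def sensitivity(self, frames: list[int] | None = None) -> np.ndarray:
        """Back-projection of unit counts (masked): the EM denominator."""
        frames = list(range(self.geometry.n_frames)) if frames is None else list(frames)
        nu, nv = self.geometry.detector_shape
        ones = np.ones((len(frames), nu, nv))
        return self.back(ones, frames)


# ---------------------------------------------------------------------------
# Module-level operations on source models
# ---------------------------------------------------------------------------

def forward_project(
    source,
    mu: VolumeGrid | None,
    geometry: AcquisitionGeometry,
    resolution: ResolutionModel | None = None,
    scatter: ScatterModel | None = None,
    calibration: float = 1.0,
) -> ProjectionSet:
    """Project a source model (or plain volume) to expected counts.

    ``source`` may be a :class:`~rvspect.source_repr.SourceModel` (projected
    at its emulated resolution) or a :class:`VolumeGrid` already at the
    emulated voxel size.
    """
    from .source_repr import SourceModel

    if isinstance(source, SourceModel):
        grid = source.emulated_grid()
    else:
        grid = source
    proj = SpectProjector(grid, mu, geometry, resolution, scatter, calibration)
    counts = proj.forward(grid.data)
    return ProjectionSet(counts=counts, geometry=geometry, is_noisy=False)


def back_project(
    projections: ProjectionSet,
    mu: VolumeGrid | None,
    geometry: AcquisitionGeometry,
    resolution: ResolutionModel | None = None,
    source_template=None,
    calibration: float = 1.0,
):
    """Adjoint projection of count data onto a source model's grid.

    Returns the accumulation up-sampled into the template's internal
    representation (regional averaging, when applicable, is applied by the
    reconstruction engine, not here).  With ``source_template=None`` a
    plain :class:`VolumeGrid` on the emulated grid is returned.
    """
    from .source_repr import SourceModel, upsample_to_internal

    if source_template is None:
        raise ValueError("back_project requires a source template or grid")
    if isinstance(source_template, SourceModel):
        grid = source_template.emulated_grid()
    else:
        grid = source_template
    proj = SpectProjector(grid, mu, geometry, resolution, None, calibration)
    acc = proj.back(projections.counts)
    if isinstance(source_template, SourceModel):
        emu = grid.copy(data=acc)
        return upsample_to_internal(emu, source_template.emulated_factor)
    return grid.copy(data=acc)
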