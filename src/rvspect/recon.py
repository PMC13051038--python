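"""OS-EM estimation engine operating identically over cuboid-voxel and
regional-voxel source models, plus activity calibration.

The update is the standard multiplicative EM step

    x <- x * A^T( y / (A x + s) ) / A^T 1

applied subset by subset, with ``s`` the forward-projected effective
scatter term (held fixed additively inside the denominator of the ratio,
never deconvolved).  For regional-voxel templates both the back-projected
ratio and the sensitivity are averaged within each region *before* taking
their quotient — the maximum-likelihood update for region basis functions,
whose fixed point on noise-free self-consistent data is the true regional
concentration.  Unlabelled (label-0) voxels update voxel-wise at the
emulated size, which is what makes mixed cuboid/regional sources work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system_model import (
    AcquisitionGeometry,
    ProjectionSet,
    ResolutionModel,
    ScatterModel,
    SpectProjector,
)
from .source_repr import (
    RegionMap,
    RegionalEstimates,
    SourceModel,
    downsample_to_emulated,
    extract_estimates,
    region_average,
    upsample_to_internal,
)
from .volume import VolumeGrid

__all__ = [
    "ReconConfig",
    "CalibrationFactor",
    "osem",
    "osem_system_matrix",
    "calibrate",
    "reconstruct_bootstrap",
    "poisson_log_likelihood",
]

_RATIO_EPS = 1e-30


@dataclass
class ReconConfig:
    """OS-EM settings.

    ``n_subsets`` views are assigned round-robin by angle-index stride, so
    each subset sees maximally separated angles.  The initial estimate is a
    uniform positive constant; values are floored at ``nonneg_floor`` after
    every update.  Typical choices: 40 iterations x 10 subsets for cuboid
    voxels, 8 x 10 for regional voxels.
    """

    n_iterations: int = 8
    n_subsets: int = 10
    initial_value: float = 1.0
    nonneg_floor: float = 1e-12
    convergence_log: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("iterations and subsets must be >= 1")
        if self.initial_value <= 0:
            raise ValueError("initial value must be positive")


@dataclass
class CalibrationFactor:
    """System calibration: image units per true MBq/mL.

    Dividing a reconstruction by ``value`` converts it to MBq/mL.
    ``provenance`` records the phantom and VOI the factor came from.
    """

    value: float
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("calibration factor must be positive")


def _subset_frames(geometry: AcquisitionGeometry, n_subsets: int) -> list[list[int]]:
    """Frames per subset: view stride n_subsets, all beds of a view together."""
    n_views = geometry.n_views
    if n_subsets > n_views:
        raise ValueError("more subsets than views")
    subsets = []
    for s in range(n_subsets):
        views = range(s, n_views, n_subsets)
        frames = [
            geometry.frame_index(b, v)
            for v in views
            for b in range(geometry.n_beds)
        ]
        subsets.append(frames)
    return subsets


def poisson_log_likelihood(observed: np.ndarray, expected: np.ndarray) -> float:
    """Poisson log-likelihood sum(y log yhat - yhat), constants dropped."""
    y = np.asarray(observed, dtype=float)
    lam = np.maximum(np.asarray(expected, dtype=float), _RATIO_EPS)
    return float(np.sum(np.where(y > 0, y * np.log(lam), 0.0) - lam))


def _em_step(
    x: np.ndarray,
    y: np.ndarray,
    forward,
    back,
    sens: np.ndarray,
    floor: float,
) -> np.ndarray:
    """One multiplicative EM update with guarded ratios and frozen zeros."""
    yhat = forward(x)
    ratio = np.where(yhat > _RATIO_EPS, y / np.maximum(yhat, _RATIO_EPS), 0.0)
    num = back(ratio)
    update = np.where(sens > 0, num / np.where(sens > 0, sens, 1.0), 1.0)
    return np.maximum(x * update, floor)


def osem_system_matrix(
    system_matrix: np.ndarray,
    data: np.ndarray,
    x0: np.ndarray,
    n_iterations: int,
    n_subsets: int = 1,
    scatter: np.ndarray | None = None,
    floor: float = 0.0,
) -> np.ndarray:
    """OS-EM for an explicit dense system matrix (rows = measurements).

    The same update rule as the full projector path, for small systems
    where the matrix can be written down; subsets partition the rows
    round-robin.
    """
    A = np.asarray(system_matrix, dtype=float)
    y = np.asarray(data, dtype=float)
    s = np.zeros_like(y) if scatter is None else np.asarray(scatter, dtype=float)
    x = np.asarray(x0, dtype=float).copy()
    rows = [list(range(r, A.shape[0], n_subsets)) for r in range(n_subsets)]
    for _ in range(n_iterations):
        for rr in rows:
            Asub = A[rr]
            sens = Asub.sum(axis=0)
            x = _em_step(
                x,
                y[rr],
                lambda v, Asub=Asub, ssub=s[rr]: Asub @ v + ssub,
                lambda r, Asub=Asub: Asub.T @ r,
                sens,
                floor,
            )
    return x


def osem(
    projections: ProjectionSet,
    mu: VolumeGrid | None,
    geometry: AcquisitionGeometry,
    resolution: ResolutionModel | None,
    scatter: ScatterModel | None,
    source_template: SourceModel,
    config: ReconConfig,
    calibration: float = 1.0,
    log_region_map: RegionMap | None = None,
    initial: np.ndarray | None = None,
) -> tuple[SourceModel, list[RegionalEstimates]]:
    """OS-EM reconstruction for cuboid, regional or mixed source models.

    Returns the converged source model and, when ``convergence_log`` is
    set, one :class:`RegionalEstimates` per iteration (for cuboid
    templates, pass ``log_region_map`` to log VOI means instead).
    ``initial`` warm-starts from a previous estimate on the internal grid
    instead of the uniform ``config.initial_value``.  Deterministic given
    the configuration.
    """
    if np.any(projections.counts < 0):
        raise ValueError("projection counts must be non-negative")
    factor = source_template.emulated_factor
    emu_grid = source_template.emulated_grid()
    projector = SpectProjector(emu_grid, mu, geometry, resolution, scatter, calibration)
    subsets = _subset_frames(geometry, config.n_subsets)
    sens_emu = [projector.sensitivity(frames) for frames in subsets]
    rmap = source_template.region_map
    block = int(np.prod(factor))

    def to_internal_avg(emulated_arr: np.ndarray) -> np.ndarray:
        """Up-sample to internal and region-average (label 0 passes through)."""
        internal = upsample_to_internal(emu_grid.copy(data=emulated_arr), factor).data
        if rmap is None:
            return internal
        _, broadcast = region_average(internal, rmap)
        return broadcast

    sens_int = [to_internal_avg(s) for s in sens_emu]

    if initial is not None:
        if initial.shape != source_template.internal.shape:
            raise ValueError("initial estimate must live on the internal grid")
        x = np.asarray(initial, dtype=float).copy()
    else:
        x = np.full(source_template.internal.shape, config.initial_value, dtype=float)
    if rmap is not None:
        _, x = region_average(x, rmap)
    log: list[RegionalEstimates] = []
    for it in range(1, config.n_iterations + 1):
        for frames, sens in zip(subsets, sens_int):
            x_emu = downsample_to_emulated(
                source_template.internal.copy(data=x), factor
            ).data
            yhat = projector.forward(x_emu, frames)
            y = projections.counts[frames]
            ratio = np.where(yhat > _RATIO_EPS, y / np.maximum(yhat, _RATIO_EPS), 0.0)
            num = to_internal_avg(projector.back(ratio, frames))
            update = np.where(sens > 0, num / np.where(sens > 0, sens, 1.0), 1.0)
            x = np.maximum(x * update, config.nonneg_floor)
        if config.convergence_log:
            logmap = rmap if rmap is not None else log_region_map
            if logmap is not None:
                xs = x
                if logmap.shape != x.shape:
                    # VOI map on a finer grid: re-sample by voxel subdivision
                    f = tuple(int(a // b) for a, b in zip(logmap.shape, x.shape))
                    if tuple(a * b for a, b in zip(f, x.shape)) != logmap.shape:
                        raise ValueError(
                            "log region map shape must be an integer multiple "
                            "of the reconstruction grid"
                        )
                    xs = upsample_to_internal(
                        source_template.internal.copy(data=x), f
                    ).data
                means, _ = region_average(xs, logmap)
                labels = sorted(means)
                voxel_ml = float(np.prod(logmap.voxel_size)) / 1000.0
                log.append(
                    RegionalEstimates(
                        labels=labels,
                        names=[logmap.name_of(lab) for lab in labels],
                        volumes_ml=[
                            float((logmap.labels == lab).sum()) * voxel_ml
                            for lab in labels
                        ],
                        concentrations=[means[lab] for lab in labels],
                        n_iterations=it,
                    )
                )
    return source_template.with_internal(x), log


def calibrate(
    recon_of_uniform_phantom: VolumeGrid,
    voi: np.ndarray,
    true_concentration: float,
) -> CalibrationFactor:
    """Calibration factor from a reconstructed uniform phantom.

    The factor is the mean reconstructed value in the VOI divided by the
    known concentration; dividing reconstructions by it yields MBq/mL.
    """
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise ValueError("calibration VOI is empty")
    if true_concentration <= 0:
        raise ValueError("true concentration must be positive")
    mean = float(recon_of_uniform_phantom.data[voi].mean())
    return CalibrationFactor(
        value=mean / true_concentration,
        provenance={
            "voi_volume_ml": float(voi.sum()) * recon_of_uniform_phantom.voxel_volume_ml,
            "true_concentration": true_concentration,
        },
    )


def reconstruct_bootstrap(
    noise_set,
    mu: VolumeGrid | None,
    geometry: AcquisitionGeometry,
    resolution: ResolutionModel | None,
    scatter: ScatterModel | None,
    source_template: SourceModel,
    config: ReconConfig,
    calibration: float = 1.0,
) -> list[RegionalEstimates]:
    """OS-EM per bootstrap realization with identical settings.

    Returns the final regional estimates of each realization, ready for
    mean +/- SD summaries downstream.
    """
    results = []
    for realization in noise_set.realizations:
        model, _ = osem(
            realization,
            mu,
            geometry,
            resolution,
            scatter,
            source_template,
            ReconConfig(
                n_iterations=config.n_iterations,
                n_subsets=config.n_subsets,
                initial_value=config.initial_value,
                nonneg_floor=config.nonneg_floor,
                convergence_log=False,
            ),
            calibration=calibration,
        )
        results.append(extract_estimates(model, n_iterations=config.n_iterations))
    return results
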