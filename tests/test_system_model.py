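"""Attenuation modeling, PSF kernels, scatter, and the projector pair."""

import numpy as np
import pytest

import rvspect as rv
from rvspect.system_model import _gaussian_kernel_1d


class TestHuToDensity:
    def test_water_and_air_anchors(self, small_grid):
        ct = small_grid.copy(data=np.zeros(small_grid.shape))
        assert np.allclose(rv.hu_to_density(ct).data, 1.0)
        ct = small_grid.copy(data=np.full(small_grid.shape, -1000.0))
        assert np.allclose(rv.hu_to_density(ct).data, 0.0)

    def test_linear_interpolation_between_breakpoints(self, small_grid):
        model = rv.AttenuationModel()
        (h0, r0), (h1, r1) = model.hu_to_density_segments[1:3]
        hu = 0.3 * h0 + 0.7 * h1
        expected = r0 + (hu - h0) * (r1 - r0) / (h1 - h0)  # two-point formula
        ct = small_grid.copy(data=np.full(small_grid.shape, hu))
        assert np.allclose(rv.hu_to_density(ct, model).data, expected)

    def test_non_monotone_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            rv.AttenuationModel(hu_to_density_segments=((0.0, 1.0), (0.0, 2.0)))

    def test_nonfinite_ct_rejected(self, small_grid):
        ct = small_grid.copy(data=np.full(small_grid.shape, np.inf))
        with pytest.raises(ValueError):
            rv.hu_to_density(ct)


class TestDensityToAttenuation:
    def test_zero_density_zero_mu(self, small_grid):
        out = rv.density_to_attenuation(small_grid.copy(data=np.zeros(small_grid.shape)))
        assert np.all(out.data == 0.0)

    def test_uniform_water(self, small_grid):
        model = rv.AttenuationModel()
        dens = small_grid.copy(data=np.ones(small_grid.shape))
        out = rv.density_to_attenuation(dens, model)
        assert np.allclose(out.data, model.mass_attenuation["soft_tissue"])

    def test_two_material_slab(self, small_grid):
        model = rv.AttenuationModel()
        data = np.ones(small_grid.shape)
        data[:, :12, :] = 1.5  # above the bone threshold
        out = rv.density_to_attenuation(small_grid.copy(data=data), model)
        vals = np.unique(out.data)
        assert len(vals) == 2
        assert np.isclose(vals[0], 1.0 * model.mass_attenuation["soft_tissue"])
        assert np.isclose(vals[1], 1.5 * model.mass_attenuation["bone"])


class TestPsfKernel:
    @pytest.mark.parametrize("distance", [0.0, 50.0, 250.0, 400.0])
    def test_kernel_sums_to_one(self, distance):
        k = rv.psf_kernel(distance, rv.ResolutionModel(), (4.42, 4.42))
        assert k.min() >= 0
        assert np.isclose(k.sum(), 1.0, atol=1e-12)

    def test_fwhm_at_zero_distance(self):
        m = rv.ResolutionModel(hole_diameter=3.0, intrinsic_fwhm=3.8)
        assert np.isclose(m.fwhm(0.0), np.hypot(3.8, 3.0))

    def test_discrete_fwhm_matches_analytic_at_250mm(self):
        m = rv.ResolutionModel()
        k = rv.psf_kernel(250.0, m, (4.42, 4.42))
        # sigma from second moment of the discrete kernel
        n = k.shape[0]
        x = (np.arange(n) - (n - 1) / 2) * 4.42
        marg = k.sum(axis=1)
        sigma = np.sqrt(np.sum(marg * x**2))
        measured_fwhm = sigma * 2 * np.sqrt(2 * np.log(2))
        assert abs(measured_fwhm - m.fwhm(250.0)) / m.fwhm(250.0) < 0.05

    def test_fwhm_monotone_in_distance(self):
        m = rv.ResolutionModel()
        d = np.linspace(0, 500, 60)
        f = np.array([m.fwhm(x) for x in d])
        assert np.all(np.diff(f) >= 0)

    def test_invalid_hole_length_rejected(self):
        with pytest.raises(ValueError):
            rv.ResolutionModel(effective_hole_length=0.0)

    def test_disabled_model_identity_kernel(self):
        k = rv.psf_kernel(100.0, rv.ResolutionModel(enabled=False), (4.42, 4.42))
        assert k.shape == (1, 1) and k[0, 0] == 1.0


class TestScatterSource:
    def test_disabled_gives_zero(self, small_grid, rng):
        act = small_grid.copy(data=rng.uniform(0, 1, small_grid.shape))
        eff, w = rv.scatter_source(act, rv.ScatterModel(enabled=False))
        assert np.all(eff.data == 0.0)
        assert w is None

    def test_point_source_reproduces_kernel(self, small_grid):
        model = rv.ScatterModel(amplitude=0.4, decay_length=15.0)
        data = np.zeros(small_grid.shape)
        data[12, 12, 12] = 2.0
        eff, _ = rv.scatter_source(small_grid.copy(data=data), model)
        k = model.kernel_for(small_grid.voxel_size)
        peak = eff.data[12, 12, 12]
        assert np.isclose(peak, 0.4 * 2.0 * k.max(), rtol=1e-6)

    def test_mass_conservation_away_from_edges(self):
        grid = rv.VolumeGrid(np.zeros((40, 40, 40)), (4.42, 4.42, 4.42))
        model = rv.ScatterModel(amplitude=0.3, decay_length=6.0)
        data = np.zeros(grid.shape)
        data[17:23, 17:23, 17:23] = 1.0  # well inside: kernel reach ~6 voxels
        eff, _ = rv.scatter_source(grid.copy(data=data), model)
        assert np.isclose(eff.data.sum(), 0.3 * data.sum(), rtol=1e-3)

    def test_mean_energy_mode_returns_weight(self, small_grid):
        model = rv.ScatterModel(mean_scatter_energy_mode=True, scatter_energy_mu_scale=1.2)
        act = small_grid.copy(data=np.ones(small_grid.shape))
        _, w = rv.scatter_source(act, model)
        assert w is not None and np.all(w.data == 1.2)


def _projector(grid, mu=None, geom=None, res=None, scat=None, cal=1.0):
    geom = geom or rv.AcquisitionGeometry.circular(
        n_views=12, orbit_radius=80.0, pixel_size=(4.42, 4.42),
        detector_shape=(grid.shape[0], grid.shape[2]), time_per_view=45.0,
    )
    return rv.SpectProjector(grid, mu, geom, res, scat, cal), geom


class TestForwardProject:
    def test_single_voxel_count_conservation(self, small_grid):
        src = np.zeros(small_grid.shape)
        src[12, 12, 12] = 2.5
        proj, geom = _projector(small_grid, cal=3.0)
        counts = proj.forward(src, frames=[0])
        expected = 2.5 * small_grid.voxel_volume_ml * geom.time_per_view * 3.0
        assert abs(counts.sum() - expected) / expected < 0.005

    def test_beer_lambert_slab(self, small_grid):
        """A uniform mu slab between source and detector attenuates by exp(-mu L)."""
        src = np.zeros(small_grid.shape)
        src[12, 8, 12] = 1.0
        mu_val = 0.15  # cm^-1
        slab = np.zeros(small_grid.shape)
        slab[:, 14:18, :] = mu_val  # 4 planes between source (y=8) and detector (+y)
        mu = small_grid.copy(data=slab)
        geom = rv.AcquisitionGeometry.circular(
            n_views=1, orbit_radius=80.0, pixel_size=(4.42, 4.42),
            detector_shape=(24, 24), time_per_view=1.0,
        )
        p_free = rv.SpectProjector(small_grid, None, geom)
        p_att = rv.SpectProjector(small_grid, mu, geom)
        free = p_free.forward(src, frames=[0]).sum()
        att = p_att.forward(src, frames=[0]).sum()
        # independent ray trace: path crosses 4 slab planes of 4.42 mm
        expected = np.exp(-mu_val * 4 * 0.442)
        assert np.isclose(att / free, expected, rtol=1e-10)

    def test_linearity_in_source_with_scatter(self, small_grid, rng):
        scat = rv.ScatterModel(amplitude=0.3, decay_length=15.0)
        proj, _ = _projector(small_grid, res=rv.ResolutionModel(), scat=scat)
        x1 = rng.uniform(0, 1, small_grid.shape)
        x2 = rng.uniform(0, 1, small_grid.shape)
        lhs = proj.forward(2.0 * x1 + 3.0 * x2)
        rhs = 2.0 * proj.forward(x1) + 3.0 * proj.forward(x2)
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-9)

    def test_negative_mu_rejected(self, small_grid):
        mu = small_grid.copy(data=np.full(small_grid.shape, -0.1))
        with pytest.raises(ValueError):
            _projector(small_grid, mu=mu)

    def test_shape_mismatch_rejected(self, small_grid):
        proj, _ = _projector(small_grid)
        with pytest.raises(ValueError):
            proj.forward(np.zeros((8, 8, 8)))


@pytest.mark.parametrize("use_mu", [False, True])
@pytest.mark.parametrize("use_psf", [False, True])
@pytest.mark.parametrize("multibed", [False, True])
def test_adjointness_all_toggles(small_grid, rng, use_mu, use_psf, multibed):
    """<Ax, y> == <x, A^T y> for every configuration of the projector pair."""
    beds = (0.0, 3 * 4.42) if multibed else (0.0,)
    nv = 16 if multibed else 24
    geom = rv.AcquisitionGeometry.circular(
        n_views=8, orbit_radius=80.0, pixel_size=(4.42, 4.42),
        detector_shape=(24, nv), time_per_view=45.0, bed_axial_offsets=beds,
    )
    mu = small_grid.copy(data=rng.uniform(0, 0.02, small_grid.shape)) if use_mu else None
    res = rv.ResolutionModel() if use_psf else None
    p = rv.SpectProjector(small_grid, mu, geom, res, None, calibration=2.0)
    x = rng.uniform(0, 1, small_grid.shape)
    y = rng.uniform(0, 1, (geom.n_frames, 24, nv))
    lhs = np.sum(p.forward(x, include_scatter=False) * y)
    rhs = np.sum(x * p.back(y))
    assert abs(lhs - rhs) / abs(lhs) < 1e-10


def test_adjointness_with_detector_mask(small_grid, rng):
    mask = np.ones((24, 24), dtype=bool)
    mask[:4, :] = False
    mask[:, :3] = False
    geom = rv.AcquisitionGeometry.circular(
        n_views=6, orbit_radius=80.0, pixel_size=(4.42, 4.42),
        detector_shape=(24, 24), time_per_view=45.0, detector_mask=mask,
    )
    p = rv.SpectProjector(small_grid, None, geom, rv.ResolutionModel())
    x = rng.uniform(0, 1, small_grid.shape)
    y = rng.uniform(0, 1, (6, 24, 24))
    lhs = np.sum(p.forward(x) * y)
    rhs = np.sum(x * p.back(y))
    assert abs(lhs - rhs) / abs(lhs) < 1e-10
    assert np.all(p.forward(x)[:, ~mask] == 0.0)


class TestBackProject:
    def test_zero_projections_zero_accumulation(self, small_grid):
        proj, geom = _projector(small_grid)
        out = proj.back(np.zeros((geom.n_frames, 24, 24)))
        assert np.all(out == 0.0)

    def test_uniform_backprojection_rotationally_symmetric(self):
        """mu=0, PSF off, 60 views: accumulation is rotation-invariant up to
        the high-frequency splat texture of the exact-adjoint rotation.

        The radially averaged profile is flat to 2%; the point-wise
        interpolation texture of the adjoint (splatting) rotation stays
        below 8%.
        """
        grid = rv.VolumeGrid(np.zeros((32, 32, 8)), (4.42, 4.42, 4.42))
        geom = rv.AcquisitionGeometry.circular(
            n_views=60, orbit_radius=100.0, pixel_size=(4.42, 4.42),
            detector_shape=(32, 8), time_per_view=1.0,
        )
        p = rv.SpectProjector(grid, None, geom)
        acc = p.back(np.ones((60, 32, 8)))[:, :, 4]
        c = (32 - 1) / 2
        ii, jj = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        r = np.hypot(ii - c, jj - c)
        inside = r < 0.8 * (32 / 2)
        vals = acc[inside]
        assert (vals.max() - vals.min()) / vals.mean() < 0.08
        # radial mean profile is flat (2-voxel annuli, populated bins only)
        bins = (r[inside] / 2.0).astype(int)
        profile = np.bincount(bins, weights=vals) / np.bincount(bins)
        assert (profile.max() - profile.min()) / profile.mean() < 0.02


def test_projection_io_round_trip(tmp_path, small_grid, rng):
    geom = rv.AcquisitionGeometry.circular(
        n_views=4, orbit_radius=80.0, pixel_size=(4.42, 4.42),
        detector_shape=(24, 24), time_per_view=45.0, bed_axial_offsets=(0.0, 8.84),
    )
    counts = rng.uniform(0, 100, (geom.n_frames, 24, 24))
    ps = rv.ProjectionSet(counts=counts, geometry=geom, is_noisy=True)
    rv.save_projections(ps, str(tmp_path / "p.nii.gz"), str(tmp_path / "p.json"))
    back = rv.load_projections(str(tmp_path / "p.nii.gz"), str(tmp_path / "p.json"))
    assert np.array_equal(back.counts, ps.counts)
    assert back.is_noisy
    assert np.array_equal(back.geometry.angles, geom.angles)
    assert back.geometry.bed_axial_offsets == geom.bed_axial_offsets


def test_forward_project_wrapper_matches_projector(small_grid, rng):
    src = small_grid.copy(data=rng.uniform(0, 1, small_grid.shape))
    geom = rv.AcquisitionGeometry.circular(
        n_views=4, orbit_radius=80.0, pixel_size=(4.42, 4.42),
        detector_shape=(24, 24), time_per_view=45.0,
    )
    ps = rv.forward_project(src, None, geom, None, None, calibration=1.5)
    p = rv.SpectProjector(small_grid, None, geom, None, None, calibration=1.5)
    assert np.array_equal(ps.counts, p.forward(src.data))


def test_gaussian_kernel_truncation_and_normalization():
    k = _gaussian_kernel_1d(2.0, truncation=4.0)
    assert len(k) == 2 * 8 + 1
    assert np.isclose(k.sum(), 1.0, atol=1e-15)
    assert np.array_equal(k, k[::-1])
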