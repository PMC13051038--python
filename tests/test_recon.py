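"""OS-EM engine: update arithmetic, calibration, bootstrap reconstruction."""

import numpy as np
import pytest

import rvspect as rv
from rvspect.recon import osem_system_matrix, poisson_log_likelihood


class TestSystemMatrixEM:
    def test_two_by_two_update_matches_hand_arithmetic(self):
        """One MLEM update from uniform init equals the brute-force EM step."""
        A = np.array([[0.7, 0.2], [0.3, 0.8]])
        y = np.array([2.0, 3.0])
        x0 = np.array([1.0, 1.0])
        out = osem_system_matrix(A, y, x0, n_iterations=1)
        # brute-force EM arithmetic, written out explicitly
        yhat = A @ x0
        expected = x0 * (A.T @ (y / yhat)) / A.sum(axis=0)
        np.testing.assert_allclose(out, expected, rtol=0, atol=0)

    def test_fixed_point_at_exact_solution(self):
        A = np.array([[0.6, 0.1], [0.2, 0.7], [0.2, 0.2]])
        x_true = np.array([3.0, 5.0])
        y = A @ x_true
        out = osem_system_matrix(A, y, x_true.copy(), n_iterations=10)
        np.testing.assert_allclose(out, x_true, rtol=1e-12)

    def test_subsets_converge_to_same_solution(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0.1, 1.0, (8, 3))
        x_true = np.array([1.0, 4.0, 2.0])
        y = A @ x_true
        full = osem_system_matrix(A, y, np.ones(3), n_iterations=400)
        sub = osem_system_matrix(A, y, np.ones(3), n_iterations=100, n_subsets=2)
        np.testing.assert_allclose(full, x_true, rtol=1e-3)
        np.testing.assert_allclose(sub, x_true, rtol=1e-3)

    def test_additive_scatter_term_respected(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = np.array([0.5, 0.5])
        x_true = np.array([2.0, 3.0])
        y = A @ x_true + s
        out = osem_system_matrix(A, y, np.ones(2), n_iterations=200, scatter=s)
        np.testing.assert_allclose(out, x_true, rtol=1e-6)


class TestOsemProjector:
    def test_mlem_likelihood_nondecreasing(self, tiny_organ_study):
        study = tiny_organ_study
        parent = study.parent_projections()
        mu = study.mu_emulated()
        projector = rv.SpectProjector(
            study.source_model().emulated_grid(), mu, study.geometry,
            study.resolution, None, study.calibration,
        )
        lls = []
        cfg = rv.ReconConfig(n_iterations=1, n_subsets=1, convergence_log=False)
        template = study.cuv_template()
        x = None
        for _ in range(12):
            model, _ = rv.osem(
                parent, mu, study.geometry, study.resolution, None, template, cfg,
                calibration=study.calibration, initial=x,
            )
            x = model.internal.data
            lls.append(poisson_log_likelihood(parent.counts, projector.forward(x)))
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-7 * np.abs(np.array(lls[:-1])))

    def test_determinism(self, tiny_organ_study):
        study = tiny_organ_study
        parent = study.parent_projections()
        cfg = rv.ReconConfig(n_iterations=2, n_subsets=5)
        args = (parent, study.mu_emulated(), study.geometry, study.resolution,
                study.scatter, study.rv_template(), cfg)
        m1, l1 = rv.osem(*args, calibration=study.calibration)
        m2, l2 = rv.osem(*args, calibration=study.calibration)
        assert np.array_equal(m1.internal.data, m2.internal.data)
        assert l1[-1].concentrations == l2[-1].concentrations

    def test_rv_internal_stays_region_constant(self, tiny_organ_study):
        study = tiny_organ_study
        parent = study.parent_projections()
        model, _ = rv.osem(
            parent, study.mu_emulated(), study.geometry, study.resolution, None,
            study.rv_template(), rv.ReconConfig(n_iterations=2, n_subsets=5),
            calibration=study.calibration,
        )
        labels = study.region_map.labels
        for lab in study.region_map.region_labels():
            assert np.unique(model.internal.data[labels == lab]).size == 1

    def test_all_zero_region_map_degenerates_to_cuv(self, tiny_organ_study):
        """Mixed mode with an empty map reproduces plain cuboid OS-EM exactly."""
        study = tiny_organ_study
        parent = study.parent_projections()
        cfg = rv.ReconConfig(n_iterations=2, n_subsets=5, convergence_log=False)
        cuv, _ = rv.osem(
            parent, study.mu_emulated(), study.geometry, study.resolution, None,
            study.cuv_template(), cfg, calibration=study.calibration,
        )
        zero_map = rv.RegionMap(
            labels=np.zeros(study.activity.shape, dtype=np.int32),
            voxel_size=study.activity.voxel_size,
        )
        mixed_template = rv.SourceModel(
            internal=study.activity.copy(data=np.ones(study.activity.shape)),
            region_map=zero_map,
            emulated_factor=study.emulated_factor,
        )
        mixed, _ = rv.osem(
            parent, study.mu_emulated(), study.geometry, study.resolution, None,
            mixed_template, cfg, calibration=study.calibration,
        )
        mixed_emu = mixed.emulated_grid().data
        np.testing.assert_array_equal(mixed_emu, cuv.internal.data)

    def test_converged_solution_reproduces_data_totals(self, tiny_organ_study):
        study = tiny_organ_study
        parent = study.parent_projections()
        model, _ = rv.osem(
            parent, study.mu_emulated(), study.geometry, study.resolution, None,
            study.cuv_template(), rv.ReconConfig(n_iterations=20, n_subsets=10,
                                                 convergence_log=False),
            calibration=study.calibration,
        )
        p = rv.SpectProjector(
            model.emulated_grid(), study.mu_emulated(), study.geometry,
            study.resolution, None, study.calibration,
        )
        reproj = p.forward(model.internal.data).sum()
        assert abs(reproj - parent.total_counts) / parent.total_counts < 0.01

    def test_estimates_nonnegative(self, tiny_organ_study):
        study = tiny_organ_study
        noisy = rv.add_poisson_noise(study.parent_projections(), seed=3)
        model, _ = rv.osem(
            noisy, study.mu_emulated(), study.geometry, study.resolution, None,
            study.rv_template(), rv.ReconConfig(n_iterations=2, n_subsets=5),
            calibration=study.calibration,
        )
        assert np.all(model.internal.data >= 0)


class TestCalibrate:
    def _uniform_recon(self):
        data = np.full((16, 16, 16), 3.2)
        return rv.VolumeGrid(data, (4.42, 4.42, 4.42))

    def test_circularity(self):
        recon = self._uniform_recon()
        voi = np.zeros(recon.shape, dtype=bool)
        voi[4:12, 4:12, 4:12] = True
        cal = rv.calibrate(recon, voi, true_concentration=1.6)
        assert np.isclose(recon.data[voi].mean() / cal.value, 1.6)

    def test_linear_in_acquisition_time(self, tiny_organ_study):
        """Doubling time per view doubles the calibration factor.

        The reconstruction deliberately runs with a unit-time projector, so
        its image stays in count-like units and the factor absorbs the
        acquisition duration, as a physical calibration does.
        """
        study = tiny_organ_study
        voi = study.region_map.labels == 1
        geom_recon = rv.AcquisitionGeometry.circular(
            n_views=study.geometry.n_views,
            orbit_radius=float(study.geometry.orbit_radius[0]),
            pixel_size=study.geometry.pixel_size,
            detector_shape=study.geometry.detector_shape,
            time_per_view=1.0,
        )
        factors = []
        for t_scale in (1.0, 2.0):
            geom = rv.AcquisitionGeometry.circular(
                n_views=study.geometry.n_views,
                orbit_radius=float(study.geometry.orbit_radius[0]),
                pixel_size=study.geometry.pixel_size,
                detector_shape=study.geometry.detector_shape,
                time_per_view=study.geometry.time_per_view * t_scale,
            )
            src = study.source_model()
            proj = rv.forward_project(src, study.mu_emulated(), geom,
                                      study.resolution, None, study.calibration)
            proj = rv.ProjectionSet(counts=proj.counts, geometry=geom_recon)
            model, _ = rv.osem(
                proj, study.mu_emulated(), geom_recon, study.resolution, None,
                study.cuv_template(),
                rv.ReconConfig(n_iterations=3, n_subsets=5, convergence_log=False),
                calibration=1.0,  # uncalibrated units
            )
            truth = study.truth_concentrations()[1]
            factors.append(rv.calibrate(model.internal, voi, truth).value)
        assert np.isclose(factors[1] / factors[0], 2.0, rtol=0.01)

    def test_empty_voi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rv.calibrate(self._uniform_recon(), np.zeros((16, 16, 16), bool), 1.0)


class TestReconstructBootstrap:
    def test_identical_realizations_zero_sd(self, tiny_organ_study):
        study = tiny_organ_study
        parent = rv.add_poisson_noise(study.parent_projections(), seed=2)
        boot = rv.bootstrap_realizations(parent, n_bins=1, n_realizations=3, seed=4)
        ests = rv.reconstruct_bootstrap(
            boot, study.mu_emulated(), study.geometry, study.resolution, None,
            study.rv_template(), rv.ReconConfig(n_iterations=2, n_subsets=5),
            calibration=study.calibration,
        )
        for lab in ests[0].labels:
            vals = [e.concentration(lab) for e in ests]
            assert all(v == vals[0] for v in vals)

    def test_organ_dispersion_small_and_mean_unbiased(self, tiny_organ_study):
        """Organ-scale regions: SD/mean over realizations stays below 5% and
        the bootstrap mean sits near the noise-free estimate."""
        study = tiny_organ_study
        parent = rv.add_poisson_noise(study.parent_projections(), seed=11)
        boot = rv.bootstrap_realizations(parent, n_bins=30, n_realizations=12, seed=12)
        cfg = rv.ReconConfig(n_iterations=4, n_subsets=10)
        ests = rv.reconstruct_bootstrap(
            boot, study.mu_emulated(), study.geometry, study.resolution, None,
            study.rv_template(), cfg, calibration=study.calibration,
        )
        parent_model, _ = rv.osem(
            parent, study.mu_emulated(), study.geometry,
            study.resolution, None, study.rv_template(), cfg,
            calibration=study.calibration,
        )
        parent_est = rv.extract_estimates(parent_model, 4).as_dict()
        noise_free, _ = rv.osem(
            study.parent_projections(), study.mu_emulated(), study.geometry,
            study.resolution, None, study.rv_template(), cfg,
            calibration=study.calibration,
        )
        nf = rv.extract_estimates(noise_free, 4).as_dict()
        for lab in (2, 3, 4):  # kidneys, spleen
            vals = np.array([e.concentration(lab) for e in ests])
            assert vals.std() / vals.mean() < 0.05
            # the bootstrap resamples the parent acquisition, so its mean
            # tracks the parent estimate; the noise-free estimate differs
            # by the parent's own quantum noise (a few percent here)
            sem = vals.std() / np.sqrt(len(vals))
            assert abs(vals.mean() - parent_est[lab]) < max(3 * sem, 0.01 * parent_est[lab])
            assert abs(vals.mean() - nf[lab]) / nf[lab] < 0.05
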