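# rvspect

Quantitative SPECT activity-concentration estimation with **regional
voxels**, for radionuclide-therapy dosimetry (e.g. ¹⁷⁷Lu peptide receptor
radionuclide therapy).

## The problem

Absorbed-dose calculations in radionuclide therapy need accurate mean
activity concentrations (MBq/mL) in organs and tumors, estimated from
SPECT projections. The limited spatial resolution of gamma cameras causes
the *partial-volume effect* (PVE): regional means read from reconstructed
images are biased, severely so for small structures. The standard remedy
is post-reconstruction partial-volume correction (PVC) with recovery
coefficients (RCs) measured on sphere phantoms — a first-order fix that
cannot capture organ shape or the nonlinear, geometry-dependent
convergence of iterative reconstruction.

`rvspect` implements an alternative: describe the source distribution not
as cuboid voxels (cu.v.) but as **regional voxels** (r.v.) — basis
functions equal to anatomical regions from a segmentation — and estimate
one concentration per region *directly from the projections* with OS-EM.
Because the regional uniformity assumption enters the estimation itself,
no post-hoc PVC is needed. Both representations share a single
rotation-based projector with attenuation, distance-dependent
collimator-detector response, and effective-scatter-source modeling, so
the two approaches can be compared like for like. Everything runs on
synthetic digital phantoms generated in-package; no patient data is
required.

## The model

Projections follow the Poisson count model `y ~ Poisson(A x + s)` where
`A` is the attenuated, resolution-modeled projector, `s` a forward-
projected effective scatter term, and `x` the source. OS-EM applies the
multiplicative update

```
x ← x · Aᵀ( y / (A x + s) ) / Aᵀ1
```

subset by subset. For regional voxels, both the back-projected ratio
`Aᵀ(y/ŷ)` and the sensitivity `Aᵀ1` are averaged within each region
*before* taking their quotient — the maximum-likelihood update for region
basis functions, whose fixed point on self-consistent data is the true
regional concentration. The source carries two resolutions in parallel: a
fine *internal* grid (default 1.105 × 1.105 × 4.42 mm³) that conforms to
the region map, and a coarser *emulated* grid (integer multiple, default
4.42 mm³) that the projector sees; block averaging down and voxel
partitioning up conserve total activity exactly.

For the cuboid-voxel route, recovery coefficients are parameterized by
the volume-to-surface ratio η = V/S and iteration count n,

```
RC(η, n) = 1 / (1 + αₙ η^(−βₙ))
```

fitted by nonlinear least squares to sphere-phantom measurements, and the
spill-in-corrected concentration is

```
C_pvc = ( C_img − C_bkg (1 − RC) ) / RC
```

with `C_bkg` from a shell VOI built by successive dilations of the object
VOI. Evaluation uses the relative difference δ = 2(C_a − C_b)/(C_a + C_b)
and the relative error ε = C_est/C_ref − 1.

## Worked example

Simulate a six-sphere NEMA-like body phantom (sphere volumes 1.2–113.1 mL,
hot spheres at 0.8 MBq/mL over a 0.08 MBq/mL background), fit a recovery
curve, and compare the three estimators over Poisson noise realizations:

```python
import rvspect as rv

study = rv.nema_study(matrix_shape=(48, 48, 32), n_views=30)
rv_cfg = rv.ReconConfig(n_iterations=8, n_subsets=10)
cuv_cfg = rv.ReconConfig(n_iterations=20, n_subsets=10)
curve = rv.derive_recovery_curve(study, cuv_cfg)
print(f"RC(eta) fit: alpha={curve.alpha:.3f}, beta={curve.beta:.3f}")
report = rv.compare_methods_report(
    study, seeds=[1, 2, 3], rv_config=rv_cfg, cuv_config=cuv_cfg,
    recovery_curve=curve,
)
summary = rv.summarize(report)
cols = ["name", "method", "concentration_mean", "concentration_std", "epsilon_mean"]
print(summary[cols].round(4).to_string(index=False))
```

which prints (truth is 0.8 MBq/mL in every sphere):

```
RC(eta) fit: alpha=2.715, beta=1.540
          name  method  concentration_mean  concentration_std  epsilon_mean
  sphere_1.2mL cuv_pvc              0.7516             0.0533       -0.0605
  sphere_1.2mL cuv_raw              0.6265             0.0429       -0.2168
  sphere_1.2mL      rv              0.8216             0.0305        0.0270
  ...
sphere_113.1mL cuv_pvc              0.7961             0.0009       -0.0049
sphere_113.1mL cuv_raw              0.7468             0.0007       -0.0665
sphere_113.1mL      rv              0.7986             0.0023       -0.0018
```

Uncorrected cuboid voxels underestimate the 1.2 mL sphere by ~22%;
recovery-coefficient PVC recovers most of it; regional voxels sit within
a few percent of truth at every size, with comparable dispersion.

The same pipeline is scriptable from the shell:

```bash
rvspect phantom nema --out phantom/
rvspect evaluate --seed 1 --n-realizations 10 --out report.csv
rvspect misalign --seed 1 --axis x --out sweep.csv
```

## Layout

- `rvspect.volume` – `VolumeGrid` container, NIfTI I/O
- `rvspect.fixtures` – digital phantoms, Poisson noise, list-mode-style bootstrap
- `rvspect.system_model` – attenuation, PSF, scatter, matched rotation-based projector pair
- `rvspect.source_repr` – region maps, dual-resolution source models, activity-conserving resampling
- `rvspect.recon` – OS-EM engine (cu.v./r.v./mixed), calibration, bootstrap reconstruction
- `rvspect.pvc` – η estimation, RC-curve fitting, background VOIs, spill-in correction
- `rvspect.evalcli` – δ/ε metrics, method-comparison and misalignment experiments
- `rvspect.cli` – `rvspect` command-line umbrella

See `docs/methods.md` for modeling assumptions, defaults, and limitations,
and `docs/phantom_spec_example.yaml` for the phantom description schema.
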