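# petscatter

Scatter correction and quantification toolkit for 2D-rebinned brain PET,
built around synthetic phantoms with known scatter ground truth.

## The problem

Modern PET scanners acquire in 3D mode, where a third or more of recorded
coincidences are Compton-scattered and must be removed before the data are
quantitative. Validating a scatter correction on patient data is hard
because the scatter-free answer is never known. This package implements a
complete, testable version of that validation problem:

* **DEC** — deconvolution (convolution-subtraction) scatter correction.
  The scatter in the standard energy window (SEW) is estimated by
  convolving each view's radial × axial projection plane with an empirical
  low-pass kernel in the spatial frequency domain,

  ```
  S(f) = 1 / (1 + α · exp(β |f|²)),     f in cycles/cm, β in cm²
  ```

  and subtracted. `α` sets the amplitude (the DC gain `1/(1+α)` is the
  fraction of counts attributed to scatter) and `β` the width of the
  scatter tails. The parameters are calibrated per object size by matching
  the predicted scatter to the *tails* of measured uniform-phantom
  sinograms — the bins outside the object's projected support, which
  contain scatter only — and tabulated against the attenuating object
  volume segmented from the transmission image (μ > 0.06 cm⁻¹).

* **HDE** — hybrid dual-energy-window correction, the reference method:
  the upper energy window (UEW, 512–624 keV) sees little scatter, so its
  own scatter is DEC-correctable; the remaining UEW trues, scaled by the
  windows' true-efficiency ratio R, predict the SEW trues, and
  `scatter = SEW − R·(UEW − DEC_scatter(UEW))`.

* A parallel-beam projector/FBP pair with attenuation correction
  (ACF = exp(∫μ dl) per line of response) and a 6 mm FWHM Gaussian
  post-filter.

* ¹⁵O quantification: autoradiographic CBF (one-compartment Kety model,
  monotone table inversion), CBV from the C¹⁵O ratio method, OEF/CMRO₂
  from a simplified ¹⁵O₂ model linear in OEF.

* The comparison statistics used to judge agreement between two correction
  routes: GM/WM slice-wise percent-difference profiles, bilateral ROI
  means with left-to-right ratios, patient-averaged absolute-difference
  tables, ICC(2,1) (two-way random effects, absolute agreement), and
  geometric mean regression.

* A synthetic-data module that generates brain-like and uniform phantoms,
  attenuated line-integral trues, ground-truth scatter in two energy
  windows, out-of-FOV background, and Poisson noise — so every stage above
  can be validated against a known answer, including an algebraically
  exact mode (`dec_self_consistent`) in which prompts satisfy the DEC
  fixed point `p = t/(1−S)` and the correction must recover the trues to
  machine precision.

## Worked example

Calibrate the kernel on a uniform cylinder and correct its own sinogram
(exact by construction in the self-consistent world):

```python
import numpy as np
import petscatter as ps

geom = ps.ScannerGeometry(n_views=24, n_radial=128, radial_bin_cm=0.2,
                          n_slices=24, slice_thickness_cm=0.26, fov_radius_cm=12.8)
act, mu, labels = ps.uniform_cylinder(geom, diameter_cm=15.0,
                                      activity_kbq_ml=10.0, length_cm=4.0)
trues = ps.forward_project(act, geom, mu)
cfg = ps.ScatterModelConfig(mode="dec_self_consistent",
                            kernel_params=ps.KernelParams(0.35, 3.0))
scatter = ps.simulate_scatter(trues, mu, cfg)
prompts = trues.with_counts(trues.counts + scatter.counts, label="SEW")
print(f"scatter fraction: {scatter.total / prompts.total:.3f}")

mask = ps.tail_mask(mu, geom)
fit, diag = ps.fit_kernel_params(prompts, mask, template=trues, mode="circular")
print(f"fitted kernel: alpha={fit.alpha:.4f}, beta={fit.beta_cm2:.4f} cm^2")

corrected, estimate = ps.dec_correct(prompts, fit, mode="circular", clamp=False)
err = np.abs(corrected.counts - trues.counts).max() / trues.counts.max()
print(f"max relative error of corrected vs true sinogram: {err:.2e}")
```

prints

```
scatter fraction: 0.741
fitted kernel: alpha=0.3500, beta=3.0000 cm^2
max relative error of corrected vs true sinogram: 2.45e-11
```

The fitted `(α, β)` match the injected kernel to four decimals, and the
corrected sinogram reproduces the true (unscattered) one to ~1e-11: in
this world the tail-matching calibration and the convolution-subtraction
are exact, which is the baseline every realistic configuration is judged
against. Attenuation-correcting and reconstructing the corrected sinogram
returns the cylinder's 10.00 kBq/ml core activity to the printed
precision.

The full study procedure — simulate a multi-subject cohort of brain
phantoms with three tracer scans each, calibrate, correct with both
methods, reconstruct, quantify, and compare — is one call:

```python
from petscatter.experiment import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(n_subjects=10, seed=0), out_dir="report/")
```

`report["abs_diff"]` holds the per-parameter absolute-difference tables
(DEC vs HDE, patient-averaged, with a Total row), `report["icc"]` the
ICC(2,1) values, and `report["slice_profiles"]` the per-slice GM/WM
percent-difference curves.

There is also a CLI (`petscatter sim | calibrate | correct-dec |
correct-hde | recon | quant | run-experiment`) operating on HDF5
sinograms, NIfTI volumes and CSV calibration tables.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the end-to-end cohort experiment (simulation → calibration → both
corrections → reconstruction → quantification → comparison report) from
scratch, writes the comparison report under `results/experiment/`, prints
a summary, and writes the results JSON to the requested path.
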