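# Methods

This note documents the models, estimators, numerical choices and known
limitations of `petscatter`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Acquisition model

Sinograms are stacks of 2D parallel-beam projections indexed
(view, radial, slice), the form produced by Fourier rebinning of 3D brain
PET data; rebinning itself is upstream and out of scope. Line integrals
are computed per slice with `skimage.transform.radon` (bilinear warping)
scaled by the radial bin size, so sinogram values are physical line
integrals (kBq/ml · cm). PET attenuation multiplies the whole
line-of-response integral by `exp(−∫μ dl)`; attenuation correction factors
are the reciprocal. The image grid is tied to the sinogram sampling
(pixel = radial bin, rotation centre at pixel `n//2`), making the
projector and `skimage.transform.iradon` an exactly matched pair: a
noiseless scatter-free cylinder reconstructs with well under 2% interior
bias (asserted in the tests).

Default geometry mimics a 59-slice brain scanner (2.6 mm slices, 2 mm
transaxial sampling); every stage is resolution-agnostic, and the
end-to-end harness runs on a coarser 64×64 × 16-slice grid so a
10-subject cohort completes in about a minute on one CPU.

## Scatter kernel

The empirical scatter kernel is a low-pass frequency response on each
view's radial × axial plane:

    S(f) = 1 / (1 + α exp(β |f|²))

with `f` the Euclidean 2D spatial frequency in cycles/cm. Frequencies are
computed from the physical bin spacings, so β is in cm² and a fitted
parameter pair transfers across sinogram sizes and anisotropic sampling
(0.2 cm radial vs 0.26 cm axial by default). `S(0) = 1/(1+α)` is the
fraction of total counts attributed to scatter. Convolution is applied by
FFT; the default `zeropad` mode pads each axis to ≥ 2× before
transforming so scatter tails cannot wrap around the FOV edge, while
`circular` mode is exact for the algebraic test world and obeys
`sum(out) = S(0)·sum(in)` identically. Since `0 < S ≤ 1/(1+α) < 1`, the
fixed-point factor `1/(1−S)` used below is always finite.

## Synthetic scatter: two worlds

`broad_gaussian` (default): scatter is a broad per-view Gaussian blur
(8 cm radial / 6 cm axial FWHM by default) of the attenuation-weighted
trues, renormalised so scattered/(scattered+true) equals the configured
scatter fraction (0.35 SEW / 0.10 UEW by default — typical 3D-mode brain
values). This shape deliberately does **not** follow the kernel's
functional form, so corrections face model mismatch the way they do
physically. An optional axial ramp adds out-of-FOV background.

`dec_self_consistent`: per view, prompts solve `p = t + k ⊛ p` in
frequency space, `P = T/(1−S)`. DEC with the true (α, β) in circular mode
then recovers the trues exactly, giving machine-precision oracles for the
correction, the calibration, and the hybrid reference. Two caveats are
inherent to this construction: (i) the FFT fixed point rings slightly
negative (~1e-4 of the scatter maximum) at the projected support edge —
clipping would destroy the exactness the mode exists for, so the signed
values are kept and counts are clipped at zero only when Poisson sampling;
(ii) with a window true-efficiency `e`, the window's prompts are generated
as `e·t/(1−S)` (the fixed point is linear in the trues), not as
`e·t + scatter-from-unscaled-trues`, which would not be a fixed point.

With α = 0.35 the self-consistent world has a DC scatter-to-prompts ratio
of 0.74 — deliberately extreme; it is an algebraic stress test, not a
physiological scenario.

## Tail-matching calibration

The tail of a calibration-phantom sinogram (bins whose μ line integral is
below 1e-3, at least 2 radial bins away from any support bin) contains
scatter only. A naive least-squares match of `k ⊛ p` against `p` over the
tail is **degenerate**: a near-identity kernel (α at its lower bound,
small β) reproduces tail counts from themselves and wins on any coarse
parameter grid. The fit therefore predicts the tail through the
generative model rather than from the tail data itself:

* **Template objective** (used for phantom calibration): the trues shape
  of a uniform calibration phantom is known up to amplitude — the
  unit-activity attenuated projection of its μ map. Model prompts are
  `h = template/(1−S)`; the amplitude is fitted linearly on the
  high-count support bins; (α, β) minimise the unweighted squared
  residuals over tail bins only. Noise enters only the regression target,
  so the estimate carries no quadratic noise bias.
* **Self-consistent objective** (no template): trues are estimated as
  `clip(p − k ⊛ p, 0)` restricted to the support and re-predicted through
  `1/(1−S)`. Exact in the noiseless limit; noise-sensitive, because
  support noise propagates through the fixed-point amplification.

Both objectives are exactly zero at the true parameters in the
self-consistent world. The optimiser is deterministic: a 40×40 log-spaced
grid over α ∈ [0.01, 10], β ∈ [0.01, 50] cm², then Nelder-Mead refinement
in log space started from the best six well-separated grid cells (the
truth basin is narrow; a single start can stall in a shallow side basin).
Views are averaged before fitting — exact for any phantom by linearity of
the fixed point, and it suppresses noise by the view count. Optional
Poisson weighting (1/max(counts, 1)) is available but off by default.

Identifiability note: a calibration phantom that fills every slice
provides no axial tails, and α is then weakly identified under noise
(β rides on the radial tail shape; α needs the 2D spread). The default
calibration phantoms are therefore shorter than the axial FOV, which is
also the realistic acquisition. With axial tails present, the tests
recover an injected kernel exactly (noiseless) and to a few percent per
parameter at 1e6 total counts.

Per-phantom fits are tabulated against the object volume from the
segmented μ map (strictly > 0.06 cm⁻¹, voxel count × voxel volume) and
linearly interpolated per parameter, clamping outside the tabulated
range.

## Hybrid dual-energy-window reference

`R` is a global scalar (total SEW trues / total UEW trues from a
scatter-free or DEC-corrected calibration acquisition; ≥ 1 for nested
windows). The SEW scatter estimate is `SEW − R·(UEW − k_UEW ⊛ UEW)` with
a dedicated UEW kernel table, followed by an optional total-preserving
Gaussian smoothing (default 2 cm FWHM; 0 disables it — used in the
exactness tests) and a nonnegativity clamp. In the idealised dual-window
self-consistent world the estimate equals the true SEW scatter to
< 1e-6. Under Poisson noise at physiological scatter fractions the
unsmoothed HDE-corrected sinogram is noisier than the DEC one (UEW noise
scaled by R² dominates), and under scatter-shape mismatch
(broad-Gaussian world) the HDE estimate's integrated absolute error is
smaller than DEC's — the two properties that make it the reference and
the simplified method respectively.

## Reconstruction

Slice-by-slice FBP of (corrected × ACF) via `skimage.transform.iradon`.
Default filter is ramp × Hann at full Nyquist; a sub-Nyquist cutoff uses
a real-space-constructed Ram-Lak filter applied in Fourier space followed
by unfiltered backprojection. The ACF multiplies the sinogram *after*
scatter subtraction (attenuation correction of scatter-corrected data).
The 3D Gaussian post-filter (default 6 mm FWHM) respects anisotropic
voxels and preserves totals with reflective boundaries. The global
calibration scalar defaults to 1.0 because the matched projector/FBP pair
is self-consistent to well under 1%; `ReconConfig.calibration` exposes it
for cross-calibration against a well counter.

## ¹⁵O quantification

All curves are decay-corrected (λ = ln2/122.24 s⁻¹ used only for
conversion); kinetic integrals use a fixed 0.5 s step with an exponential
update that reproduces the constant-input steady state `C_t → p·ρ·C_a`
exactly.

* CBF: one-compartment model `dC_t/dt = (f ρ/6000)·C_a − (f/(6000 p))·C_t`
  (f in ml/100 g/min); accumulated counts over the scan are inverted by
  monotone table lookup (0.5 ml/100 g/min grid to 160; above-table voxels
  are clamped and flagged).
* CBV = 100·C_pet/(ρ·R_sl·C_blood).
* OEF: `A_O2 = OEF·A_w(f) + V_B·∫C_a,O2 dt` with `A_w` the same
  accumulation operator and `V_B = CBV·ρ·R_sl/100`; linear per-voxel
  solve, clipped to [0, 1.5] with flags; CMRO₂ = OEF·CBF·CaO₂.

Constants (p = 0.8 ml/g, ρ = 1.04 g/ml, R_sl = 0.85, CaO₂ = 0.19 ml O₂/ml)
are standard literature values, config-exposed. Recirculating water of
metabolism is deliberately omitted from the O₂ model; the simulator uses
the identical forward model, so round-trip validation (< 0.5% across a
physiological grid) is exact by design, and the package's purpose —
propagating scatter-correction differences into the parametric maps — is
unaffected. The arterial input is a gamma variate
`A·(t−t0)^γ·exp(−(t−t0)/τ)`, delay- and dispersion-free by construction.

## Comparison statistics

GM/WM masks by strict thresholding (> 0.5) of probability maps; slice
profiles as 100·(mean_a − mean_b)/mean_b per slice with NaN for undefined
slices; elliptical (16 × 32 mm) and circular (16 mm) ROIs voxelised by
centre-inclusion, mirrored across the mid-sagittal plane for bilateral
placement, averaged over 3 adjacent slices; left-to-right ratios for
bilateral ROIs only. ICC(2,1) is computed from two-way ANOVA mean squares
(cross-checked against an independent implementation in the tests);
geometric mean regression uses slope = sign(r)·sd(y)/sd(x). The
absolute-difference report averages 100·|a−b|/b over subjects per ROI
with an unweighted Total row.

## End-to-end harness

`run_experiment` simulates a cohort of jittered brain phantoms (nested
ellipsoids: GM shell 4:1 over a WM core, cold CSF rim, 0.151 cm⁻¹ skull
shell; ±5% size and ±8% physiology jitter per subject), three tracer
scans each at 1e7 prompts (typical of ¹⁵O brain acquisitions; `None`
disables noise), calibrates both windows' kernels on two uniform
phantoms, corrects with DEC and HDE, reconstructs, quantifies, and emits
the full comparison report. The synthetic world intentionally contains
scatter-model mismatch, so the two methods genuinely disagree at the
several-percent level; the tested contract is procedural: in the limit of
no noise, self-consistent scatter and known kernels, every difference
cell collapses to zero and all ICCs equal 1 exactly.

What a green suite does and does not establish: it validates the
algebra, the estimators and the procedure on data generated by the
package's own acquisition model. It does not model detector physics
(crystal blur, randoms, dead time), spatially-variant scatter kernels,
patient motion, or real out-of-FOV activity beyond an additive axial
ramp; no clinical value reported elsewhere is reproduced or asserted.

## Known limitations

* The scatter kernel is spatially invariant per view; physical scatter
  varies with position in the FOV.
* The template calibration objective assumes a uniformly filled,
  correctly segmented phantom; fill inhomogeneity or segmentation error
  would bias (α, β).
* The broad-Gaussian scatter world often drives the fitted β to its upper
  bound (50 cm²) because true Gaussian tails are broader than the kernel
  family; the fit diagnostics flag this.
* `dec_self_consistent` mode carries sub-promille negative ringing at
  support edges (see above); containers accept negatives up to 1% of the
  maximum for synthetic data.
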