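# Methods

## Physical model

A susceptibility distribution χ(r) (ppb, relative to the surrounding
medium) perturbs the resonance frequency by the Lorentz-sphere-corrected
dipole convolution, diagonal in Fourier space:

    f(k) = D(k) χ(k),   D(k) = 1/3 − (k·b)² / |k|²,

with b the unit B₀ direction. D is bounded in [−2/3, 1/3] and vanishes on
the magic-angle cone 3cos²ψ = 1. A white-matter specimen with one dominant
fiber axis f is modelled with a cylindrically symmetric tensor
χ̂ = χᵢI + χₐ(ffᵀ − I/3); the anisotropy convention is **χₐ ≡ χ∥ − χ⊥**
(the source text does not fix a convention; this one follows the
susceptibility-anisotropy literature, and all signs in the package are
stated against it). The tensor's field follows
f(k) = (1/3)bᵀχ̂(k)b − (k·b)(kᵀχ̂(k)b)/|k|², which for f ∥ b reduces to
(2/3)·D(k) per unit χₐ — a useful closed-form check.

On top of the susceptibility field, the tissue interior carries a
non-susceptibility compartmental offset A·sin²θ + B (θ = angle between
fiber axis and B₀, folded to [0°, 90°]): A captures the
microstructure-orientation effect, B the orientation-invariant exchange
part. Because this offset cannot propagate outside the tissue, fitting the
field on an agar shell *around* the specimen measures (χᵢ, χₐ) free of
compartmental contamination, and the internal residual mean after
subtracting the fitted susceptibility field isolates A·sin²θ + B.

## Numerical choices

- **k = 0 convention.** The dipole kernel's DC term is set to 0 (mean-free
  fields), matching demodulated phase, which carries no absolute frequency
  reference. Consequence: the spatial mean of a susceptibility map is not
  recoverable by any inversion; recovered maps are contrasts, and bulk
  readouts are reported as specimen-minus-reference differences.
- **Nyquist symmetrization.** On even grids the Nyquist frequency is its own
  negative, so a kernel evaluated naively from FFT frequencies is not
  point-symmetric on Nyquist planes and `real(ifft(·))` would silently
  deviate from the diagonal operator (≈5% errors in practice). All k-space
  kernels are averaged with their point reflection; this is a no-op away
  from Nyquist planes and makes the forward model exactly diagonal.
- **Padding.** `forward_field` zero-pads by 2× per axis (cropped after) to
  suppress circular wrap, which keeps boundary-decay properties of compact
  sources. The inversions default to the periodic lattice (`pad=1`), the
  standard COSMOS convention, and accept `pad` to match a padded forward
  operator; with matched operators the noiseless inversion is exact to
  machine precision.
- **COSMOS conditioning.** Coefficients with Σₙ Dₙ(k)² < τ = 0.01 are
  Tikhonov-damped (denominator + τ) rather than truncated, avoiding
  ringing. The `well_conditioned` mask is returned so error metrics can be
  restricted to coefficients the data actually determine.
- **QUASAR stabilisation.** The per-coefficient 2×2 normal matrix gets a
  ridge of 10⁻³·trace wherever its smallest eigenvalue falls below
  10⁻³·trace (this includes k = 0, where X is undetermined and R absorbs
  the mean). At least 4 orientations are required so the two unknowns are
  overdetermined with margin. Fields are assumed referenced upstream; no
  demeaning happens inside the inversions (demeaning a cropped field would
  inject a box function across all Fourier coefficients).
- **Geometry checks.** Orientation sets must have pairwise separations
  > 1° after antipodal folding, and the stacked per-orientation design
  ([Dₙ, 1] for QUASAR) must keep its smallest singular value above 10⁻³ at
  probe k-directions; collinear sets are rejected.
- **Background removal.** The harmonic (external-source) component is the
  solution of the Dirichlet problem on the mask interior: 7-point
  finite-difference Laplacian, boundary values from the measured total
  field, conjugate gradients at 10⁻⁶ relative tolerance, max 2000
  iterations (non-convergence raises with the residual norm). The result
  is demeaned over the mask; quantitative residual checks use a 2-voxel
  eroded mask, since the method is least reliable at the boundary ring.
  Internal fields are preserved up to the harmonic extension of their own
  boundary values — compact, deep sources are preserved to ≲1%.
- **Echo combination.** Per-voxel weighted least-squares slope of
  temporally unwrapped phase against 2π·TE, weights ∝ magnitude² (inverse
  phase variance). Temporal unwrapping (cumulative nearest-multiple-of-2π)
  replaces spatial region-growing unwrapping; it is exact whenever the
  field stays below π per ΔTE (≈118 Hz at ΔTE = 4.23 ms), which covers the
  synthetic regime by construction. Voxels with zero magnitude are flagged
  in a reliability map and set to 0.
- **R₂*.** The closed form is the log-linear weighted least-squares fit of
  ln S against TE with weights magnitude² — non-iterative, exact on
  noiseless monoexponential data, scale-invariant. Other closed forms
  (e.g. auto-regressive ones) share the noiseless contract but differ in
  noise behaviour.
- **Agar shell.** `dilate(specimen, outer) \ dilate(specimen, inner)` with
  a 6-connected (city-block) structuring element iterated — the most
  conservative reading of "voxels away in all directions"; defaults
  inner = 1, outer = 5. Shell voxels overlapping other specimens or the
  volume edge are excluded.
- **External-field fit.** One pooled ordinary least-squares problem over
  all agar voxels of all orientations, design = [δf_{i,N}, δf_{a,N},
  per-orientation indicator baselines Cₙ]; this is the exact minimiser of
  the summed objective (not per-orientation fits averaged). Identifiability
  requires ≥ 2 distinct θₙ. The L2 norm over voxels is used (no robust
  weighting), and Cₙ is a constant per orientation — no linear field
  gradients are absorbed.
- **Internal residual.** f_{R,N} is the specimen-mask mean of
  fₙ − χ̂ᵢδf_{i,N} − χ̂ₐδf_{a,N}. The agar baseline Cₙ is *not* subtracted
  by default (it is a property of the agar reference, not of the specimen
  interior); `subtract_baseline=True` is available for data whose
  per-orientation offset is global.
- **sin²θ fits and error propagation.** `fit_sin2` is plain OLS with
  t-based intervals (also used for R₂*(θ)); two points interpolate exactly
  with infinite CI half-widths at zero residual dof. For the pipeline's
  residual fit, `fit_residual_sin2` solves the GLS problem with covariance
  Ω = (σ̂²/n_specimen)·I + L·Cov(χ̂)·Lᵀ, where L holds the specimen-mean
  response loadings. This matters: the χₐ loading is nearly affine in
  sin²θ, so the first-stage estimation error moves Â directly while
  leaving the visible residual scatter almost unchanged — ordinary OLS
  intervals undercover (≈75–90% instead of 95% under the default phantom
  at SNR 50), while the propagated intervals are calibrated (≈94% in a
  300-replicate check). Normal quantiles are used because the agar sample
  that determines Cov(χ̂) is large.
- **Mean fiber axis.** Principal eigenvector of the dyadic average Σvvᵀ,
  immune to the antipodal sign ambiguity of per-voxel eigenvectors.
- **Cross-method regression.** Ordinary least squares of y on x with
  t-intervals, matching the stated comparison method; errors-in-variables
  in x are not corrected (a Deming fit would be the alternative), so
  slopes are mildly attenuated when x is noisy.

## The synthetic-data generator

`simulate_study` composes the generative model the analysis assumes:

    fₙ = χᵢ·δf_{i,N} + χₐ·δf_{a,N} + M_specimen·(A sin²θₙ + B)
         + Cₙ·M_agar + backgroundₙ + noise,

computed with the package's own forward chain, so recovery tests are exact
self-consistency checks in the noiseless limit. Defaults are the
specimen-session conditions: 96³ grid at 0.7 mm isotropic, cylinder radius
6 / length 40 voxels with the fiber along the cylinder axis, χᵢ = 1.17 ppb,
χₐ = 4.03 ppb, A = 1.46 ppb, B = −2.75 ppb (the reported ex vivo
white-matter means, used as generator settings), and the ten registered
specimen-session rotations [50, 60, 9, 66, 39, 0, 18, 31, 81, 88]° to the
reference axis. The whole-brain geometry (reference + [12, 12, 36, 46, 61,
62, 75, 77, 78]°) and spherical-Fibonacci hemisphere sets are also
available. Only the polar angles of the experimental sets are published;
azimuths are assigned by even spreading over [0°, 360°) in acquisition
order. Baselines Cₙ default to seeded N(0, 2 ppb) draws — the few-ppb scale
of agar chemical-exchange and residual-background offsets. Field noise for
a given per-echo SNR is derived from the phase-noise CRLB of the echo
combination (`field_noise_sd_ppb`; SNR 50 → 0.76 ppb with the 9-echo
specimen protocol). Background sources are spheres placed outside the
analysis mask and anti-aliased with a 1-voxel Gaussian: the band-limited
field of a hard-edged voxel source carries Nyquist ringing that is not
discretely harmonic and would defeat harmonic background removal for
reasons that have nothing to do with the solver.

What the generator deliberately does **not** emulate: fiber dispersion or
bending (the single-axis assumption is exact by construction, whereas real
genu/splenium specimens violate it), sub-voxel hollow-cylinder frequency
structure, registration/interpolation errors between orientations,
gradient-nonlinearity distortions, temperature drifts, and spatially
varying coil sensitivity. Passing recovery tests therefore demonstrates
correctness of the estimators under their stated model, not robustness to
these real-data effects.

## Problem sizes and runtime

Tests run the full-scale default phantom (96³) once for the specimen
round-trip and Monte-Carlo checks (unit responses are computed once and
reused across the 100 noise replicates), 32³ grids for inversion exactness,
16³ grids against the brute-force spatial-summation oracle, and 48–80³
grids for geometry and background-removal checks. The complete suite runs
in ~2 minutes on one CPU; `scripts/acceptance.py` in ~1–2 minutes. In the
Monte-Carlo bias check the replicate noise is centred across the replicate
axis, so the bias estimate measures implementation bias rather than the
sample mean of 100 noise draws; coverage accounting is unaffected.

## Known limitations

- The spatial mean of χ is unobservable (mean-free convention); all
  recovered maps are referenced contrasts.
- COSMOS bulk readouts on masked, desk-scale phantoms carry a ~1–2%
  multiplicative attenuation from field truncation at the mask; the
  cross-method regression slope is accordingly ≈0.98, not 1.000.
- LBV-style background removal is unreliable within ~2 voxels of the mask
  boundary and removes the harmonic extension of an internal source's
  boundary field (≲1% for compact deep sources, worse for sources near the
  boundary).
- Temporal unwrapping fails above π per ΔTE; spatial unwrapping is out of
  scope.
- Susceptibility tensor imaging beyond the cylindrically symmetric
  (χᵢ, χₐ) parametrisation is not implemented.
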