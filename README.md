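# oriqsm

Multi-orientation quantitative susceptibility mapping (QSM) and white-matter
compartmentalization analysis for gradient-echo (GRE) phase data, built
around the ex vivo workflow in which a specimen is physically rotated
relative to the main field B₀.

## The problem

The GRE signal phase in white matter carries two distinct kinds of
information. The **bulk magnetic susceptibility** of the tissue — isotropic
component χᵢ and, for coherent fiber bundles, an anisotropic component χₐ of
a cylindrically symmetric tensor — shifts the field *outside* the tissue in
a way fully described by dipole physics. The **compartmental
(microstructure) frequency offset** generated by water exchanging between
myelin, intra- and extra-axonal spaces lives strictly *inside* the tissue
and depends on the angle θ between the fiber axis and B₀ as A·sin²θ + B.
Separating the two requires data at many orientations to B₀, which for a
postmortem specimen is obtained by rotating the sample.

`oriqsm` implements the full chain as a tested Python library:

- **dipole physics** — the Fourier-domain unit dipole kernel
  D(k) = 1/3 − (k·b)²/|k|², forward fields of scalar and cylindrically
  symmetric tensor sources (χ̂ = χᵢI + χₐ(ffᵀ − I/3)), Lorentz-sphere
  corrected, mean-free;
- **field mapping** — weighted multi-echo phase combination (weights ∝
  magnitude², temporal unwrapping) and harmonic background-field removal by
  a Laplace boundary-value solve on the mask interior;
- **inversion** — COSMOS per-Fourier-coefficient least squares
  X(k) = ΣₙDₙFₙ / ΣₙDₙ², with per-orientation residual maps, and QUASAR,
  the joint fit Fₙ(k) = Dₙ(k)X(k) + R(k) that co-estimates an
  orientation-invariant non-susceptibility field f_ρ;
- **specimen analysis** — the agar external-field fit
  min ‖M_agar(fₙ − χᵢδf_{i,N} − χₐδf_{a,N} − Cₙ)‖² pooled over orientations,
  internal residual means f_{R,N}, and the sin²θ fit A·sin²θ + B with
  error-propagated confidence intervals;
- **relaxometry** — closed-form (log-linear weighted) R₂* mapping and the
  R₂*(θ) = A·sin²θ + B orientation fit;
- **synthetic data** — a ground-truth phantom generator (cylinder specimen
  in agar, the two experimental rotation-angle sets, baselines, harmonic
  backgrounds, noise) so every stage is verifiable by parameter recovery.

## Worked example

The default phantom is a cylinder of radius 6 and length 40 voxels (0.7 mm
isotropic, 96³ grid) whose generator parameters are the reported ex vivo
white-matter means: χᵢ = 1.17 ppb, χₐ = 4.03 ppb, A = 1.46 ppb,
B = −2.75 ppb, scanned at the ten registered specimen-session rotations
(0–88° to B₀). Running the core analysis,

```sh
python analysis/04_specimen_fit.py --seed 0
```

prints

```
noiseless: chi_i = 1.170 +- 0.000 ppb, chi_a = 4.030 +- 0.000 ppb
          A = 1.460 [1.460, 1.460] ppb, B = -2.750 [-2.750, -2.750] ppb, r2(sin^2) = 1.0000
snr50: chi_i = 1.159 +- 0.022 ppb, chi_a = 3.979 +- 0.050 ppb
          A = 1.433 [1.406, 1.460] ppb, B = -2.738 [-2.760, -2.716] ppb, r2(sin^2) = 0.9998
```

Noiseless data reproduce the generator exactly (the fit is the exact
minimiser of the generative model); at a per-echo SNR of 50 all four
parameters stay within their confidence intervals of the truth. The
brackets on A and B are 95% intervals with the χ-estimation error from the
agar fit propagated into the sin²θ stage.

The same analysis is available from the shell:

```sh
oriqsm run --config configs/demo_specimen.yaml
```

which simulates a small phantom and writes `results/demo_specimen_fit.csv`
with columns `chi_i_ppb, chi_a_ppb, A_ppb, B_ppb, …` (one row per specimen).
Other numbered scripts under `analysis/` demonstrate field mapping and
background removal (`02`), COSMOS/QUASAR inversions and the
residual-vs-f_ρ relationship (`03`), R₂*(θ) (`05`), and the six-specimen
COSMOS-vs-external-field regression (`06`).

## Conventions

Susceptibilities and fields are in ppb relative to the surrounding medium
(1 ppb ≙ 0.1277 Hz at 3 T; converters `ppb_to_hz`/`hz_to_ppb` are
provided). χₐ ≡ χ∥ − χ⊥. Fiber axes are antipodally equivalent; θ is folded
to [0°, 90°]. Volumes are NIfTI-1; orientations travel as JSON lists of
unit B₀ vectors in the registered frame.
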