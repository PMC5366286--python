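# Methods

## Signal models and moments

All models express the normalized per-axis attenuation f(b) = S(b)/S(0)
of a pulsed-gradient experiment with b = (γδG)²(Δ − δ/3) (evaluated in SI
units and converted to s/mm² by an explicit 1e-6 factor).  The statistical
models derive from the spectrum-of-diffusivities integral
S(b)/S(0) = ∫P(D)e^(−bD)dD, and every closed form in `myodiff.models` is
unit-tested against adaptive quadrature of its own density, so the model
zoo is internally consistent by construction rather than by transcription.

Kurtosis is defined throughout as the normalized variance of the
diffusivity distribution, K = 3·Var[D]/E[D]².  This is the definition
consistent with the gamma closed form K = 3/k, the biexponential
K = 3v(1−v)(Df−Ds)²/D̄², and the beta form 3β/(α(α+β+1)).  Skewness is
reported only for the gamma (2/√k) and beta families, the two whose shape
admits meaningful asymmetry; the beta skewness is the standard
2(β−α)√(α+β+1)/((α+β+2)√(αβ)), verified against quadrature.

Numerical choices worth knowing:

* the truncated-Gaussian signal is evaluated through `erfcx` with a
  branch on the sign of bσ/√2 − Dm/(√2σ); the naive erf/exp product
  overflows once σ approaches its lower bound during optimization.
* the DK log-signal exponent is clipped at +200 — bounded optimization
  visits (D, K) corners where the quadratic term would otherwise overflow.
  The clip is far outside the physically meaningful region.
* the beta signal uses the Kummer function `scipy.special.hyp1f1`;
  non-finite results raise an error carrying (α, α+β, −b·Dmax).
* the DK density is a Gaussian *not* truncated at zero: its kurtosis is
  then exactly K, at the price of mass at negative diffusivities.  Its
  quadrature oracle therefore integrates over the full real line.
* the stretched exponential is exp(−bᵃ·Ds) by default; the alternative
  exp(−(b·Ds)ᵃ) parameterization common elsewhere in the literature is
  available via `stretched_form="(b*Ds)^a"`.  The model has no analytic
  diffusivity density and no finite moments, and the package refuses both
  rather than approximating.

The displacement propagator is the inverse Fourier transform of the
signal over a symmetric uniform q-grid (b = 4π²q²(Δ − δ/3)); FWHM/FWTM
are read off by linear interpolation, and a grid whose resolved FWHM
spans fewer than four displacement steps is rejected.  Note that for a
two-compartment mixture the *ratio* FWTM/FWHM, not the absolute FWTM, is
the reliable tail-heaviness comparator: the narrow slow compartment
raises the peak and thereby shrinks both absolute widths slightly.

## Tensor frame and angles

The diffusion tensor is estimated by linear least squares on the
log-signal, by default from b ≤ 2000 s/mm² — the regime where the
Gaussian model still describes myocardium well; the cap is overridable.
Mean ADC is the eigenvalue mean and FA the usual normalized eigenvalue
dispersion.  Helix/transverse/sheetlet angles are computed from the
primary and tertiary eigenvectors in a local wall frame after fixing the
eigenvector signs (v1·circ ≥ 0, v3·radial ≥ 0), which makes the maps
deterministic while leaving the angles themselves sign-invariant.  For
phantoms the generator supplies the true frame; for real data a
cylindrical fallback (global long axis, per-slice centroid) is provided.
It is a stand-in, not a claim of equivalence to mesh-based wall
coordinates.

## Voxelwise fitting

Non-Gaussian models are fit as S0·Πᵢf(bᵢ) with bᵢ = b(g·vᵢ)².  The frame
is carried by six symmetric-tensor elements whose eigenvectors enter the
forward model; their eigenvalues are redundant for the non-Gaussian
models but keep the parameter accounting (P = 8/14/15 including the
residual variance) aligned with the AICc convention used for ranking.
The optimizer is scipy's trust-region-reflective bounded least squares
(ftol = xtol = 1e-10, ≤500 iterations per parameter; chosen so noiseless
recovery reaches ≤1e-4 relative error).  Bounds: diffusivity-like
parameters in [0, 5e-3] mm²/s (free-water ceiling), a ∈ (0, 1],
v ∈ [0, 1], K ∈ [0, 10], shape parameters in (1e-6, 1e3],
Dmax ∈ [0.5e-3, 5e-3] mm²/s.

Initialization cascade: DT and DK by linear least squares on the
log-signal (DK restricted to b ≤ 5000 s/mm², where the truncated cumulant
expansion is trustworthy); stretched from the DT fit with a = 1;
biexponential from segmented monoexponential fits to b < 1000 and
b > 6000 s/mm²; truncated Gaussian, gamma and beta by inverting the DK
fit's per-axis mean and kurtosis (gamma: k = 3/K, θ = D̄K/3; truncated
Gaussian: Dm = D̄, σ = D̄√(K/3); beta: α = 3(1−μ)/K − μ with
μ = D̄/Dmax), the beta Dmax starting at free water, 2.3e-3 mm²/s.
Nonpositive initial kurtosis falls back to K = 0.01 with a warning.

Two post-hoc safeguards proved necessary:

* **Frame restarts.** Non-Gaussian attenuation compresses distinct axes
  toward nearly equal apparent (log-linear) diffusivities, so the DT
  eigenframe is often unresolved in the sheetlet/sheetlet-normal plane.
  The fit is restarted from the DT frame rotated within its most
  degenerate eigen-plane (default grid: 0°, 45°, 90°) and the
  lowest-residual solution kept.  Deterministic, no random restarts.
* **Canonical axis order.** The factorized model is invariant to
  permuting axis labels together with eigenvectors; after fitting, axes
  are relabeled so axis 1 has the highest apparent diffusivity
  (attenuation at a reference b of 1000 s/mm²), matching the
  fiber/sheetlet/sheetlet-normal convention.

The frame is refit jointly with the shape parameters by default;
`freeze_frame=True` fixes it at the DT eigenvectors — about 3× faster and
used by the demo pipeline, at the price of residual axis mixing where the
frame is truly degenerate.  Whether the original analysis refit or froze
the frame is not documented; joint fitting is the safer default.

## Model ranking

AICc uses the natural logarithm and per-voxel mean squared residual.  To
keep n identical across models, the DK model is *fit* on b ≤ min(b_max,
5000) but its residuals for AICc are evaluated on the common b ≤ b_max
set.  The b_max sweep refits every model from scratch on each subset
(default grid 1200:400:10000 s/mm²); cells where n ≤ P + 1 are marked
invalid rather than fatal.  Ties in the best-model map go to the lower
parameter count, then lexicographic model id.

## Noise handling

Phase correction takes the voxelwise phase of the mean complex non-DW
image as reference, subtracts it from all complex images, and keeps the
real part, yielding zero-mean Gaussian noise suitable for least squares.
No spatial phase smoothing is applied by default (an optional flag
exists), since the reference construction alone matches the stated
procedure.  The noise SD estimator uses background-voxel statistics
(SD, or 1.4826·MAD with `robust=True`; magnitude-mode inputs are rescaled
by 1/√(2−π/2) for the Rayleigh background).  The cited original
estimation method is not described in the source; the background
estimator is a documented substitute.

## Synthetic phantoms

The generator emulates the study conditions, not real anatomy: an annular
short-axis wall (default 20×20×5 voxels) with a linear transmural helix
ramp (+60° endo to −60° epi), a cylindrical wall frame, v3 radial
(sheetlet angle 0), uniform distribution parameters within a heart, and
complex Gaussian channel noise with a smooth in-plane object phase.
Default signal scale S0 = 2.36e4 and noise SD 243 (SNR ≈ 97) mirror the
reported acquisition.  Schemes: Cartesian q-space grids — half-sphere
(257 directions; the radius-5 lattice ball holds exactly 514 nonzero
sites, i.e. 257 antipodal pairs) or symmetric full grid (514) — with
b ∝ |q|² up to 10,000 s/mm², δ = 5 ms, Δ = 9 ms, and measurement order
pseudo-randomized over b.  A golden-spiral shells style exists for tests.

Group-level targets (healthy/sham/TAC) are per-axis mean diffusivity
(taken as the biexponential mixture mean of the published compartment
values), kurtosis, skewness and Dmax, each with an across-hearts SD;
per-heart values are Gaussian draws, seeded.  Beta-model realization
matches mean and kurtosis exactly per axis; because one Dmax is shared
across axes (as in the fitted model) the three skewness targets cannot
all be met exactly, so Dmax is chosen to minimize the summed squared
skewness residuals.  In practice the per-axis exact solutions differ by
<10% in Dmax and the residuals are small.  Gamma and biexponential (and
Gaussian/DT) generation are available for misspecification and
model-selection experiments.

What the phantoms deliberately do not contain: realistic anatomy or
mesh-based wall coordinates, partial-volume rims, perfusion, temperature
drift, multi-coil noise.  Passing tests therefore demonstrate the
correctness and statistical behavior of the estimation machinery under
the assumed generative family — not that real myocardium follows any of
these distributions.

## Statistics

Group comparison uses per-heart ROI means with the exact two-tailed
Mann-Whitney U test: all C(n1+n2, n1) labelings of pooled mid-ranks are
enumerated and the smaller one-sided tail doubled (capped at 1); groups
larger than 12 fall back to the normal approximation, recorded in the
output.  Percent differences are reported in both conventions —
signed (a−b)/b and magnitude |a−b|/|b| — because published percent
figures for negative-valued quantities (skewness) are ambiguous about
the reference.  Significance is flagged at 5% uncorrected, with a
clearly-labeled Holm-adjusted column alongside.

## Problem sizes

The test suite and acceptance script run phantom experiments at reduced
size — ROIs of 10–100 voxels, 4 hearts per group, 3 replicates for the
group-discrimination check, 500–1000 Monte-Carlo repetitions — selected
so the full pipeline exercises every stage in minutes on one core.  At
n = 4+4 hearts the exact Mann-Whitney test reaches significance only on
complete separation (p = 2/70), so group-level checks are framed over
replicates rather than asserted on any single draw.

## Known limitations

* The beta model's (α, β, Dmax) are nearly unidentifiable when the
  density is edge-dominated (α or β ≪ 1): widely different parameter sets
  give signals equal to machine precision.  Derived moments remain stable;
  raw shape parameters from noisy fits should be interpreted with care.
* Fitting interface-like partial-volume voxels (two-population mixtures)
  with single-frame factorized models is structurally misspecified: no
  model in the zoo can represent a sum of two factorized signals, and in
  synthetic mixtures the stretched exponential or truncated Gaussian,
  not the biexponential, is usually the AICc winner (see the ledgered
  acceptance analysis).
* The sweep refits from scratch at every b_max for determinism; there is
  no warm-start, so dense grids are slow on large ROIs.
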