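# myodiff

Non-Gaussian diffusion modelling and information-criterion model ranking
for cardiac diffusion MRI.

## The problem

Diffusion tensor imaging assumes that water displacement in tissue is
Gaussian, but myocardium — with its membranes, organelles and ordered
sheetlets — restricts diffusion, and the deviation grows with diffusion
weighting. `myodiff` is for researchers analysing high-b-value ex-vivo (or
phantom) cardiac diffusion data who want to ask: *which signal model best
describes the decay, over what b-value range, and do its
diffusivity-distribution moments (kurtosis, skewness) discriminate disease
states such as pressure-overload hypertrophy?*

## The models

A voxel is modelled as a spectrum of Gaussian diffusion environments with
density P(D), giving the normalized signal

    S(b)/S(0) = ∫ P(D) e^{-bD} dD,

with kurtosis defined as K = 3·Var[D]/E[D]², so K = 0 for a single
Gaussian compartment.  Seven attenuation models are implemented along each
diffusion-tensor eigenvector (fiber, sheetlet, sheetlet-normal):

| model | f(b) | P(D) |
|---|---|---|
| monoexponential / DT | exp(−b·D) | δ(D − D) |
| stretched exponential | exp(−bᵃ·Ds) | — (no analytic form) |
| diffusion kurtosis (DK) | exp(−b·D + K·b²D²/6) | Gaussian(D, D²K/3) |
| biexponential | v·e^(−b·Df) + (1−v)·e^(−b·Ds) | two point masses |
| truncated Gaussian | erf-form (stable erfcx evaluation) | Gaussian truncated at 0 |
| gamma | (1 + bθ)^(−k) | Gamma(k, θ) |
| beta | M(α, α+β, −b·Dmax) (Kummer M) | Beta(α, β) on (0, Dmax) |

Non-Gaussian models are fit voxelwise by bounded trust-region least
squares in the diagonalized tensor frame, S(b)/S(0) = Π f(bᵢ) with
bᵢ = b(g·vᵢ)², and ranked by the corrected Akaike information criterion

    AICc = n·ln(ε²) + 2P + 2P(P+1)/(n−P−1),

with the relative likelihood exp((AICc_min − AICc_i)/2).  Complex data are
phase-corrected (real-part extraction after removing the mean non-DW
phase) so that high-b fits avoid the Rician noise floor.  A synthetic
phantom generator provides annular "hearts" with transmural helix ramps,
group-level moment targets (healthy / sham / TAC hypertrophy) and complex
Gaussian noise at a configurable SNR.

## Worked example

```python
import numpy as np
from myodiff import fitting, phantom, selection

scheme = phantom.make_scheme(514, b_max=10000.0, style="grid-full", seed=0)
spec = phantom.PhantomSpec(model_id="beta", group="tac", seed=11,
                           shape=(16, 16, 3), roi_voxels=12, noise_sd=243.0)
gt = phantom.make_phantom(spec)
data = phantom.simulate_signals(gt, scheme, seed=12).real_corrected()

i, j, k = np.argwhere(gt.roi_mask)[0]
fit = fitting.fit_voxel("beta", data[i, j, k], scheme)
mom = fit.derived_moments()
print("kurtosis  ", np.round(mom["kurtosis"], 3))
print("true      ", np.round(gt.moments()["kurtosis"], 3))
print("Dmax [mm^2/s]", round(fit.global_params["Dmax"], 6))
```

prints (seed 11/12):

```
kurtosis   [0.132 0.621 0.636]
true       [0.138 0.612 0.615]
Dmax [mm^2/s] 0.001619
```

i.e. the per-axis kurtosis of a hypertrophic-range voxel (lowest along the
fiber axis, highest along the sheetlet-normal axis) is recovered within a
few percent at the emulated scanner noise level, along with the upper
diffusivity limit Dmax of the beta model.

The same workflow from the shell:

```sh
myodiff simulate --group tac --model beta --seed 11 --out sim/
myodiff correct --magnitude sim/magnitude.nii.gz --phase sim/phase.nii.gz \
                --scheme sim/scheme --out real.nii.gz
myodiff fit --data real.nii.gz --scheme sim/scheme --mask sim/roi_mask.nii.gz \
            --models dt,beta --out fits.tsv
myodiff run --seed 1 --out bundle/       # full pipeline with report tables
```

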