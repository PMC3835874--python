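# blocknlm

Bayesian block-wise non-local means (NLM) speckle filtering for 3D
ultrasound volumes.

Speckle — the granular interference pattern inherent to coherent
imaging — obscures anatomy and lowers soft-tissue contrast in 3D
ultrasound. Classic NLM removes additive Gaussian noise by averaging
voxels whose surrounding patches look alike, but ultrasound speckle is
signal-dependent. `blocknlm` implements the NLM variant adapted to the
noise statistics of log-compressed ultrasound, with a block-wise
formulation that cuts the cost by roughly *n*³ for a block stride *n*.
It ships a synthetic speckle-phantom generator, so the whole pipeline is
exercisable without any clinical data, plus quality metrics, a parallel
backend and a command-line interface.

## The model

Observed intensity follows the signal-dependent noise model

```
u(x) = v(x) + v(x)^γ η(x),      η ~ N(0, σ²)
```

with γ = 0.5 matching the empirical mean-vs-standard-deviation relation
of log-compressed ultrasound (local noise SD grows as √v). Under the
induced Gaussian conditional `u | v ~ N(v, v^{2γ}σ²)`, patch similarity
is measured by

```
d(B_i, B_j) = Σ_p (u_p(B_i) − u_p(B_j))² / u_p(B_j)^{2γ}
```

(the denominator uses the *candidate* patch `B_j`), and a reference
patch is restored as

```
NL(u)(B_i) = Σ_{B_j ∈ Δ_i} w(B_i, B_j) u(B_j),
w(B_i, B_j) = (1/Z_i) exp(−d(B_i, B_j)/h²)
```

with the candidates `B_j` ranging over every voxel-centered patch whose
support fits inside the search window Δ_i of radius M. Reference
patches of size (2R+1)³ are placed on a stride-*n* grid; each voxel's
final intensity is the plain mean of all block estimates that cover it.
Defaults follow the standard regime: h = 20, M = 5 (an 11×11×11 search
window), n = R+1. The classic Gaussian-noise NLM filter and a
voxel-wise Bayesian filter are included for comparison.

## Worked example

Generate a 64³ phantom (piecewise-constant anatomy, levels 40–220),
corrupt it with γ = 0.5 speckle at σ = 5, filter block-wise with R = 1,
and compare:

```
$ blocknlm simulate --dims 64x64x64 --sigma 5 --seed 1 \
    --out-clean clean.64x64x64.raw --out-noisy noisy.64x64x64.raw
simulate: dims=(64, 64, 64) gamma=0.5 sigma=5.0 seed=1 elapsed=0.02s

$ blocknlm denoise --in noisy.64x64x64.raw --out denoised.64x64x64.raw \
    --mode block --ref-radius 1
load: noisy.64x64x64.raw dims=(64, 64, 64)
grid: counts=(26, 26, 26) blocks=17576 step=2 origin=6
filter: block-wise vectorized (serial)
done: denoised.64x64x64.raw elapsed=9.33s

$ blocknlm evaluate --a clean.64x64x64.raw --b noisy.64x64x64.raw
PSNR 16.4675 dB | MSE 1466.67 | MAE 30.7651 | residual mean -0.875541 std 38.2872

$ blocknlm evaluate --a clean.64x64x64.raw --b denoised.64x64x64.raw
PSNR 19.4069 dB | MSE 745.4 | MAE 20.0089 | residual mean -5.20119 std 26.802
```

The filter raises PSNR against the clean ground truth by ≈ 2.9 dB and
cuts the mean absolute error by a third; the residual statistics
summarize what was removed (ideally pure speckle, mean ≈ 0). Raw files
carry their dimensions in the filename (`name.WxHxF.raw`, x varying
fastest); NIfTI (`.nii`/`.nii.gz`) and multi-page TIFF are recognized by
extension. The same pipeline is available from Python:

```python
import blocknlm as bn

clean = bn.make_phantom(bn.default_phantom_spec((64, 64, 64)))
noisy = bn.add_speckle(clean, bn.NoiseParams(gamma=0.5, sigma=5, seed=1))
params = bn.FilterParams(ref_radius=1, search_radius=5, decay=20.0)
denoised = bn.blockwise_nlm_filter(noisy, params)
print(bn.evaluate(clean, denoised))
```

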