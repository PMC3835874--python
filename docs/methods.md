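# Methods

## Noise model

Log-compressed ultrasound speckle is modeled as signal-dependent
additive noise

    u(x) = v(x) + v(x)^γ η(x),      η ~ N(0, σ²), i.i.d. per voxel,

where `v` is the clean intensity and `u` the observation. γ = 0.5 is
the default: it reproduces the empirical finding that the local noise
standard deviation of log-compressed ultrasound grows as √v. γ = 0
recovers additive Gaussian noise; γ = 1 behaves like multiplicative
noise. The model implies `u | v ~ N(v, v^{2γ} σ²)`.

Observed intensities are clamped from below at ε = 10⁻³ (intensity
units) after corruption, and the Bayesian distance clamps its
denominators the same way: the distance divides by observed candidate
intensities, which can otherwise be arbitrarily small, and
log-compressed ultrasound data is positive anyway.

## Filters

**Classic NLM (voxel-wise).** Patch distance is the Gaussian-kernel
weighted squared L2 norm with kernel std α (default 1 voxel; the kernel
is normalized to unit sum, so a constant patch difference c yields
distance c² regardless of α or R; `alpha=None` selects a flat kernel).
Weights are `exp(−d/h²)`, normalized over the search window.

**Bayesian NLM (voxel-wise and block-wise).** Patch distance

    d(B_i, B_j) = Σ_p (u_p(B_i) − u_p(B_j))² / u_p(B_j)^{2γ}

— the candidate patch supplies the denominator, so the distance is
deliberately asymmetric. Weights are `exp(−d/h²)` normalized over the
candidate set; the noise variance σ² is folded into the single decay
parameter h and is not set separately. The candidate set always
includes the reference itself with its natural weight exp(0) = 1; no
maximum-weight substitution is applied.

**Block-wise restoration.** Reference blocks of size (2R+1)³ are placed
on a stride-n grid with the first center at M+R per axis; the per-axis
block count is `floor((dim − 2M − (2R+1))/n) + 1`, which places every
block and its full search window inside the volume. Candidates are all
voxel-centered blocks (stride 1) whose support fits in the search
window, i.e. centers within M−R of the reference center. Each covered
voxel's output is the unweighted arithmetic mean of all block estimates
that contain it, accumulated as a running (sum, count) pair rather than
an explicit per-voxel estimate list. Voxels no block covers — the
border margin of width M+R plus any stride remainder — are copied
bit-exactly from the input; no padding scheme is used, consistent with
the grid formulas that exclude exactly that margin.

The idealized operation count for an N³ cube is
`(2R+1)³ (2M+1)³ ((N−n)/n)³`; relative to voxel-wise processing the
block stride divides the cost by ≈ n³ (factor 8 at n = 2, the limit of
the finite-N ratio as N grows). The exact count for real dims is
`NUM_BX·NUM_BY·NUM_BZ·(2R+1)³·(2M−2R+1)³`. The exact count is
monotonically non-increasing in n; note that only the *idealized* count
is monotone in R — in the exact count the in-bounds candidate window
(2M−2R+1)³ shrinks as R grows and can outweigh the (2R+1)³ growth.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| R (`ref_radius`) | patch half-width, voxels | required | typical range 1–5 |
| M (`search_radius`) | search-window half-width, voxels | 5 | 11×11×11 window |
| n (`step`) | block-grid stride, voxels | R+1 | n ≤ 2R keeps blocks overlapping |
| h (`decay`) | weight bandwidth, intensity units | 20.0 | exponent divisor is exactly h² |
| γ (`gamma`) | noise exponent | 0.5 | 0 = additive Gaussian |
| α (`alpha`) | classic-distance kernel std, voxels | 1.0 | None = flat kernel |

h is *not* rescaled by patch size or noise level: because the Bayesian
distance is a plain sum over the P = (2R+1)³ patch voxels, its typical
magnitude grows linearly with P (≈ 2σ²P inside homogeneous regions for
γ = 0.5 and intensities near their level). With h fixed at 20, R = 1
filters strongly, while R ≥ 2 under heavy speckle (σ ≥ 5 in the
phantom's 40–220 intensity range) drives all non-self weights toward
zero and the filter degenerates to the identity. Users who want larger
patches at a fixed smoothing strength should scale h ∝ √P themselves;
adaptive selection of h is a known open problem for this estimator and
is out of scope here.

## Synthetic phantoms

`make_phantom` renders piecewise-constant anatomy (spheres = Euclidean
balls, boxes = Chebyshev balls, painted in order, optional linear
ramp) on a positive background; the default phantom spans levels
40–220, echoing the 8-bit display range of log-compressed ultrasound
and keeping h = 20 in a sensible regime. `add_speckle` applies the
noise model with a seeded PCG64 generator, drawing the noise field in
fixed x-fastest voxel order so results are bit-reproducible and
layout-stable.

What passing tests on these phantoms show: the estimator, grid,
aggregation and noise model behave exactly as specified, and filtering
improves fidelity under the assumed noise law. What they do not show:
performance on real scans, whose speckle is spatially correlated by the
point-spread function and scan conversion, and whose anatomy is not
piecewise constant — the phantom has neither property.

## Numerical choices

- All volumes are converted to float64 internally; the filters
  accumulate many products of squared differences.
- Standalone weight computations subtract the minimum distance before
  exponentiating — exactly neutral after normalization, but immune to
  underflow when every distance ≫ h². Inside the filters the self
  candidate anchors the normalizer at ≥ 1, so no shift is applied there.
- Candidate/offset iteration is fixed x-fastest, then y, then z, so
  serial results are bit-reproducible. Mirror-symmetry of the filters
  holds to summation-order precision (~10⁻¹⁰ relative), not bit-exactly,
  because mirroring permutes the accumulation order.
- Two block-wise engines: a literal per-block loop (the parallel unit
  of work) and a vectorized engine that sweeps the (2(M−R)+1)³
  candidate offsets over the whole volume, computing each offset's
  per-voxel ratio field and box-summing it with exact separable
  ones-kernel correlations. Both compute the same estimator and agree
  to ~10⁻¹² per voxel; the test suite pins both to an independent
  brute-force oracle at 10⁻⁹.
- Parallelism is over reference blocks: the flattened grid is split
  into near-equal contiguous chunks (remainder to the earliest chunks),
  each chunk returns a partial (sum, count) accumulator, and partials
  are merged serially in chunk order — results are deterministic for a
  fixed chunk count, bit-identical to the serial engine at one worker,
  and within 10⁻⁹ of it otherwise.
- Degenerate settings behave as limits dictate: M = R leaves a single
  candidate (the block itself) and the filter is the identity on covered
  voxels; constant volumes pass through every filter unchanged; σ = 0
  noise is the exact identity.

## Test problem sizes

Oracle-equivalence tests run on 10³–24³ volumes (the brute-force
references are pure nested loops); the denoising-efficacy check uses
the full 64³ phantom, 20 seeds per configuration, with the default
M = 5 search window. Noise-moment checks use 10⁶ voxels, giving
3-standard-error bands of ±0.03 on a mean of 100.

## Known limitations

- Fixed h couples smoothing strength to patch size (see above); no
  adaptive or per-voxel bandwidth.
- No patch preselection, integral-image or FFT acceleration; the
  vectorized engine is memory-bound at roughly
  (2(M−R)+1)³ × (grid size) temporary weights.
- Margins are copied, not filtered: a border of width M+R stays noisy.
- Voxel units only — anisotropic voxel spacing is ignored.
- No DICOM ingestion; raw/NIfTI/TIFF only.
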