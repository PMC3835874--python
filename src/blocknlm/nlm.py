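"""Patch distances, similarity weights and the two voxel-wise NLM filters.

Non-local means restores a voxel as a weighted average of intensities
whose surrounding patches resemble the target voxel's patch.  Two
variants live here:

* the **classic** filter, with a Gaussian-kernel-weighted squared L2
  patch distance and weights ``w ~ exp(-d / h^2)`` — appropriate for
  additive Gaussian noise;
* the **Bayesian** filter for signal-dependent speckle, whose patch
  distance divides each squared difference by the candidate patch
  intensity raised to ``2*gamma``,

      d(B_i, B_j) = sum_p (u_p(B_i) - u_p(B_j))^2 / u_p(B_j)^(2*gamma),

  the log-likelihood implied by ``u | v ~ N(v, v^(2*gamma) sigma^2)``
  after substituting the observed candidate patch for the unknown clean
  one.  With ``gamma = 0`` it degenerates to a flat (unweighted) squared
  L2 distance.

Candidates are restricted to a cubic search window of radius M around
the voxel.  Border voxels whose search window or patch would leave the
volume are copied unchanged; the restored region is the interior margin
of width M + R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .simulate import INTENSITY_FLOOR
from .volume import Volume

__all__ = [
    "FilterParams",
    "Patch",
    "extract_patch",
    "patch_kernel",
    "gaussian_l2_distance",
    "bayes_distance",
    "classic_nlm_weights",
    "bayes_weights",
    "classic_nlm_filter",
    "bayes_nlm_filter_voxelwise",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """All tunables of the filters.

    ref_radius : R, half-width of the similarity/reference patch (voxels);
                 patch size P = (2R+1)^3
    search_radius : M >= R, half-width of the search window (voxels);
                 window size (2M+1)^3
    step : n, the block-grid stride used by the block-wise filter;
           defaults to R+1, which keeps neighbouring restored blocks
           overlapping (edge continuity)
    decay : h, the smoothing bandwidth in intensity units; the weight
            exponent divisor is exactly h^2, with no patch-size rescaling
    gamma : noise-model exponent of the Bayesian distance
    alpha : std (voxels) of the Gaussian kernel of the classic distance;
            None means a flat kernel
    """

    ref_radius: int
    search_radius: int
    step: Optional[int] = None
    decay: float = 20.0
    gamma: float = 0.5
    alpha: Optional[float] = 1.0

    def __post_init__(self) -> None:
        if self.ref_radius < 1:
            raise ValidationError(f"ref_radius must be >= 1, got {self.ref_radius}")
        if self.search_radius < self.ref_radius:
            raise ValidationError(
                f"search_radius ({self.search_radius}) must be >= "
                f"ref_radius ({self.ref_radius})"
            )
        if self.step is not None and self.step < 1:
            raise ValidationError(f"step must be >= 1, got {self.step}")
        if not self.decay > 0:
            raise ValidationError(f"decay h must be > 0, got {self.decay}")
        if self.gamma < 0:
            raise ValidationError(f"gamma must be >= 0, got {self.gamma}")
        if self.alpha is not None and not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0 or None, got {self.alpha}")

    @property
    def stride(self) -> int:
        """Effective block step: ``step`` or its default R+1."""
        return self.step if self.step is not None else self.ref_radius + 1

    @property
    def patch_size(self) -> int:
        """P = (2R+1)^3."""
        return (2 * self.ref_radius + 1) ** 3

    @property
    def window_size(self) -> int:
        """(2M+1)^3."""
        return (2 * self.search_radius + 1) ** 3

    @property
    def margin(self) -> int:
        """Border width M + R excluded from restoration."""
        return self.search_radius + self.ref_radius


@dataclass(frozen=True)
class Patch:
    """The (2R+1)^3 intensities of a cubic neighbourhood, x-fastest order."""

    values: np.ndarray
    center: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        side = round(vals.size ** (1 / 3))
        if side**3 != vals.size or side % 2 != 1:
            raise ValidationError(
                f"patch length {vals.size} is not an odd cube (2R+1)^3"
            )
        object.__setattr__(self, "values", vals)

    @property
    def radius(self) -> int:
        return (round(self.values.size ** (1 / 3)) - 1) // 2


PatchLike = Union[Patch, np.ndarray, Sequence[float]]


def _patch_values(p: PatchLike) -> np.ndarray:
    if isinstance(p, Patch):
        return p.values
    return np.asarray(p, dtype=np.float64).ravel()


def extract_patch(vol: Volume, center: tuple[int, int, int], radius: int) -> Patch:
    """Cut the cubic neighbourhood of ``radius`` around ``center``.

    Values are flattened x-fastest, matching the raw-file layout.
    """
    x, y, z = center
    r = radius
    w, h, f = vol.dims
    if x - r < 0 or y - r < 0 or z - r < 0 or x + r >= w or y + r >= h or z + r >= f:
        raise ValidationError(
            f"patch of radius {r} at {center} leaves volume of dims {vol.dims}"
        )
    cube = vol.data[x - r : x + r + 1, y - r : y + r + 1, z - r : z + r + 1]
    return Patch(cube.ravel(order="F"), center=(x, y, z))


def patch_kernel(radius: int, alpha: Optional[float]) -> np.ndarray:
    """Isotropic 3D Gaussian over patch offsets, normalized to sum 1.

    ``alpha=None`` (or infinite) yields the flat kernel 1/P.
    """
    side = 2 * radius + 1
    if alpha is None or not np.isfinite(alpha):
        return np.full((side, side, side), 1.0 / side**3)
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(t**2) / (2.0 * alpha**2))
    k = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return k / k.sum()


def gaussian_l2_distance(
    p_i: PatchLike, p_j: PatchLike, alpha: Optional[float] = 1.0
) -> float:
    """Gaussian-kernel-weighted squared L2 distance between two patches.

    ``sum_p k_alpha(p) (p_i(p) - p_j(p))^2`` with the kernel normalized
    to unit sum, so a constant difference c gives exactly c^2.
    """
    vi, vj = _patch_values(p_i), _patch_values(p_j)
    if vi.size != vj.size:
        raise ValidationError(f"patch size mismatch: {vi.size} vs {vj.size}")
    radius = (round(vi.size ** (1 / 3)) - 1) // 2
    k = patch_kernel(radius, alpha).ravel()
    return float(np.dot(k, (vi - vj) ** 2))


def bayes_distance(
    p_i: PatchLike, p_j: PatchLike, gamma: float = 0.5, floor: float = INTENSITY_FLOOR
) -> float:
    """Signal-adaptive patch distance with the candidate-patch denominator.

    ``sum_p (p_i(p) - p_j(p))^2 / p_j(p)^(2*gamma)``.  Candidate values
    below the positivity floor are clamped (and the event logged), never
    an error: observed ultrasound intensities can be arbitrarily small.
    """
    vi, vj = _patch_values(p_i), _patch_values(p_j)
    if vi.size != vj.size:
        raise ValidationError(f"patch size mismatch: {vi.size} vs {vj.size}")
    if gamma == 0:
        return float(np.sum((vi - vj) ** 2))
    if vj.min() < floor:
        logger.debug(
            "clamping %d candidate value(s) below %g in bayes_distance",
            int(np.sum(vj < floor)),
            floor,
        )
    den = np.power(np.maximum(vj, floor), 2.0 * gamma)
    return float(np.sum((vi - vj) ** 2 / den))


def _normalized_weights(distances: np.ndarray, h: float) -> np.ndarray:
    # shifting by the min distance leaves the normalized weights exactly
    # unchanged and prevents exp underflow when every distance >> h^2
    w = np.exp(-(distances - distances.min()) / (h * h))
    return w / w.sum()


def classic_nlm_weights(
    ref: PatchLike,
    candidates: Sequence[PatchLike],
    h: float,
    alpha: Optional[float] = 1.0,
) -> np.ndarray:
    """Normalized similarity weights ``w_j ~ exp(-d_alpha(ref, cand_j)/h^2)``.

    The normalization constant is taken over the supplied candidate set,
    so the weights always sum to 1.
    """
    if not h > 0:
        raise ValidationError(f"h must be > 0, got {h}")
    if len(candidates) == 0:
        raise ValidationError("candidate set must be non-empty")
    d = np.array([gaussian_l2_distance(ref, c, alpha) for c in candidates])
    return _normalized_weights(d, h)


def bayes_weights(
    ref: PatchLike,
    candidates: Sequence[PatchLike],
    h: float,
    gamma: float = 0.5,
) -> np.ndarray:
    """Normalized weights from the signal-adaptive distance."""
    if not h > 0:
        raise ValidationError(f"h must be > 0, got {h}")
    if len(candidates) == 0:
        raise ValidationError("candidate set must be non-empty")
    d = np.array([bayes_distance(ref, c, gamma) for c in candidates])
    return _normalized_weights(d, h)


# ---------------------------------------------------------------------------
# Voxel-wise filters
# ---------------------------------------------------------------------------


def _search_offsets(m: int) -> list[tuple[int, int, int]]:
    """All integer offsets in [-m, m]^3, x varying fastest."""
    r = range(-m, m + 1)
    return [(dx, dy, dz) for dz in r for dy in r for dx in r]


def _shift(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """``out[x] = a[x + d]`` where defined, 0 elsewhere (never read)."""
    out = np.zeros_like(a)
    dst = tuple(
        slice(max(0, -di), n - max(0, di)) for di, n in zip(d, a.shape)
    )
    src = tuple(
        slice(max(0, di), n - max(0, -di)) for di, n in zip(d, a.shape)
    )
    out[dst] = a[src]
    return out


def _boxsum(a: np.ndarray, radius: int) -> np.ndarray:
    """Exact (2r+1)^3 box sum via separable correlation, zero-padded."""
    k = np.ones(2 * radius + 1)
    for axis in range(3):
        a = ndimage.correlate1d(a, k, axis=axis, mode="constant", cval=0.0)
    return a


def _check_min_dims(u: Volume, params: FilterParams) -> None:
    need = 2 * params.margin + 1
    if min(u.dims) < need:
        raise ValidationError(
            f"volume dims {u.dims} too small: each dim must be >= "
            f"2*(M+R)+1 = {need} for R={params.ref_radius}, "
            f"M={params.search_radius}"
        )


def _voxelwise_filter(u: Volume, params: FilterParams, mode: str) -> Volume:
    """Shared engine of both voxel-wise filters.

    Iterates over search-window offsets d: for each d the patch distance
    between every interior voxel i and its candidate i+d is obtained by
    correlating the shifted squared-difference field with the patch
    kernel, which evaluates all reference voxels at once.  Weighted
    numerator and normalizer accumulate across offsets in fixed
    x-fastest order; normalization happens once at the end.
    """
    _check_min_dims(u, params)
    a = u.data
    m, r = params.search_radius, params.ref_radius
    h2 = params.decay**2
    interior = tuple(slice(params.margin, n - params.margin) for n in a.shape)
    if mode == "classic":
        kernel = patch_kernel(r, params.alpha)
    num = np.zeros_like(a[interior])
    z = np.zeros_like(num)
    for d in _search_offsets(m):
        sh = _shift(a, d)
        diff2 = (a - sh) ** 2
        if mode == "classic":
            s = ndimage.correlate(diff2, kernel, mode="constant", cval=0.0)
        elif params.gamma == 0:
            s = _boxsum(diff2, r)
        else:
            den = np.power(np.maximum(sh, INTENSITY_FLOOR), 2.0 * params.gamma)
            s = _boxsum(diff2 / den, r)
        w = np.exp(-s[interior] / h2)
        num += w * sh[interior]
        z += w
    out = a.copy()
    out[interior] = num / z
    return Volume(out)


def classic_nlm_filter(v: Volume, params: FilterParams) -> Volume:
    """Classic NLM: Gaussian-kernel L2 patch distance, search window M.

    Each interior voxel is restored as a convex combination of the
    intensities in its search window; the border margin of width M+R is
    copied from the input.
    """
    return _voxelwise_filter(v, params, "classic")


def bayes_nlm_filter_voxelwise(u: Volume, params: FilterParams) -> Volume:
    """Voxel-wise Bayesian NLM for signal-dependent speckle.

    Weights come from the signal-adaptive patch distance (candidate-
    intensity denominator); the restored voxel is the weighted average
    of the candidate center intensities over the search window.
    """
    return _voxelwise_filter(u, params, "bayes")
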