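"""Synthetic speckle phantoms for exercising the filters without real scans.

The generator has two halves:

* :func:`make_phantom` builds a piecewise-constant "anatomy" — spheres
  and boxes of distinct echogenicity on a uniform background, optionally
  with a linear intensity ramp — in the [20, 220] range typical of
  8-bit log-compressed ultrasound display.
* :func:`add_speckle` corrupts it with the signal-dependent noise model

      u(x) = v(x) + v(x)^gamma * eta(x),      eta ~ N(0, sigma^2)

  which with ``gamma = 0.5`` reproduces the mean-vs-standard-deviation
  relation observed in log-compressed ultrasound: the local noise
  standard deviation grows as ``sqrt(v)``.  ``gamma = 0`` recovers plain
  additive Gaussian noise; ``gamma = 1`` behaves multiplicatively.

What this emulates — and what it does not: the phantom has the intensity
statistics the filters assume (positive levels, signal-dependent noise)
but none of the spatial correlation a real point-spread function or
scan conversion would introduce; speckle here is voxel-wise independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .volume import Volume

__all__ = [
    "NoiseParams",
    "PhantomObject",
    "PhantomSpec",
    "make_phantom",
    "add_speckle",
    "default_phantom_spec",
    "INTENSITY_FLOOR",
]

# Positivity floor applied after corruption: the Bayesian patch distance
# divides by observed intensities raised to 2*gamma, so observed values
# are clamped to stay strictly positive.
INTENSITY_FLOOR = 1e-3


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the signal-dependent speckle model.

    gamma : dimensionless exponent (0.5 fits log-compressed ultrasound)
    sigma : noise standard deviation (intensity units when gamma = 0)
    seed  : RNG seed; identical (params, input) pairs give identical output
    """

    gamma: float = 0.5
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError(f"gamma must be >= 0, got {self.gamma}")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class PhantomObject:
    """One constant-intensity object.

    shape  : "sphere" (Euclidean ball) or "box" (Chebyshev ball)
    center : (x, y, z) voxel coordinates (floats allowed)
    size   : radius in voxels — Euclidean for spheres, half-width for boxes
    level  : intensity, strictly positive
    """

    shape: str
    center: tuple[float, float, float]
    size: float
    level: float


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth phantom description."""

    dims: tuple[int, int, int]
    background_level: float = 60.0
    objects: Sequence[PhantomObject] = field(default_factory=tuple)
    ramp: Optional[tuple[float, float, float]] = None


def make_phantom(spec: PhantomSpec) -> Volume:
    """Render a piecewise-constant phantom (plus optional linear ramp).

    Objects are painted in order, later objects overwriting earlier
    ones.  Every voxel of the result is strictly positive.

    Raises
    ------
    ValidationError
        If any level is non-positive or an object extends outside dims.
    """
    w, h, f = spec.dims
    if min(w, h, f) < 1:
        raise ValidationError(f"phantom dims must be >= 1, got {spec.dims}")
    if spec.background_level <= 0:
        raise ValidationError(
            f"background level must be > 0, got {spec.background_level}"
        )
    data = np.full((w, h, f), float(spec.background_level))
    x, y, z = np.ogrid[0:w, 0:h, 0:f]
    for obj in spec.objects:
        if obj.level <= 0:
            raise ValidationError(f"object level must be > 0, got {obj.level}")
        cx, cy, cz = obj.center
        lo = (cx - obj.size, cy - obj.size, cz - obj.size)
        hi = (cx + obj.size, cy + obj.size, cz + obj.size)
        if min(lo) < -0.5 or any(a > d - 0.5 for a, d in zip(hi, (w, h, f))):
            raise ValidationError(
                f"object {obj.shape} at {obj.center} size {obj.size} "
                f"extends outside dims {spec.dims}"
            )
        if obj.shape == "sphere":
            mask = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= obj.size**2
        elif obj.shape == "box":
            mask = (
                (np.abs(x - cx) <= obj.size)
                & (np.abs(y - cy) <= obj.size)
                & (np.abs(z - cz) <= obj.size)
            )
        else:
            raise ValidationError(f"unknown object shape {obj.shape!r}")
        data[mask] = float(obj.level)
    if spec.ramp is not None:
        gx, gy, gz = spec.ramp
        data = data + gx * x + gy * y + gz * z
    if data.min() <= 0:
        raise ValidationError(
            "phantom has non-positive voxels (check ramp slopes and levels)"
        )
    return Volume(data)


def add_speckle(v: Volume, params: NoiseParams) -> Volume:
    """Corrupt ``v`` with the signal-dependent speckle model.

    The noise field eta is drawn from a seeded PCG64 generator in fixed
    x-fastest voxel order, so the result is bit-reproducible for a given
    (seed, dims) and independent of how the clean volume was produced.
    The output is clamped at ``INTENSITY_FLOOR`` so downstream distances
    never divide by zero.
    """
    if params.gamma > 0 and v.data.min() <= 0:
        raise ValidationError(
            "signal-dependent noise (gamma > 0) requires strictly positive input"
        )
    rng = np.random.Generator(np.random.PCG64(params.seed))
    w, h, f = v.dims
    eta = rng.standard_normal(w * h * f).reshape((w, h, f), order="F")
    u = v.data + np.power(v.data, params.gamma) * (params.sigma * eta)
    return Volume(np.maximum(u, INTENSITY_FLOOR))


def default_phantom_spec(dims: tuple[int, int, int] = (64, 64, 64)) -> PhantomSpec:
    """The standard test phantom: three objects on a level-60 background.

    Object sizes scale with the volume so the same anatomy fits any cube
    from 24 voxels up: a large mid-gray sphere, a small bright sphere and
    a hypoechoic box, levels spanning [40, 220].
    """
    w, h, f = dims
    s = min(dims)
    if s < 24:
        raise ValidationError(f"default phantom needs dims >= 24, got {dims}")
    return PhantomSpec(
        dims=dims,
        background_level=60.0,
        objects=(
            PhantomObject("sphere", (w / 2, h / 2, f / 2), 0.22 * s, 160.0),
            PhantomObject("sphere", (w / 4, h / 4, 0.6 * f), 0.09 * s, 220.0),
            PhantomObject("box", (0.72 * w, 0.3 * h, 0.3 * f), 0.10 * s, 40.0),
        ),
    )
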