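"""Image-quality metrics and residual volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .volume import Volume

__all__ = ["QualityReport", "mse", "mae", "psnr", "residual", "evaluate"]


@dataclass(frozen=True)
class QualityReport:
    """Summary comparison of two volumes.

    psnr is in dB (infinite when the volumes are identical); mae and
    the residual stats are in intensity units, mse in squared units.
    """

    psnr: float
    mse: float
    mae: float
    residual_mean: float
    residual_std: float

    def __str__(self) -> str:
        return (
            f"PSNR {self.psnr:.4f} dB | MSE {self.mse:.6g} | MAE {self.mae:.6g} | "
            f"residual mean {self.residual_mean:.6g} std {self.residual_std:.6g}"
        )


def _check_dims(a: Volume, b: Volume) -> None:
    if a.dims != b.dims:
        raise ValidationError(f"dims mismatch: {a.dims} vs {b.dims}")


def mse(a: Volume, b: Volume) -> float:
    """Mean squared voxel difference."""
    _check_dims(a, b)
    return float(np.mean((a.data - b.data) ** 2))


def mae(a: Volume, b: Volume) -> float:
    """Mean absolute voxel difference."""
    _check_dims(a, b)
    return float(np.mean(np.abs(a.data - b.data)))


def psnr(a: Volume, b: Volume, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio, ``10 log10(peak^2 / MSE)``, in dB.

    Identical volumes give ``inf``.
    """
    if not peak > 0:
        raise ValidationError(f"peak must be > 0, got {peak}")
    err = mse(a, b)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / err))


def residual(original: Volume, filtered: Volume) -> Volume:
    """Voxel-wise ``original - filtered`` — what the filter removed."""
    _check_dims(original, filtered)
    return Volume(original.data - filtered.data)


def evaluate(a: Volume, b: Volume, peak: float = 255.0) -> QualityReport:
    """Full quality report comparing volume ``b`` against reference ``a``."""
    res = residual(a, b)
    return QualityReport(
        psnr=psnr(a, b, peak),
        mse=mse(a, b),
        mae=mae(a, b),
        residual_mean=float(res.data.mean()),
        residual_std=float(res.data.std()),
    )
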