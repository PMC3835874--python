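"""Independent brute-force reference implementations.

Everything here is written as literal nested loops straight from the
defining formulas, sharing no code with the package internals, so the
fast implementations can be checked against them on small volumes.
"""

import math

import numpy as np

EPS = 1e-3


def gaussian_patch_weights(radius, alpha):
    """3D Gaussian over offsets in [-r, r]^3, normalized to sum 1."""
    side = 2 * radius + 1
    k = np.empty((side, side, side))
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if alpha is None:
                    k[dx + radius, dy + radius, dz + radius] = 1.0
                else:
                    k[dx + radius, dy + radius, dz + radius] = math.exp(
                        -(dx * dx + dy * dy + dz * dz) / (2.0 * alpha * alpha)
                    )
    return k / k.sum()


def classic_nlm_oracle(data, R, M, h, alpha):
    """Voxel-wise classic NLM with Gaussian-kernel L2 distance."""
    w, hh, f = data.shape
    out = data.copy()
    kern = gaussian_patch_weights(R, alpha)
    margin = M + R
    for x in range(margin, w - margin):
        for y in range(margin, hh - margin):
            for z in range(margin, f - margin):
                num = 0.0
                den = 0.0
                for jx in range(x - M, x + M + 1):
                    for jy in range(y - M, y + M + 1):
                        for jz in range(z - M, z + M + 1):
                            d = 0.0
                            for px in range(-R, R + 1):
                                for py in range(-R, R + 1):
                                    for pz in range(-R, R + 1):
                                        diff = (
                                            data[x + px, y + py, z + pz]
                                            - data[jx + px, jy + py, jz + pz]
                                        )
                                        d += (
                                            kern[px + R, py + R, pz + R]
                                            * diff
                                            * diff
                                        )
                            wgt = math.exp(-d / (h * h))
                            num += wgt * data[jx, jy, jz]
                            den += wgt
                out[x, y, z] = num / den
    return out


def bayes_voxel_oracle(data, R, M, h, gamma):
    """Voxel-wise Bayesian NLM with the candidate-denominator distance."""
    w, hh, f = data.shape
    out = data.copy()
    margin = M + R
    for x in range(margin, w - margin):
        for y in range(margin, hh - margin):
            for z in range(margin, f - margin):
                num = 0.0
                den = 0.0
                for jx in range(x - M, x + M + 1):
                    for jy in range(y - M, y + M + 1):
                        for jz in range(z - M, z + M + 1):
                            d = 0.0
                            for px in range(-R, R + 1):
                                for py in range(-R, R + 1):
                                    for pz in range(-R, R + 1):
                                        ui = data[x + px, y + py, z + pz]
                                        uj = data[jx + px, jy + py, jz + pz]
                                        if gamma == 0:
                                            d += (ui - uj) ** 2
                                        else:
                                            d += (ui - uj) ** 2 / max(
                                                uj, EPS
                                            ) ** (2 * gamma)
                            wgt = math.exp(-d / (h * h))
                            num += wgt * data[jx, jy, jz]
                            den += wgt
                out[x, y, z] = num / den
    return out


def legal_block_centers(dim, R, M, n):
    """Enumerate legal block-center coordinates along one axis.

    A center c is legal when the whole search window [c-M-R, c+M+R]
    stays inside [0, dim); centers start at the smallest legal position
    and advance by n.
    """
    centers = []
    c = M + R
    while c + M + R <= dim - 1:
        centers.append(c)
        c += n
    return centers


def blockwise_oracle(data, R, M, n, h, gamma):
    """Block-wise Bayesian NLM: grid, per-block restoration, mean merge."""
    w, hh, f = data.shape
    cxs = legal_block_centers(w, R, M, n)
    cys = legal_block_centers(hh, R, M, n)
    czs = legal_block_centers(f, R, M, n)
    total = np.zeros_like(data)
    count = np.zeros_like(data)
    for cz in czs:
        for cy in cys:
            for cx in cxs:
                num = np.zeros((2 * R + 1, 2 * R + 1, 2 * R + 1))
                den = 0.0
                for jx in range(cx - (M - R), cx + (M - R) + 1):
                    for jy in range(cy - (M - R), cy + (M - R) + 1):
                        for jz in range(cz - (M - R), cz + (M - R) + 1):
                            d = 0.0
                            for px in range(-R, R + 1):
                                for py in range(-R, R + 1):
                                    for pz in range(-R, R + 1):
                                        ui = data[cx + px, cy + py, cz + pz]
                                        uj = data[jx + px, jy + py, jz + pz]
                                        if gamma == 0:
                                            d += (ui - uj) ** 2
                                        else:
                                            d += (ui - uj) ** 2 / max(
                                                uj, EPS
                                            ) ** (2 * gamma)
                            wgt = math.exp(-d / (h * h))
                            for px in range(-R, R + 1):
                                for py in range(-R, R + 1):
                                    for pz in range(-R, R + 1):
                                        num[px + R, py + R, pz + R] += (
                                            wgt
                                            * data[jx + px, jy + py, jz + pz]
                                        )
                            den += wgt
                sl = (
                    slice(cx - R, cx + R + 1),
                    slice(cy - R, cy + R + 1),
                    slice(cz - R, cz + R + 1),
                )
                total[sl] += num / den
                count[sl] += 1.0
    out = data.copy()
    covered = count > 0
    out[covered] = total[covered] / count[covered]
    return out
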