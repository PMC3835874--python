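"""Parallel execution of the per-block restoration work.

The unit of parallel work is the reference block: each block is
restored independently, so the flattened block grid is split into
near-equal contiguous chunks and the chunks are processed by a pool of
workers.  Every chunk produces a partial (sum, count) accumulator pair;
the partials are merged serially in chunk order, so for a fixed chunk
count the floating-point result does not depend on worker scheduling,
and the output matches the serial per-block engine to summation-order
precision (<= 1e-9 per voxel, bit-identical for one worker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .blockwise import BlockGrid, build_grid, restore_block
from .errors import BlockNLMError, ValidationError
from .nlm import FilterParams
from .volume import Volume

__all__ = ["WorkPartition", "partition_grid", "run_parallel"]


@dataclass(frozen=True)
class WorkPartition:
    """Disjoint contiguous index ranges covering the flattened block grid."""

    chunks: tuple[tuple[int, int], ...]
    workers: int

    def __len__(self) -> int:
        return len(self.chunks)


def partition_grid(grid: BlockGrid, workers: int) -> WorkPartition:
    """Split the grid into ``min(workers, len(grid))`` contiguous chunks.

    Chunk sizes differ by at most one, with the remainder going to the
    earliest chunks.
    """
    if workers < 1:
        raise ValidationError(f"workers must be >= 1, got {workers}")
    nblocks = len(grid)
    nchunks = min(workers, nblocks)
    base, rem = divmod(nblocks, nchunks)
    chunks = []
    start = 0
    for i in range(nchunks):
        size = base + (1 if i < rem else 0)
        chunks.append((start, start + size))
        start += size
    return WorkPartition(chunks=tuple(chunks), workers=workers)


def _restore_chunk(
    u: Volume,
    params: FilterParams,
    grid: BlockGrid,
    chunk: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Partial per-voxel (sum, count) over one contiguous block range."""
    start, stop = chunk
    r = params.ref_radius
    total = np.zeros(u.dims)
    count = np.zeros(u.dims)
    try:
        for i in range(start, stop):
            x, y, z = grid.center(i)
            cube = restore_block(u, (x, y, z), params)
            sl = (
                slice(x - r, x + r + 1),
                slice(y - r, y + r + 1),
                slice(z - r, z + r + 1),
            )
            total[sl] += cube
            count[sl] += 1.0
    except Exception as exc:
        raise BlockNLMError(
            f"block restoration failed in grid range [{start}, {stop}): {exc}"
        ) from exc
    return total, count


def run_parallel(u: Volume, params: FilterParams, workers: int = 1) -> Volume:
    """Block-wise Bayesian NLM with the work split across ``workers``.

    Mathematically identical to the serial block-wise filter; per-voxel
    differences are bounded by floating-point summation order.  With
    ``workers=1`` the chunk runs in-process and the result is
    bit-identical to the serial per-block engine.
    """
    grid = build_grid(u.dims, params)
    partition = partition_grid(grid, workers)
    if partition.workers == 1 or len(partition) == 1:
        partials = [_restore_chunk(u, params, grid, c) for c in partition.chunks]
    else:
        partials = Parallel(n_jobs=partition.workers)(
            delayed(_restore_chunk)(u, params, grid, c) for c in partition.chunks
        )
    total = np.zeros(u.dims)
    count = np.zeros(u.dims)
    for part_total, part_count in partials:  # fixed chunk order
        total += part_total
        count += part_count
    covered = count > 0
    out = u.data.copy()
    out[covered] = total[covered] / count[covered]
    return Volume(out)
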