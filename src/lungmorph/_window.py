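"""Exact sliding-cube window sums via separable prefix sums.

The moving-mask maps are defined as window counts; doing them with prefix
sums keeps integer inputs integer-exact (the porosity map must equal
brute-force per-voxel counting bit for bit) and is O(N) regardless of
kernel size.  Each axis pass works on a contiguous copy, which keeps the
cumulative sums cache-friendly on whole-organ volumes.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


def _sliding_sum_axis(a: np.ndarray, k: int, axis: int, dtype) -> np.ndarray:
    a = np.ascontiguousarray(np.moveaxis(a, axis, -1))
    c = np.cumsum(a, axis=-1, dtype=dtype)
    n_out = a.shape[-1] - k + 1
    s = np.empty(a.shape[:-1] + (n_out,), dtype=dtype)
    s[..., 0] = c[..., k - 1]
    if n_out > 1:
        np.subtract(c[..., k:], c[..., :-k], out=s[..., 1:])
    return np.moveaxis(s, -1, axis)


def box_sum(arr: np.ndarray, edge: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of ``arr`` over the cubic window of odd edge centred on each voxel.

    Returns ``(sums, inside)`` where ``inside`` is True for voxels whose
    window lies entirely inside the array; ``sums`` is 0 elsewhere.  Integer
    inputs accumulate in int64, so counts are exact.
    """
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ConfigurationError("box_sum expects a 3D array")
    if edge < 1 or edge % 2 == 0:
        raise ConfigurationError(f"window edge must be a positive odd integer, got {edge}")
    if any(edge > s for s in arr.shape):
        raise ConfigurationError(f"window edge {edge} exceeds array shape {arr.shape}")

    dtype = np.int64 if arr.dtype.kind in "bui" else np.float64
    valid = arr
    for axis in range(3):
        valid = _sliding_sum_axis(valid, edge, axis, dtype)

    h = edge // 2
    sums = np.zeros(arr.shape, dtype=dtype)
    inside = np.zeros(arr.shape, dtype=bool)
    sl = tuple(slice(h, s - h) for s in arr.shape)
    sums[sl] = valid
    inside[sl] = True
    return sums, inside
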