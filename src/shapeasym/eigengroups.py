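"""Spherical-harmonic eigen-groups and spatial wavelengths.

On a sphere the Laplace-Beltrami eigenvalues come in degenerate groups:
the L-th group holds the 2L+1 eigenvalues of spherical-harmonic degree L,
occupying 1-based eigenvalue indices L^2+1 .. (L+1)^2.  A closed genus-0
surface inherits this grouping as a natural division of its spectrum into
spatial scales, with the group's wavelength approximated by the spherical
relation W = 2*pi*Rs / sqrt(L*(L+1)) for an equivalent-sphere radius Rs.

Eigenvalue indexing is 1-based throughout, with index 1 the (near-)zero
mode of a closed surface.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "group_of_index",
    "group_index_range",
    "cumulative_count",
    "group_wavelength",
    "equivalent_radius",
    "group_means",
]


def group_of_index(i: int) -> int:
    """Eigen-group degree L of 1-based eigenvalue index i: ceil(sqrt(i)) - 1."""
    if i < 1:
        raise ValueError("eigenvalue indices are 1-based")
    s = math.isqrt(i)
    return s - 1 if s * s == i else s  # integer-exact ceil(sqrt(i)) - 1


def cumulative_count(L: int) -> int:
    """Number of eigenvalues in groups 0..L: (L+1)^2."""
    if L < 0:
        raise ValueError("group degree must be >= 0")
    return (L + 1) ** 2


def group_index_range(L: int) -> tuple[int, int]:
    """Inclusive 1-based eigenvalue index span [L^2+1, (L+1)^2] of group L."""
    if L < 0:
        raise ValueError("group degree must be >= 0")
    return (L ** 2 + 1, (L + 1) ** 2)


def group_wavelength(L: int, Rs: float) -> float:
    """Spatial wavelength W = 2*pi*Rs / sqrt(L*(L+1)) in mm.

    Undefined (infinite) for the constant mode L = 0.
    """
    if Rs <= 0:
        raise ValueError("equivalent radius must be positive")
    if L < 1:
        return float("inf")
    return 2.0 * math.pi * Rs / math.sqrt(L * (L + 1))


def equivalent_radius(area: float) -> float:
    """Radius of the sphere with the given surface area: sqrt(area / 4 pi)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return math.sqrt(area / (4.0 * math.pi))


def group_means(vector, lmin: int = 1, lmax: int = 11) -> np.ndarray:
    """Mean of a per-index vector over each eigen-group lmin..lmax.

    ``vector[i-1]`` holds the value at eigenvalue index i, which must
    cover the final group completely (indices up to (lmax+1)^2).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.size < cumulative_count(lmax):
        raise ValueError(
            f"vector of length {vector.size} does not cover group {lmax} "
            f"(needs {cumulative_count(lmax)} entries)")
    out = np.empty(lmax - lmin + 1)
    for j, L in enumerate(range(lmin, lmax + 1)):
        lo, hi = group_index_range(L)
        out[j] = vector[lo - 1:hi].mean()
    return out
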