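"""Analytic Gaussian density algebra for molecular shape.

Each heavy atom i contributes a spherical Gaussian

    rho_i(r) = p * exp(-alpha_i * |r - c_i|^2)

with the exponent fixed so that an isolated atom's integral equals its
hard-sphere volume 4/3*pi*R_i^3 (the Grant-Pickup parameterization):

    alpha_i = pi * (3 p / (4 pi R_i^3))^(2/3).

Products of Gaussians are Gaussians, so every quantity here (union volumes
via inclusion-exclusion, cross overlaps, density moments) reduces to sums of
closed-form integrals.  All lengths are Å, volumes Å^3.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "alphas_for_radii",
    "cross_overlap",
    "union_terms",
    "terms_volume",
    "terms_moment",
]

_PI32 = np.pi ** 1.5


def alphas_for_radii(radii: np.ndarray, p: float) -> np.ndarray:
    """Gaussian exponents making each isolated-atom integral 4/3*pi*R^3."""
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    return np.pi * (3.0 * p / (4.0 * np.pi * radii ** 3)) ** (2.0 / 3.0)


def cross_overlap(
    ca: np.ndarray,
    aa: np.ndarray,
    cb: np.ndarray,
    ab: np.ndarray,
    p: float,
) -> float:
    """Sum of pairwise product-Gaussian integrals between two atom sets.

    This is the overlap volume V_AB used in the shape Tanimoto; evaluated
    between a set and itself it yields the self-overlap volume V_AA.
    """
    ca = np.asarray(ca, float)
    cb = np.asarray(cb, float)
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
    asum = aa[:, None] + ab[None, :]
    k = np.exp(-(aa[:, None] * ab[None, :] / asum) * d2)
    return float(np.sum(p * p * k * (np.pi / asum) ** 1.5))


def union_terms(
    centers: np.ndarray,
    alphas: np.ndarray,
    p: float,
    order: int = 2,
    weight_tol: float = 1e-14,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inclusion-exclusion expansion of the union density up to ``order``.

    Returns ``(weights, exponents, centers)`` of signed Gaussian terms whose
    sum approximates the density 1 - prod_i (1 - rho_i); truncation at order
    k keeps subsets of size <= k.  Negligible product terms are pruned.
    """
    if order < 1:
        raise ValueError("inclusion-exclusion order must be >= 1")
    centers = np.asarray(centers, float)
    n = len(centers)
    ws: list[float] = []
    als: list[float] = []
    cs: list[np.ndarray] = []

    # stack entries: (last index, weight, alpha, alpha-weighted center sum, size)
    def expand(last: int, w: float, asum: float, cw: np.ndarray, size: int):
        center = cw / asum
        sign = 1.0 if size % 2 == 1 else -1.0
        ws.append(sign * w)
        als.append(asum)
        cs.append(center)
        if size == order:
            return
        for j in range(last + 1, n):
            aj = alphas[j]
            d2 = float(np.sum((center - centers[j]) ** 2))
            wj = w * p * np.exp(-(asum * aj / (asum + aj)) * d2)
            # prune by the term's own integral magnitude
            if wj * (np.pi / (asum + aj)) ** 1.5 < weight_tol:
                continue
            expand(j, wj, asum + aj, cw + aj * centers[j], size + 1)

    for i in range(n):
        expand(i, p, float(alphas[i]), alphas[i] * centers[i], 1)

    return (
        np.asarray(ws, float),
        np.asarray(als, float),
        np.asarray(cs, float).reshape(len(ws), 3),
    )


def terms_volume(ws: np.ndarray, als: np.ndarray) -> float:
    """Integral of a signed Gaussian expansion."""
    return float(np.sum(ws * (np.pi / als) ** 1.5))


def terms_moment(
    ws: np.ndarray, als: np.ndarray, cs: np.ndarray, powers: tuple[int, int, int]
) -> float:
    """Integral of x^i y^j z^k times the expansion, about the origin.

    Supports the moments needed for steric multipoles: per-axis powers up to
    3 with total degree <= 3.  For a single normalized Gaussian with center c
    and exponent a the 1-D factors are:

        <1> = sqrt(pi/a),  <x> = c <1>,  <x^2> = (c^2 + 1/(2a)) <1>,
        <x^3> = (c^3 + 3c/(2a)) <1>.
    """
    i, j, k = powers
    if i + j + k > 3 or min(i, j, k) < 0:
        raise ValueError("supported powers: total degree <= 3")
    base = np.sqrt(np.pi / als)  # 1-D Gaussian integral factor

    def axis_factor(power: int, c: np.ndarray) -> np.ndarray:
        if power == 0:
            return base
        if power == 1:
            return c * base
        if power == 2:
            return (c ** 2 + 1.0 / (2.0 * als)) * base
        return (c ** 3 + 3.0 * c / (2.0 * als)) * base

    fx = axis_factor(i, cs[:, 0])
    fy = axis_factor(j, cs[:, 1])
    fz = axis_factor(k, cs[:, 2])
    return float(np.sum(ws * fx * fy * fz))
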