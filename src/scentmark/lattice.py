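"""Small geometric helpers for periodic lattices (ring / torus).

Sites are 0-based integer coordinates with periodic wrap on every axis.
Internally every position is carried as an ``(x, y)`` pair; in 1D the
``y`` component is identically zero and the flat site index is just
``x`` (2D: ``x * L + y``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "site_index",
    "site_coords",
    "neighbor_sites",
    "min_image",
    "circular_mean",
    "boundary_of_mask",
    "order_boundary_sites",
]


def site_index(x: np.ndarray, y: np.ndarray, L: int, dims: int) -> np.ndarray:
    """Flat site index of coordinates ``(x, y)``."""
    if dims == 1:
        return np.asarray(x)
    return np.asarray(x) * L + np.asarray(y)


def site_coords(s: np.ndarray, L: int, dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`site_index`."""
    s = np.asarray(s)
    if dims == 1:
        return s, np.zeros_like(s)
    return s // L, s % L


def neighbor_sites(x: int, y: int, L: int, dims: int) -> list[tuple[int, int]]:
    """Von-Neumann neighbours with periodic wrap (2 in 1D, 4 in 2D)."""
    if dims == 1:
        return [((x + 1) % L, 0), ((x - 1) % L, 0)]
    return [
        ((x + 1) % L, y),
        ((x - 1) % L, y),
        (x, (y + 1) % L),
        (x, (y - 1) % L),
    ]


def min_image(d: np.ndarray, L: int) -> np.ndarray:
    """Signed displacement folded into ``(-L/2, L/2]``."""
    return np.asarray(d) - L * np.round(np.asarray(d) / L)


def circular_mean(coords: np.ndarray, L: int, weights: np.ndarray | None = None) -> float:
    """Periodic (circular) mean of 1D coordinates on a ring of ``L`` sites.

    The standard angle-average: map each coordinate to an angle on the
    unit circle, average the unit vectors, map back.  Well defined as
    long as the coordinates do not cancel exactly.
    """
    theta = 2.0 * np.pi * np.asarray(coords, dtype=float) / L
    if weights is None:
        c, s = np.mean(np.cos(theta)), np.mean(np.sin(theta))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        c, s = np.sum(w * np.cos(theta)), np.sum(w * np.sin(theta))
    if np.hypot(c, s) < 1e-12:
        raise ValueError("circular mean undefined: coordinates cancel")
    return float((np.arctan2(s, c) * L / (2.0 * np.pi)) % L)


def boundary_of_mask(mask: np.ndarray, L: int, dims: int) -> np.ndarray:
    """Flat indices of mask sites with >= 1 von-Neumann neighbour outside."""
    mask = np.asarray(mask, dtype=bool)
    if dims == 1:
        inside = mask & np.roll(mask, 1) & np.roll(mask, -1)
    else:
        m = mask.reshape(L, L)
        inside = (
            m
            & np.roll(m, 1, 0)
            & np.roll(m, -1, 0)
            & np.roll(m, 1, 1)
            & np.roll(m, -1, 1)
        ).ravel()
    return np.flatnonzero(mask & ~inside)


def order_boundary_sites(
    sites: np.ndarray, L: int, dims: int, centroid: tuple[float, float]
) -> np.ndarray:
    """Boundary sites ordered into a loop.

    1D: the (at most two) boundary sites in coordinate order.  2D: sites
    sorted by polar angle about the territory centroid — for the compact,
    roughly convex territories this model produces that yields a
    contiguous walk around the perimeter.
    """
    sites = np.asarray(sites)
    x, y = site_coords(sites, L, dims)
    if dims == 1:
        return sites[np.argsort(x)]
    dx = min_image(x - centroid[0], L)
    dy = min_image(y - centroid[1], L)
    return sites[np.argsort(np.arctan2(dy, dx))]
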