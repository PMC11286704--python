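"""Scripted equivalents of the four interactive mask-refinement tools.

The interactive software offers seeded add/remove (Chan-Vese active contour
started from a clicked point) and regional add/remove (maximum-entropy
threshold inside a drawn shape / unconditional clearing).  Here each tool is a
pure function on one 2D slice so that refinements can be replayed from an edit
script.

The Chan-Vese two-phase piecewise-constant energy

    E(C, c1, c2) = mu * Per(C) + l1 * sum_in (I - c1)^2 + l2 * sum_out (I - c2)^2

is minimized by coordinate descent: exact updates of the region means (c1, c2)
alternate with checkerboard sweeps in which every pixel whose flip strictly
decreases E is flipped.  Because same-color pixels are never 4-adjacent, the
perimeter interactions of simultaneous flips are independent and the energy is
guaranteed non-increasing at every step — a property the test suite asserts
per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.measure import grid_points_in_poly

from .errors import DegenerateInputError
from .preprocess import PooledHistogram, max_entropy_threshold

__all__ = [
    "SeedPoint",
    "FreeformRegion",
    "ChanVeseParams",
    "chan_vese_evolve",
    "add_by_seed",
    "remove_by_seed",
    "add_by_region",
    "remove_by_region",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class SeedPoint:
    slice_index: int
    row: int
    col: int
    series: str = "pre"  # "pre" | "post"


@dataclass
class FreeformRegion:
    slice_index: int
    polygon: list[tuple[float, float]]  # (row, col) vertices
    series: str = "pre"

    def validate(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not _ShapelyPolygon(self.polygon).is_simple:
            raise ValueError("polygon must be simple (non-self-intersecting)")


@dataclass
class ChanVeseParams:
    mu: float = 0.1
    lambda1: float = 1.0
    lambda2: float = 1.0
    max_iter: int = 200
    tol: float = 1e-3
    init_radius: int = 3
    max_fraction: float = 0.5  # leak guard: reject components above this slice fraction


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Number of 4-neighbors of each pixel that are foreground."""
    m = mask.astype(np.int32)
    out = np.zeros_like(m)
    out[1:, :] += m[:-1, :]
    out[:-1, :] += m[1:, :]
    out[:, 1:] += m[:, :-1]
    out[:, :-1] += m[:, 1:]
    return out


def _inner_neighbor_total(shape: tuple[int, int]) -> np.ndarray:
    """Number of in-image 4-neighbors per pixel (2, 3 or 4)."""
    n = np.full(shape, 4, dtype=np.int32)
    n[0, :] -= 1
    n[-1, :] -= 1
    n[:, 0] -= 1
    n[:, -1] -= 1
    return n


def chan_vese_energy(img: np.ndarray, mask: np.ndarray, p: ChanVeseParams) -> float:
    """Evaluate the discrete two-phase energy (perimeter = differing 4-pairs)."""
    inside = img[mask]
    outside = img[~mask]
    c1 = inside.mean() if inside.size else 0.0
    c2 = outside.mean() if outside.size else 0.0
    perim = int((mask[1:, :] != mask[:-1, :]).sum()) + int((mask[:, 1:] != mask[:, :-1]).sum())
    e = p.mu * perim
    e += p.lambda1 * float(((inside - c1) ** 2).sum())
    e += p.lambda2 * float(((outside - c2) ** 2).sum())
    return float(e)


def chan_vese_evolve(
    img: np.ndarray,
    init: np.ndarray,
    params: ChanVeseParams | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Minimize the Chan-Vese energy from ``init``; returns (mask, energies).

    ``energies`` holds the energy after each outer iteration and is
    non-increasing by construction.
    """
    p = params or ChanVeseParams()
    img = np.asarray(img, dtype=float)
    mask = np.asarray(init, dtype=bool).copy()
    rr, cc = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij")
    checker = (rr + cc) % 2
    n_total = _inner_neighbor_total(img.shape)

    energies: list[float] = []
    prev_c = None
    for _ in range(p.max_iter):
        inside = img[mask]
        outside = img[~mask]
        if inside.size == 0 or outside.size == 0:
            raise DegenerateInputError("no boundary found: one phase is empty")
        c1 = float(inside.mean())
        c2 = float(outside.mean())
        if abs(c1 - c2) < 1e-12:
            raise DegenerateInputError("no boundary found: phases indistinguishable")

        d_fg = p.lambda1 * (img - c1) ** 2  # cost of being foreground
        d_bg = p.lambda2 * (img - c2) ** 2

        flipped_any = False
        for color in (0, 1):
            n_fg = _neighbor_count(mask)
            n_bg = n_total - n_fg
            # Flip delta for bg -> fg and fg -> bg respectively.
            delta_up = (d_fg - d_bg) + p.mu * (n_bg - n_fg)
            delta_down = (d_bg - d_fg) + p.mu * (n_fg - n_bg)
            flips = np.where(mask, delta_down, delta_up) < 0
            flips &= checker == color
            if flips.any():
                mask[flips] = ~mask[flips]
                flipped_any = True

        energies.append(chan_vese_energy(img, mask, p))
        converged = not flipped_any
        if prev_c is not None and abs(c1 - prev_c[0]) < p.tol and abs(c2 - prev_c[1]) < p.tol:
            if converged:
                break
        prev_c = (c1, c2)
        if converged:
            break
    return mask, energies


def _seed_component(
    norm_slice: np.ndarray,
    seed: SeedPoint,
    params: ChanVeseParams,
) -> np.ndarray | None:
    """Run the contour from a disk at the seed; return the seed's component.

    Returns None (after warning) on degenerate slices, when the seed ends up in
    the background phase, or when the component trips the leak guard.
    """
    h, w = norm_slice.shape
    if not (0 <= seed.row < h and 0 <= seed.col < w):
        raise IndexError(f"seed ({seed.row}, {seed.col}) outside slice of shape {norm_slice.shape}")
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    init = (rr - seed.row) ** 2 + (cc - seed.col) ** 2 <= params.init_radius**2
    try:
        fg, _ = chan_vese_evolve(norm_slice, init, params)
    except DegenerateInputError as exc:
        warnings.warn(f"seeded edit rejected: {exc}", stacklevel=3)
        return None
    labels, _ = ndimage.label(fg, structure=_STRUCT_8)
    lab = labels[seed.row, seed.col]
    if lab == 0:
        warnings.warn("seeded edit rejected: no boundary found at seed", stacklevel=3)
        return None
    comp = labels == lab
    if comp.sum() > params.max_fraction * norm_slice.size:
        warnings.warn("seeded edit rejected: contour leaked beyond half the slice", stacklevel=3)
        return None
    return comp


def add_by_seed(
    norm_slice: np.ndarray,
    mask_slice: np.ndarray,
    seed: SeedPoint,
    params: ChanVeseParams | None = None,
) -> np.ndarray:
    """OR the seeded Chan-Vese component into the mask slice."""
    p = params or ChanVeseParams()
    comp = _seed_component(np.asarray(norm_slice, dtype=float), seed, p)
    out = np.asarray(mask_slice, dtype=bool).copy()
    if comp is not None:
        out |= comp
    return out


def remove_by_seed(
    norm_slice: np.ndarray,
    mask_slice: np.ndarray,
    seed: SeedPoint,
    params: ChanVeseParams | None = None,
) -> np.ndarray:
    """Subtract the seeded Chan-Vese component from the mask slice."""
    p = params or ChanVeseParams()
    comp = _seed_component(np.asarray(norm_slice, dtype=float), seed, p)
    out = np.asarray(mask_slice, dtype=bool).copy()
    if comp is not None:
        out &= ~comp
    return out


def rasterize_polygon(shape: tuple[int, int], polygon: list[tuple[float, float]]) -> np.ndarray:
    """Pixels whose centers fall inside the polygon (even-odd crossing rule)."""
    return grid_points_in_poly(shape, np.asarray(polygon, dtype=float)).astype(bool)


def add_by_region(
    norm_slice: np.ndarray,
    mask_slice: np.ndarray,
    region: FreeformRegion,
    bins: int = 256,
) -> np.ndarray:
    """Maximum-entropy threshold restricted to the drawn region; OR above-cut.

    The Kapur criterion is evaluated on the histogram of in-polygon voxels
    only; a degenerate (single-level) region is a warned no-op.
    """
    region.validate()
    norm_slice = np.asarray(norm_slice, dtype=float)
    inpoly = rasterize_polygon(norm_slice.shape, region.polygon)
    out = np.asarray(mask_slice, dtype=bool).copy()
    if not inpoly.any():
        warnings.warn("regional add rejected: polygon covers no pixel centers", stacklevel=2)
        return out
    counts, edges = np.histogram(norm_slice[inpoly], bins=bins, range=(0.0, 1.0))
    hist = PooledHistogram(counts=counts.astype(np.int64), bin_edges=edges)
    try:
        t = max_entropy_threshold(hist)
    except DegenerateInputError:
        warnings.warn("regional add rejected: degenerate in-region histogram", stacklevel=2)
        return out
    out |= inpoly & (norm_slice > t)
    return out


def remove_by_region(mask_slice: np.ndarray, region: FreeformRegion) -> np.ndarray:
    """Unconditionally clear every mask voxel inside the drawn region."""
    region.validate()
    out = np.asarray(mask_slice, dtype=bool).copy()
    out[rasterize_polygon(out.shape, region.polygon)] = False
    return out
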