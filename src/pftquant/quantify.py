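"""Volumetry: masks to millilitres, per-slice fluid curves, secretory response.

Volume is the segmented voxel count times the voxel volume from acquisition
geometry (slice thickness x row spacing x col spacing, mm^3), divided by 1000
to give mL.  Full floating-point precision is kept; rounding is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeResult", "compute_volume", "slice_curve", "secretory_response", "volume_result"]


@dataclass
class VolumeResult:
    pre_ml: float
    post_ml: float
    delta_ml: float
    curve_pre: np.ndarray
    curve_post: np.ndarray


def compute_volume(mask: np.ndarray, spacing_zyx: tuple[float, float, float]) -> float:
    """Total mask volume in mL."""
    if min(spacing_zyx) <= 0:
        raise ValueError("spacing components must be positive")
    voxel_mm3 = spacing_zyx[0] * spacing_zyx[1] * spacing_zyx[2]
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def slice_curve(mask: np.ndarray, spacing_zyx: tuple[float, float, float]) -> np.ndarray:
    """Per-slice fluid volume (mL); sums exactly to :func:`compute_volume`."""
    if min(spacing_zyx) <= 0:
        raise ValueError("spacing components must be positive")
    voxel_mm3 = spacing_zyx[0] * spacing_zyx[1] * spacing_zyx[2]
    counts = np.count_nonzero(np.asarray(mask, dtype=bool), axis=(1, 2))
    return counts.astype(float) * voxel_mm3 / 1000.0


def secretory_response(pre_ml: float, post_ml: float) -> float:
    """Secretory response dV = post - pre (mL); may be negative."""
    if pre_ml < 0 or post_ml < 0:
        raise ValueError("volumes must be nonnegative")
    return post_ml - pre_ml


def volume_result(
    pre_mask: np.ndarray,
    post_mask: np.ndarray,
    spacing_zyx: tuple[float, float, float],
) -> VolumeResult:
    curve_pre = slice_curve(pre_mask, spacing_zyx)
    curve_post = slice_curve(post_mask, spacing_zyx)
    pre_ml = float(curve_pre.sum())
    post_ml = float(curve_post.sum())
    return VolumeResult(
        pre_ml=pre_ml,
        post_ml=post_ml,
        delta_ml=secretory_response(pre_ml, post_ml),
        curve_pre=curve_pre,
        curve_post=curve_post,
    )
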