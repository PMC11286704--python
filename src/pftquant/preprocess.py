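"""Intensity normalization and pooled maximum-entropy (Kapur) thresholding.

The pre- and post-secretin stacks are treated as one pooled sample: a single
clip value (99.999th pooled percentile) normalizes both volumes to [0, 1], and
a single threshold is chosen on the pooled histogram so that the same intensity
cut defines candidate fluid in both series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .imageio import ExamPair

__all__ = [
    "NormalizedPair",
    "PooledHistogram",
    "normalize_pair",
    "pooled_histogram",
    "max_entropy_threshold",
    "apply_threshold",
]

DEFAULT_BINS = 256
DEFAULT_CLIP_PERCENTILE = 99.999


@dataclass
class NormalizedPair:
    """Pre/post volumes rescaled to [0, 1] by a shared clip value."""

    pre: np.ndarray
    post: np.ndarray
    clip_value: float


@dataclass
class PooledHistogram:
    """Equal-width histogram on [0, 1] over the pooled pre+post voxels."""

    counts: np.ndarray
    bin_edges: np.ndarray


def normalize_pair(pair: ExamPair, clip_percentile: float = DEFAULT_CLIP_PERCENTILE) -> NormalizedPair:
    """Clip the top tail of the pooled intensities to 1 and rescale.

    The clip value is the ``clip_percentile`` (linear-interpolation) percentile
    of the pooled pre+post intensities; values are divided by it and clamped to
    [0, 1].
    """
    pooled = np.concatenate([pair.pre.voxels.ravel(), pair.post.voxels.ravel()])
    clip_value = float(np.percentile(pooled, clip_percentile))
    if clip_value <= 0:
        raise DegenerateInputError("degenerate intensities: pooled clip value is not positive")
    pre = np.clip(pair.pre.voxels.astype(np.float32) / clip_value, 0.0, 1.0)
    post = np.clip(pair.post.voxels.astype(np.float32) / clip_value, 0.0, 1.0)
    return NormalizedPair(pre=pre, post=post, clip_value=clip_value)


def pooled_histogram(norm: NormalizedPair, bins: int = DEFAULT_BINS) -> PooledHistogram:
    """Histogram both normalized volumes jointly into ``bins`` bins on [0, 1].

    The last bin is right-closed (numpy convention), so values exactly 1 are
    counted.
    """
    pooled = np.concatenate([norm.pre.ravel(), norm.post.ravel()])
    counts, edges = np.histogram(pooled, bins=bins, range=(0.0, 1.0))
    return PooledHistogram(counts=counts.astype(np.int64), bin_edges=edges)


def max_entropy_threshold(hist: PooledHistogram) -> float:
    """Kapur maximum-entropy threshold on a pooled histogram.

    For each candidate cut (a bin edge), the criterion is the sum of the
    Shannon entropies (natural log) of the below-cut and above-cut class
    distributions, with class probabilities renormalized within each class and
    empty bins contributing zero.  The returned threshold is the bin edge of
    the maximizing cut; ties resolve to the lowest cut.
    """
    p = hist.counts.astype(float)
    total = p.sum()
    if np.count_nonzero(p) < 2:
        raise DegenerateInputError("degenerate histogram: fewer than 2 nonempty bins")
    p /= total

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    # Cumulative mass / sum(p ln p) strictly below each cut k = 1..B-1.
    P0 = np.cumsum(p)[:-1]
    S0 = np.cumsum(plogp)[:-1]
    P1 = 1.0 - P0
    S1 = plogp.sum() - S0

    valid = (P0 > 0) & (P1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.where(valid, -S0 / P0 + np.log(np.where(P0 > 0, P0, 1.0)), -np.inf)
        h1 = np.where(valid, -S1 / P1 + np.log(np.where(P1 > 0, P1, 1.0)), -np.inf)
    criterion = h0 + h1
    # Ties resolve to the lowest cut; the tolerance absorbs the rounding noise
    # that makes mathematically tied cuts differ at ~1e-15.
    best = int(np.argmax(criterion >= criterion.max() - 1e-10))
    return float(hist.bin_edges[best + 1])


def apply_threshold(norm: NormalizedPair, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Binary candidate-fluid masks: voxels with normalized intensity > t."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return norm.pre > t, norm.post > t
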