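"""Synthetic abdominal phantoms with ground truth, plus simulated raters.

The phantom emulates a coronal T2-weighted pre/post-secretin pair: a tapered
elliptic "body" of moderate signal containing bright fluid structures — a few
winding bowel tubes in the mid-abdomen plus any subset of six confounder
classes (spinal canal, intervertebral discs, renal pelvis/ureter, bladder,
gallbladder, incompletely saturated fat rim) rendered with class-characteristic
caricature geometry matched to the default heuristic rule table.  The
post-secretin volume is identical to the pre volume except that the bowel
tubes are grown outward (a distance-ordered dilation) until the requested
secreted volume has been added, preserving the matched-acquisition registration
of the real protocol.

Ground truth is exact: reported true volumes are mask voxel counts times the
voxel volume.  Everything is deterministic under a fixed seed.

Rater simulation supports the agreement statistics: masks perturbed at their
boundary to a target mutual Dice coefficient, and rating tables drawn from the
two-variance-component model under which the population ICC(2,1) is
sigma_b^2 / (sigma_b^2 + sigma_r^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PlacementError
from .imageio import ExamPair, ImageSeries

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "simulate_raters",
    "simulate_rating_table",
    "ALL_CONFOUNDERS",
]

ALL_CONFOUNDERS = (
    "spinal_canal",
    "intervertebral_disc",
    "renal_pelvis_ureter",
    "bladder",
    "gallbladder",
    "fat_rim",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PhantomConfig:
    """Phantom acquisition and anatomy parameters.

    Defaults mirror the target acquisition: 4 mm contiguous coronal slices at
    0.8 x 0.8 mm in-plane, a secretory response of 55 mL (a typical pediatric
    post-pre difference), fluid roughly 3.5x brighter than soft tissue, and
    all six confounder classes present.
    """

    shape: tuple[int, int, int] = (28, 160, 160)
    pixel_spacing_mm: tuple[float, float] = (0.8, 0.8)
    slice_thickness_mm: float = 4.0
    n_bowel_tubes: int = 3
    secretion_delta_ml: float = 55.0
    confounders: tuple[str, ...] = ALL_CONFOUNDERS
    fluid_intensity: float = 0.9
    tissue_intensity: float = 0.25
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fluid_intensity > self.tissue_intensity >= 0:
            raise ValueError("fluid_intensity must exceed tissue_intensity >= 0")
        if self.noise_sd < 0 or self.secretion_delta_ml < 0:
            raise ValueError("noise_sd and secretion_delta_ml must be >= 0")
        unknown = set(self.confounders) - set(ALL_CONFOUNDERS)
        if unknown:
            raise ValueError(f"unknown confounder classes: {sorted(unknown)}")

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        return (self.slice_thickness_mm, *self.pixel_spacing_mm)


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying one phantom exam pair."""

    bowel_mask_pre: np.ndarray
    bowel_mask_post: np.ndarray
    confounder_masks: dict[str, np.ndarray] = field(default_factory=dict)
    true_pre_ml: float = 0.0
    true_post_ml: float = 0.0


class _Geometry:
    """Voxel-center mm coordinate grids and the body envelope."""

    def __init__(self, config: PhantomConfig):
        nz, ny, nx = config.shape
        dz, dy, dx = config.spacing_zyx
        self.zc = (np.arange(nz) + 0.5)[:, None, None] * dz
        self.yc = (np.arange(ny) + 0.5)[None, :, None] * dy
        self.xc = (np.arange(nx) + 0.5)[None, None, :] * dx
        self.extent = (nz * dz, ny * dy, nx * dx)
        self.center = tuple(e / 2 for e in self.extent)
        # Elliptic body cross-section, mildly tapered toward the first/last slices.
        taper = 1.0 - ((self.zc - self.center[0]) / (0.75 * self.extent[0])) ** 2
        self.taper = np.sqrt(np.clip(taper, 0.0, None))
        self.body_semi = (0.47 * self.extent[1], 0.44 * self.extent[2])

    def body(self, shrink_mm: float = 0.0) -> np.ndarray:
        ay = np.maximum(self.body_semi[0] * self.taper - shrink_mm, 1e-6)
        ax = np.maximum(self.body_semi[1] * self.taper - shrink_mm, 1e-6)
        r2 = ((self.yc - self.center[1]) / ay) ** 2 + ((self.xc - self.center[2]) / ax) ** 2
        return r2 <= 1.0

    def ellipsoid(self, center_frac: tuple[float, float, float], semi_mm: tuple[float, float, float]) -> np.ndarray:
        cz, cy, cx = (f * e for f, e in zip(center_frac, self.extent))
        r2 = (
            ((self.zc - cz) / semi_mm[0]) ** 2
            + ((self.yc - cy) / semi_mm[1]) ** 2
            + ((self.xc - cx) / semi_mm[2]) ** 2
        )
        return r2 <= 1.0


def _render_confounders(config: PhantomConfig, geom: _Geometry) -> dict[str, np.ndarray]:
    """Class-characteristic confounder masks at fixed anatomic slots."""
    masks: dict[str, np.ndarray] = {}
    ez, ey, ex = geom.extent

    if "bladder" in config.confounders:
        masks["bladder"] = geom.ellipsoid((0.45, 0.76, 0.50), (20.0, 18.0, 24.0))

    if "gallbladder" in config.confounders:
        masks["gallbladder"] = geom.ellipsoid((0.35, 0.32, 0.27), (12.0, 16.0, 9.0))

    if "spinal_canal" in config.confounders:
        # Thin craniocaudal cylinder at the posterior midline, spanning ~70%
        # of the craniocaudal extent.
        r2 = ((geom.zc - 0.84 * ez) / 4.0) ** 2 + ((geom.xc - 0.50 * ex) / 4.0) ** 2
        span = (geom.yc >= 0.15 * ey) & (geom.yc <= 0.85 * ey)
        masks["spinal_canal"] = (r2 <= 1.0) & span

    if "intervertebral_disc" in config.confounders:
        disc = np.zeros(config.shape, dtype=bool)
        for fy in (0.16, 0.29, 0.42, 0.55):
            disc |= geom.ellipsoid((0.62, fy, 0.50), (11.0, 3.5, 11.0))
        masks["intervertebral_disc"] = disc

    if "renal_pelvis_ureter" in config.confounders:
        core = geom.ellipsoid((0.75, 0.42, 0.24), (7.0, 9.0, 6.0))
        # Two short inferior branches (proximal ureter caricature).
        b1 = (
            (((geom.zc - 0.75 * ez) / 3.0) ** 2 + ((geom.xc - 0.245 * ex) / 2.5) ** 2 <= 1.0)
            & (geom.yc >= 0.42 * ey)
            & (geom.yc <= 0.42 * ey + 18.0)
        )
        b2 = (
            (((geom.zc - 0.75 * ez) / 2.5) ** 2 + ((geom.xc - 0.225 * ex) / 2.5) ** 2 <= 1.0)
            & (geom.yc >= 0.42 * ey)
            & (geom.yc <= 0.42 * ey + 12.0)
        )
        masks["renal_pelvis_ureter"] = core | b1 | b2

    if "fat_rim" in config.confounders:
        nz = config.shape[0]
        rim = geom.body(0.0) & ~geom.body(1.8)
        zidx = np.arange(nz)[:, None, None]
        central = (zidx >= round(0.1 * nz)) & (zidx <= round(0.9 * nz))
        masks["fat_rim"] = rim & np.broadcast_to(central, config.shape)

    return masks


def _render_tubes(
    config: PhantomConfig,
    geom: _Geometry,
    forbidden: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Winding bowel tubes in the mid-abdomen, clipped clear of confounders."""
    ez, ey, ex = geom.extent
    lo = np.array([0.22 * ez, 0.22 * ey, 0.33 * ex])
    hi = np.array([0.55 * ez, 0.55 * ey, 0.70 * ex])
    spacing = np.array(config.spacing_zyx)
    shape = config.shape

    bowel = np.zeros(shape, dtype=bool)
    for _ in range(config.n_bowel_tubes):
        for _attempt in range(8):
            pos = lo + rng.random(3) * (hi - lo)
            direction = rng.normal(size=3)
            direction[0] *= 0.3
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(5.0, 7.0)
            points = np.zeros(shape, dtype=bool)
            for _step in range(50):
                idx = np.minimum(
                    np.maximum((pos / spacing).astype(int), 0),
                    np.array(shape) - 1,
                )
                points[tuple(idx)] = True
                turn = rng.normal(scale=0.35, size=3)
                turn[0] *= 0.3
                direction = direction + turn
                direction /= np.linalg.norm(direction)
                pos = pos + 2.5 * direction
                for axis in range(3):
                    if pos[axis] < lo[axis] or pos[axis] > hi[axis]:
                        pos[axis] = np.clip(pos[axis], lo[axis], hi[axis])
                        direction[axis] = -direction[axis]
            dist = ndimage.distance_transform_edt(~points, sampling=spacing)
            tube = (dist <= radius) & ~forbidden
            if tube.sum() * np.prod(spacing) / 1000.0 >= 3.0:
                bowel |= tube
                break
        else:
            raise PlacementError("placement failure: could not place a bowel tube")
    return bowel


def _grow_secretion(
    bowel: np.ndarray,
    allowed: np.ndarray,
    n_add: int,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Add the n_add nearest allowed voxels to the tubes (dilation-like growth)."""
    if n_add == 0:
        return bowel.copy()
    candidates = allowed & ~bowel
    n_candidates = int(candidates.sum())
    if n_candidates < n_add:
        raise PlacementError(
            f"placement failure: secretion target needs {n_add} voxels, "
            f"only {n_candidates} available"
        )
    dist = ndimage.distance_transform_edt(~bowel, sampling=spacing)
    dist = np.where(candidates, dist, np.inf)
    flat = dist.ravel()
    # Stable ordering: distance, then raster index (deterministic tie-break).
    chosen = np.argsort(flat, kind="stable")[:n_add]
    grown = bowel.copy()
    grown.ravel()[chosen] = True
    return grown


def generate_phantom(config: PhantomConfig) -> tuple[ExamPair, PhantomTruth]:
    """Render one matched pre/post exam pair with exact ground truth."""
    nz, ny, nx = config.shape
    if nz < 8 or ny < 96 or nx < 96:
        raise ValueError("phantom shape too small to place objects (>= 8x96x96)")
    rng = np.random.default_rng(config.seed)
    geom = _Geometry(config)

    confounders = _render_confounders(config, geom)
    conf_union = np.zeros(config.shape, dtype=bool)
    for name, m in confounders.items():
        if (conf_union & m).any():
            raise PlacementError(f"placement failure: confounder overlap at {name}")
        conf_union |= m

    # Keep bowel well clear of confounders (>= ~6 mm in-plane, >= 3 slices in
    # z) so that clusters never merge under 26-connectivity even when a few
    # above-threshold noise voxels decorate the gaps.  The z spacing in the
    # metric is compressed so a 6 mm margin spans two slices.
    dz, dy, dx = config.spacing_zyx
    margin_dist = ndimage.distance_transform_edt(
        ~conf_union, sampling=(dz * 6.0 / 9.0, dy, dx)
    )
    forbidden = margin_dist <= 6.0
    bowel_pre = _render_tubes(config, geom, forbidden, rng)

    voxel_ml = np.prod(config.spacing_zyx) / 1000.0
    n_add = int(round(config.secretion_delta_ml / voxel_ml))
    allowed = geom.body(12.0) & ~forbidden
    bowel_post = _grow_secretion(bowel_pre, allowed, n_add, config.spacing_zyx)

    body = geom.body(0.0)
    base = np.where(body, config.tissue_intensity, 0.0)

    # Fluid signal varies smoothly within each structure (as T2 fluid signal
    # does in vivo); spreading the fluid mode keeps the pooled entropy
    # threshold well clear of the tissue mode.
    scale = config.fluid_intensity / 0.9
    fluid_img = np.zeros(config.shape, dtype=float)

    def paint(mask: np.ndarray, extent_mask: np.ndarray) -> None:
        lo = rng.uniform(0.78, 0.84) * scale
        hi = rng.uniform(0.97, 1.03) * scale
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        proj = geom.zc * u[0] + geom.yc * u[1] + geom.xc * u[2]
        pmin, pmax = proj[extent_mask].min(), proj[extent_mask].max()
        frac = (proj - pmin) / max(pmax - pmin, 1e-9)
        np.maximum(fluid_img, np.where(mask, lo + (hi - lo) * frac, 0.0), out=fluid_img)

    for m in confounders.values():
        paint(m, m)
    # One gradient over the grown (post) bowel so shared voxels match between
    # the two acquisitions.
    paint(bowel_post, bowel_post)
    img_post = np.where(fluid_img > 0, fluid_img, base)
    fluid_img_pre = np.where(bowel_post & ~bowel_pre, 0.0, fluid_img)
    img_pre = np.where(fluid_img_pre > 0, fluid_img_pre, base)
    if config.noise_sd > 0:
        img_pre = img_pre + rng.normal(0.0, config.noise_sd, size=config.shape)
        img_post = img_post + rng.normal(0.0, config.noise_sd, size=config.shape)
    img_pre = np.clip(img_pre, 0.0, None).astype(np.float32)
    img_post = np.clip(img_post, 0.0, None).astype(np.float32)

    pair = ExamPair(
        pre=ImageSeries(img_pre, config.pixel_spacing_mm, config.slice_thickness_mm, "phantom pre"),
        post=ImageSeries(img_post, config.pixel_spacing_mm, config.slice_thickness_mm, "phantom post"),
    )
    truth = PhantomTruth(
        bowel_mask_pre=bowel_pre,
        bowel_mask_post=bowel_post,
        confounder_masks=confounders,
        true_pre_ml=float(bowel_pre.sum() * voxel_ml),
        true_post_ml=float(bowel_post.sum() * voxel_ml),
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------

def _dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _perturb_boundary(mask: np.ndarray, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Randomly toggle boundary voxels; ``strength`` layers of perturbation."""
    out = mask.copy()
    remaining = strength
    while remaining > 1e-9:
        p = min(1.0, remaining)
        outer = ndimage.binary_dilation(out, structure=_STRUCT_26) & ~out
        inner = out & ~ndimage.binary_erosion(out, structure=_STRUCT_26)
        boundary = outer | inner
        flips = boundary & (rng.random(out.shape) < 0.5 * p)
        out[flips] = ~out[flips]
        remaining -= 1.0
    return out


def simulate_raters(
    truth_mask: np.ndarray,
    target_dsc: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two boundary-perturbed copies of a mask with a target mutual Dice.

    The perturbation strength is searched so that dice(m1, m2) lands within
    +/- 0.05 of ``target_dsc``; deterministic per seed.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if not truth_mask.any():
        raise ValueError("truth_mask must be nonempty")
    if not 0.5 < target_dsc <= 1.0:
        raise ValueError("target_dsc must lie in (0.5, 1]")
    if target_dsc == 1.0:
        return truth_mask.copy(), truth_mask.copy()

    def pair_at(strength: float) -> tuple[np.ndarray, np.ndarray]:
        r1 = np.random.default_rng((seed, 1))
        r2 = np.random.default_rng((seed, 2))
        return (
            _perturb_boundary(truth_mask, strength, r1),
            _perturb_boundary(truth_mask, strength, r2),
        )

    lo, hi = 0.0, 6.0
    best: tuple[np.ndarray, np.ndarray] | None = None
    best_err = np.inf
    for _ in range(30):
        mid = (lo + hi) / 2
        m1, m2 = pair_at(mid)
        d = _dice(m1, m2)
        err = abs(d - target_dsc)
        if err < best_err:
            best, best_err = (m1, m2), err
        if err <= 0.02:
            break
        if d > target_dsc:
            lo = mid
        else:
            hi = mid
    if best is None or best_err > 0.05:
        raise PlacementError("target DSC infeasible for this mask")
    return best


def simulate_rating_table(
    n_exams: int,
    sigma_between: float,
    sigma_rater: float,
    mu: float,
    seed: int,
) -> np.ndarray:
    """n x 2 table of secretory-response ratings from a variance-component model.

    Exam truths are Normal(mu, sigma_between^2); each rater observes
    truth + Normal(0, sigma_rater^2) independently.  The population ICC(2,1)
    is sigma_between^2 / (sigma_between^2 + sigma_rater^2).
    """
    if n_exams < 3:
        raise ValueError("n_exams must be >= 3")
    if sigma_between < 0 or sigma_rater < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    truth = rng.normal(mu, sigma_between, size=n_exams)
    errors = rng.normal(0.0, sigma_rater, size=(n_exams, 2))
    return truth[:, None] + errors
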