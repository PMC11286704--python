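"""Connected-component morphometry and heuristic non-bowel object removal.

Candidate fluid masks contain, besides bowel, a predictable menagerie of
T2-bright structures: cerebrospinal fluid in the spinal canal, intervertebral
discs, urine in the renal pelvis and bladder, bile in the gallbladder, and
incompletely fat-saturated subcutaneous fat at the body contour.  Each cluster
is measured (volume, normalized centroid, bounding box, sphericity, principal
axis angle, craniocaudal span) on an isotropically resampled copy and compared
against interval rules per object class; matching clusters are deleted from
the native-spacing mask so that reported volumes always come from acquisition
geometry.

Sphericity here uses exposed-voxel-face surface area, which is exact and
deterministic but systematically larger than the smooth surface area: a digital
ball measures ~0.65, a cube is the discrete maximum at
pi^(1/3)*6^(2/3)/6 ~ 0.806.  The default rule thresholds are calibrated to
this scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigError

__all__ = [
    "ClusterMorphometry",
    "HeuristicRule",
    "DEFAULT_RULES",
    "label_clusters",
    "remove_small_clusters",
    "resample_isotropic",
    "compute_morphometry",
    "classify_nonbowel",
    "remove_nonbowel",
    "load_rules",
    "save_rules",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

OBJECT_CLASSES = (
    "spinal_canal",
    "intervertebral_disc",
    "renal_pelvis_ureter",
    "bladder",
    "gallbladder",
    "fat_rim",
)

# Craniocaudal axis for coronal stacks: in-plane row axis (index 1 of z,y,x).
DEFAULT_CRANIOCAUDAL_AXIS = 1


@dataclass
class ClusterMorphometry:
    """Shape features of one connected cluster, in physical units."""

    label: int
    volume_ml: float
    centroid_norm: tuple[float, float, float]  # (z, y, x), fractions of extent
    bbox_extent_mm: tuple[float, float, float]
    sphericity: float
    principal_axis_angle_deg: float  # from the craniocaudal axis, [0, 90]
    craniocaudal_span_frac: float
    unstable: bool = False  # < 4 voxels: covariance-based features unreliable

    _FEATURES = (
        "volume_ml",
        "centroid_z",
        "centroid_y",
        "centroid_x",
        "bbox_z_mm",
        "bbox_y_mm",
        "bbox_x_mm",
        "sphericity",
        "principal_axis_angle_deg",
        "craniocaudal_span_frac",
    )

    def feature(self, name: str) -> float:
        if name == "centroid_z":
            return self.centroid_norm[0]
        if name == "centroid_y":
            return self.centroid_norm[1]
        if name == "centroid_x":
            return self.centroid_norm[2]
        if name == "bbox_z_mm":
            return self.bbox_extent_mm[0]
        if name == "bbox_y_mm":
            return self.bbox_extent_mm[1]
        if name == "bbox_x_mm":
            return self.bbox_extent_mm[2]
        if name in ("volume_ml", "sphericity", "principal_axis_angle_deg", "craniocaudal_span_frac"):
            return getattr(self, name)
        raise ConfigError(f"unknown morphometry feature: {name}")


@dataclass
class HeuristicRule:
    """Interval predicates over cluster features for one object class."""

    object_class: str
    predicates: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for feat, lo, hi in self.predicates:
            if feat not in ClusterMorphometry._FEATURES:
                raise ConfigError(f"rule '{self.object_class}' references unknown feature '{feat}'")
            if lo > hi:
                raise ConfigError(f"rule '{self.object_class}': min > max for '{feat}'")

    def matches(self, m: ClusterMorphometry) -> bool:
        return all(lo <= m.feature(feat) <= hi for feat, lo, hi in self.predicates)


INF = float("inf")

# Default rule table.  The literature names the object classes and the feature
# set but not numeric ranges; these intervals were calibrated on the synthetic
# phantoms in :mod:`pftquant.synthetic` and ship as an editable config.
# Coordinates: centroid_z anterior(0)->posterior(1), centroid_y superior(0)->
# inferior(1), centroid_x right(0)->left(1), all fractions of the field of view.
DEFAULT_RULES: list[HeuristicRule] = [
    HeuristicRule("bladder", [
        ("volume_ml", 25.0, INF),
        ("sphericity", 0.45, 1.0),
        ("centroid_y", 0.65, 1.0),
        ("centroid_x", 0.30, 0.70),
    ]),
    HeuristicRule("gallbladder", [
        ("volume_ml", 4.0, 80.0),
        ("sphericity", 0.50, 1.0),
        ("centroid_y", 0.0, 0.45),
        ("centroid_x", 0.0, 0.42),
    ]),
    HeuristicRule("fat_rim", [
        ("sphericity", 0.0, 0.30),
        ("bbox_y_mm", 85.0, INF),
        ("bbox_x_mm", 85.0, INF),
    ]),
    HeuristicRule("spinal_canal", [
        ("craniocaudal_span_frac", 0.55, 1.0),
        ("sphericity", 0.0, 0.48),
        ("centroid_x", 0.40, 0.60),
        ("centroid_z", 0.62, 1.0),
        ("principal_axis_angle_deg", 0.0, 25.0),
        ("bbox_x_mm", 0.0, 30.0),
        ("bbox_z_mm", 0.0, 30.0),
    ]),
    HeuristicRule("intervertebral_disc", [
        ("volume_ml", 0.0, 8.0),
        ("sphericity", 0.40, 1.0),
        ("centroid_x", 0.30, 0.70),
        ("centroid_z", 0.55, 1.0),
        ("craniocaudal_span_frac", 0.0, 0.15),
    ]),
    HeuristicRule("renal_pelvis_ureter", [
        ("volume_ml", 1.0, 15.0),
        ("centroid_x", 0.10, 0.38),
        ("centroid_y", 0.20, 0.60),
        ("centroid_z", 0.60, 0.95),
    ]),
    HeuristicRule("renal_pelvis_ureter", [
        ("volume_ml", 1.0, 15.0),
        ("centroid_x", 0.62, 0.90),
        ("centroid_y", 0.20, 0.60),
        ("centroid_z", 0.60, 0.95),
    ]),
]


def load_rules(path: str | Path) -> list[HeuristicRule]:
    """Load a rule table from a JSON file; validates feature names eagerly."""
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read rule table {path}: {exc}") from exc
    rules = []
    for entry in raw:
        preds = [(str(f), float(lo) if lo is not None else -INF, float(hi) if hi is not None else INF)
                 for f, lo, hi in entry["predicates"]]
        rules.append(HeuristicRule(entry["object_class"], preds))
    return rules


def save_rules(rules: list[HeuristicRule], path: str | Path) -> None:
    raw = [
        {"object_class": r.object_class,
         "predicates": [[f, None if lo == -INF else lo, None if hi == INF else hi]
                        for f, lo, hi in r.predicates]}
        for r in rules
    ]
    Path(path).write_text(json.dumps(raw, indent=2))


# ---------------------------------------------------------------------------
# Cluster extraction and measurement
# ---------------------------------------------------------------------------

def label_clusters(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected 3D components, labeled 1..K in first-voxel raster order."""
    labels, count = ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCT_26)
    return labels, int(count)


def remove_small_clusters(
    mask: np.ndarray,
    spacing_zyx: tuple[float, float, float],
    min_ml: float = 1.0,
) -> np.ndarray:
    """Drop clusters with volume strictly below ``min_ml`` (native spacing)."""
    labels, count = label_clusters(mask)
    if count == 0 or min_ml <= 0:
        return np.asarray(mask, dtype=bool).copy()
    voxel_ml = float(np.prod(spacing_zyx)) / 1000.0
    counts = np.bincount(labels.ravel(), minlength=count + 1)
    keep = counts * voxel_ml >= min_ml
    keep[0] = False
    return keep[labels]


def resample_isotropic(
    mask: np.ndarray,
    spacing_zyx: tuple[float, float, float],
) -> tuple[np.ndarray, float]:
    """Nearest-neighbor resample to cubic voxels of edge = min in-plane spacing.

    Works for binary masks and for integer label arrays (labels preserved).
    Returns the resampled array and the isotropic edge length (mm).
    """
    target = float(min(spacing_zyx[1], spacing_zyx[2]))
    factors = tuple(s / target for s in spacing_zyx)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return np.asarray(mask).copy(), target
    out = ndimage.zoom(np.asarray(mask), factors, order=0, mode="nearest", grid_mode=True)
    return out, target


def _surface_area_faces(m: np.ndarray, edge_mm: float) -> float:
    """Surface area by counting exposed voxel faces (cube of 1 voxel -> 6)."""
    padded = np.pad(m, 1)
    faces = 0
    for axis in range(3):
        diff = padded != np.roll(padded, 1, axis=axis)
        faces += int(diff.sum())
    return faces * edge_mm * edge_mm


def compute_morphometry(
    labels: np.ndarray,
    iso_spacing_mm: float,
    craniocaudal_axis: int = DEFAULT_CRANIOCAUDAL_AXIS,
) -> list[ClusterMorphometry]:
    """Measure every labeled cluster of an isotropically resampled label map."""
    labels = np.asarray(labels)
    n = int(labels.max())
    results = []
    voxel_ml = iso_spacing_mm**3 / 1000.0
    shape = labels.shape
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        m = labels[sl] == lab
        count = int(m.sum())
        coords = np.argwhere(m).astype(float)
        coords += [s.start for s in sl]

        centroid = coords.mean(axis=0)
        centroid_norm = tuple(float((c + 0.5) / shape[i]) for i, c in enumerate(centroid))
        bbox_extent = tuple(float((s.stop - s.start) * iso_spacing_mm) for s in sl)
        volume_ml = count * voxel_ml

        area = _surface_area_faces(m, iso_spacing_mm)
        v_mm3 = count * iso_spacing_mm**3
        sphericity = float(np.pi ** (1 / 3) * (6.0 * v_mm3) ** (2 / 3) / area)

        unstable = count < 4
        if unstable or count < 2:
            angle = 0.0
        else:
            cov = np.cov(coords.T)
            evals, evecs = np.linalg.eigh(cov)
            principal = evecs[:, -1]
            cosang = abs(float(principal[craniocaudal_axis]))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))

        cc = craniocaudal_axis
        span = (objects[lab - 1][cc].stop - objects[lab - 1][cc].start) / shape[cc]

        results.append(ClusterMorphometry(
            label=lab,
            volume_ml=volume_ml,
            centroid_norm=centroid_norm,
            bbox_extent_mm=bbox_extent,
            sphericity=sphericity,
            principal_axis_angle_deg=angle,
            craniocaudal_span_frac=float(span),
            unstable=unstable,
        ))
    return results


def classify_nonbowel(
    features: ClusterMorphometry,
    rules: list[HeuristicRule] | None = None,
) -> str | None:
    """First rule (declared order) whose predicates all hold; None if retained."""
    for rule in DEFAULT_RULES if rules is None else rules:
        if rule.matches(features):
            return rule.object_class
    return None


def remove_nonbowel(
    mask: np.ndarray,
    spacing_zyx: tuple[float, float, float],
    rules: list[HeuristicRule] | None = None,
    craniocaudal_axis: int = DEFAULT_CRANIOCAUDAL_AXIS,
) -> tuple[np.ndarray, list[dict]]:
    """Delete heuristically identified non-bowel clusters from the native mask.

    Morphometry is computed on an isotropic resampling; removal is applied in
    native spacing through the shared label map.  Returns the filtered mask and
    a log of ``{class, volume_ml, centroid_norm}`` entries per removal.
    """
    labels, count = label_clusters(mask)
    if count == 0:
        return np.asarray(mask, dtype=bool).copy(), []
    labels_iso, iso = resample_isotropic(labels, spacing_zyx)
    morph = compute_morphometry(labels_iso, iso, craniocaudal_axis)

    removed_labels = []
    log = []
    for m in morph:
        cls = classify_nonbowel(m, rules)
        if cls is not None:
            removed_labels.append(m.label)
            log.append({
                "object_class": cls,
                "volume_ml": m.volume_ml,
                "centroid_norm": m.centroid_norm,
                "label": m.label,
            })
    out = np.asarray(mask, dtype=bool).copy()
    if removed_labels:
        out[np.isin(labels, removed_labels)] = False
    return out, log
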