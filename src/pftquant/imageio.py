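"""DICOM series I/O, geometry validation, and result-bundle serialization.

Array axis convention used throughout the package: ``(slice, row, col)``,
0-based.  For the coronal T2-weighted stacks this pipeline targets, the slice
axis runs anterior-posterior, rows run craniocaudally (superior at row 0) and
columns run right-left.  Voxel spacing is carried as millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import GeometryError, ParseError, PFTQuantError

__all__ = [
    "ImageSeries",
    "ExamPair",
    "ResultBundle",
    "read_series",
    "write_series",
    "load_exam",
    "write_bundle",
    "read_bundle",
]

# Secondary Capture Image Storage: simplest SOP class for synthetic series.
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"


@dataclass
class ImageSeries:
    """One 3D grayscale stack plus its acquisition geometry.

    Parameters
    ----------
    voxels
        Nonnegative intensities, shape ``(n_slices, n_rows, n_cols)``.
    pixel_spacing_mm
        In-plane spacing ``(row, col)`` in mm.
    slice_thickness_mm
        Slice thickness in mm (slices are assumed contiguous).
    series_label
        Free-text label (series description or directory name).
    patient_meta
        Pass-through key/value metadata; may be empty (de-identified input).
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    series_label: str = ""
    patient_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise GeometryError("voxel array must be 3D with >= 1 slice")
        if self.voxels.shape[1] < 16 or self.voxels.shape[2] < 16:
            raise GeometryError("each slice must be at least 16x16")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise PFTQuantError("intensities must be finite and nonnegative")
        self.pixel_spacing_mm = (
            float(self.pixel_spacing_mm[0]),
            float(self.pixel_spacing_mm[1]),
        )
        self.slice_thickness_mm = float(self.slice_thickness_mm)
        if min(self.pixel_spacing_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise GeometryError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel spacing along (slice, row, col) in mm."""
        return (self.slice_thickness_mm, *self.pixel_spacing_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.slice_thickness_mm * self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]


@dataclass
class ExamPair:
    """Geometry-matched pre- and post-secretin series processed jointly."""

    pre: ImageSeries
    post: ImageSeries

    def __post_init__(self) -> None:
        a, b = self.pre, self.post
        if a.shape != b.shape or a.spacing_zyx != b.spacing_zyx:
            raise GeometryError(
                "geometry mismatch: pre "
                f"shape={a.shape} spacing={a.spacing_zyx}, post "
                f"shape={b.shape} spacing={b.spacing_zyx}"
            )


@dataclass
class ResultBundle:
    """Everything saved at the end of one exam analysis."""

    pre_mask: np.ndarray
    post_mask: np.ndarray
    pre_volume_ml: float
    post_volume_ml: float
    delta_volume_ml: float
    slice_curve_pre: np.ndarray
    slice_curve_post: np.ndarray
    spacing_zyx: tuple[float, float, float]
    analysis_meta: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if abs(self.delta_volume_ml - (self.post_volume_ml - self.pre_volume_ml)) > 1e-9:
            raise PFTQuantError("delta_volume_ml must equal post - pre")
        for curve, total in (
            (self.slice_curve_pre, self.pre_volume_ml),
            (self.slice_curve_post, self.post_volume_ml),
        ):
            if abs(float(np.sum(curve)) - total) > 1e-9:
                raise PFTQuantError("slice curve must sum to its total volume")


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

def _slice_position(ds: Dataset) -> float | None:
    """Projection of ImagePositionPatient onto the slice normal."""
    ipp = getattr(ds, "ImagePositionPatient", None)
    iop = getattr(ds, "ImageOrientationPatient", None)
    if ipp is None or iop is None or len(ipp) != 3 or len(iop) != 6:
        return None
    r = np.asarray(iop[:3], dtype=float)
    c = np.asarray(iop[3:], dtype=float)
    normal = np.cross(r, c)
    return float(np.dot(normal, np.asarray(ipp, dtype=float)))


def read_series(directory: str | Path) -> ImageSeries:
    """Read one single-frame DICOM series from ``directory``.

    Slices are sorted by spatial position along the slice normal; series with
    no position information fall back to instance-number order.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ParseError(f"no files in {directory}")

    datasets = []
    for path in files:
        try:
            ds = pydicom.dcmread(path)
            ds.pixel_array  # force decode now so failures name the file
        except Exception as exc:  # pragma: no cover - exercised via bad files
            raise ParseError(f"parse failure: {path}: {exc}") from exc
        datasets.append(ds)

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ParseError(f"mixed series in {directory}: {sorted(map(str, uids))}")

    keyed = []
    for ds in datasets:
        pos = _slice_position(ds)
        if pos is None:
            pos = float(getattr(ds, "InstanceNumber", 0))
        keyed.append((pos, ds))
    keyed.sort(key=lambda t: t[0])
    datasets = [ds for _, ds in keyed]

    first = datasets[0]
    spacing = getattr(first, "PixelSpacing", None)
    thickness = getattr(first, "SliceThickness", None)
    if spacing is None or thickness is None:
        raise GeometryError(f"incomplete geometry in {directory}: missing spacing attributes")

    voxels = np.stack([ds.pixel_array.astype(np.float32) for ds in datasets])
    meta = {}
    for key in ("PatientID", "PatientName", "StudyDate"):
        if hasattr(first, key):
            meta[key] = str(getattr(first, key))
    return ImageSeries(
        voxels=voxels,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        slice_thickness_mm=float(thickness),
        series_label=str(getattr(first, "SeriesDescription", directory.name)),
        patient_meta=meta,
    )


def write_series(
    series: ImageSeries,
    directory: str | Path,
    *,
    file_order: list[int] | None = None,
) -> list[Path]:
    """Write ``series`` as single-frame DICOM files (synthetic fixture writer).

    Intensities are stored as uint16, so the caller should pass integer-valued
    voxels for bit-exact round trips.  ``file_order`` permutes the on-disk file
    naming (not the spatial positions) to exercise sort-order robustness.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = series.shape[0]
    order = list(range(n)) if file_order is None else list(file_order)
    if sorted(order) != list(range(n)):
        raise ValueError("file_order must be a permutation of slice indices")

    series_uid = generate_uid(entropy_srcs=[series.series_label or "pftquant", str(n)])
    paths = []
    vox = np.round(series.voxels).astype(np.uint16)
    for file_idx, slice_idx in enumerate(order):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = _SC_SOP_CLASS
        sop_uid = generate_uid(entropy_srcs=[str(series_uid), str(slice_idx)])
        ds.file_meta.MediaStorageSOPInstanceUID = sop_uid
        ds.SOPClassUID = _SC_SOP_CLASS
        ds.SOPInstanceUID = sop_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = series.series_label or "synthetic"
        ds.Modality = "MR"
        ds.InstanceNumber = slice_idx + 1
        # Coronal orientation: rows along -z (craniocaudal), cols along x.
        ds.ImageOrientationPatient = [1, 0, 0, 0, 0, -1]
        ds.ImagePositionPatient = [0.0, slice_idx * series.slice_thickness_mm, 0.0]
        ds.PixelSpacing = [series.pixel_spacing_mm[0], series.pixel_spacing_mm[1]]
        ds.SliceThickness = series.slice_thickness_mm
        ds.Rows, ds.Columns = series.shape[1], series.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        for key, value in series.patient_meta.items():
            setattr(ds, key, value)
        ds.PixelData = np.ascontiguousarray(vox[slice_idx]).tobytes()
        path = directory / f"IM{file_idx:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def load_exam(pre_dir: str | Path, post_dir: str | Path) -> ExamPair:
    """Read and geometry-validate a matched pre/post series pair."""
    return ExamPair(pre=read_series(pre_dir), post=read_series(post_dir))


# ---------------------------------------------------------------------------
# Result bundles
# ---------------------------------------------------------------------------

def _mask_affine(spacing_zyx: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing_zyx[0], spacing_zyx[1], spacing_zyx[2], 1.0])


def write_bundle(bundle: ResultBundle, out_dir: str | Path, *, overwrite: bool = False) -> Path:
    """Write masks (NIfTI, uint8 {0,1}) and a JSON report into ``out_dir``.

    The bundle invariants are validated before any file is created.
    """
    bundle.validate()
    out_dir = Path(out_dir)
    report_path = out_dir / "report.json"
    if report_path.exists() and not overwrite:
        raise PFTQuantError(f"refuse to overwrite existing bundle at {out_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    affine = _mask_affine(bundle.spacing_zyx)
    for name, mask in (("pre_mask", bundle.pre_mask), ("post_mask", bundle.post_mask)):
        img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
        nib.save(img, out_dir / f"{name}.nii.gz")

    report = {
        "pre_volume_ml": bundle.pre_volume_ml,
        "post_volume_ml": bundle.post_volume_ml,
        "delta_volume_ml": bundle.delta_volume_ml,
        "slice_curve_pre_ml": [float(v) for v in bundle.slice_curve_pre],
        "slice_curve_post_ml": [float(v) for v in bundle.slice_curve_post],
        "spacing_zyx_mm": list(bundle.spacing_zyx),
        "analysis_meta": bundle.analysis_meta,
    }
    report_path.write_text(json.dumps(report, indent=2))
    return out_dir


def read_bundle(out_dir: str | Path) -> ResultBundle:
    """Re-read a bundle written by :func:`write_bundle` (bit-exact masks)."""
    out_dir = Path(out_dir)
    report = json.loads((out_dir / "report.json").read_text())
    masks = {}
    for name in ("pre_mask", "post_mask"):
        img = nib.load(out_dir / f"{name}.nii.gz")
        masks[name] = np.asarray(img.dataobj).astype(bool)
    return ResultBundle(
        pre_mask=masks["pre_mask"],
        post_mask=masks["post_mask"],
        pre_volume_ml=report["pre_volume_ml"],
        post_volume_ml=report["post_volume_ml"],
        delta_volume_ml=report["delta_volume_ml"],
        slice_curve_pre=np.asarray(report["slice_curve_pre_ml"], dtype=float),
        slice_curve_post=np.asarray(report["slice_curve_post_ml"], dtype=float),
        spacing_zyx=tuple(report["spacing_zyx_mm"]),
        analysis_meta=report["analysis_meta"],
    )
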