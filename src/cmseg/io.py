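"""Reading, writing and intensity normalization of images and label maps.

Supported containers: PNG and TIFF for 2D images and 2D label maps (via
imageio/tifffile), NIfTI-1 for 3D volumes and 3D label maps (via nibabel),
and delimited text for 1D signals, CM profiles and per-label pixel counts.
Intensities are promoted to float on load; label maps are written as
integer containers so round-trips are exact.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ImageRecord",
    "RunConfig",
    "read_image",
    "read_labels",
    "normalize_array",
    "normalize_intensity",
    "write_labels",
    "read_signal",
    "write_signal",
    "write_cm_table",
]

_PNG_EXT = {".png"}
_TIFF_EXT = {".tif", ".tiff"}
_NIFTI_EXT = {".nii", ".nii.gz"}


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


@dataclass
class ImageRecord:
    """An image plus the provenance needed to write results back."""

    data: np.ndarray  # 2D (rows, cols[, channels]) or 3D volume
    spacing: Optional[tuple] = None  # physical voxel size, when known
    source: Optional[str] = None
    format: Optional[str] = None  # "png" | "tiff" | "nifti" | "array"
    affine: Optional[np.ndarray] = None  # NIfTI affine, carried through

    @property
    def dimension(self) -> int:
        if self.format == "nifti":
            return 3
        if self.data.ndim == 2:
            return 2
        if self.data.ndim == 3 and self.data.shape[-1] <= 4:
            return 2  # trailing channels
        return 3


def read_image(path) -> ImageRecord:
    """Load a PNG/TIFF (2D) or NIfTI (3D) image as floating-point data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    ext = _suffix(path)
    try:
        if ext in _PNG_EXT or ext in _TIFF_EXT:
            import imageio.v3 as iio

            data = np.asarray(iio.imread(path), dtype=float)
            fmt = "png" if ext in _PNG_EXT else "tiff"
            record = ImageRecord(data=data, source=str(path), format=fmt)
        elif ext in _NIFTI_EXT:
            import nibabel as nib

            img = nib.load(str(path))
            data = np.asarray(img.get_fdata(), dtype=float)
            zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
            if len(set(np.round(zooms, 6))) > 1:
                warnings.warn(
                    f"anisotropic voxels {zooms}: CM distances assume isotropic "
                    "voxels; resample the volume beforehand for faithful geometry",
                    stacklevel=2,
                )
            record = ImageRecord(
                data=data,
                spacing=zooms,
                source=str(path),
                format="nifti",
                affine=np.asarray(img.affine),
            )
        else:
            raise ValueError(
                f"unsupported image extension {ext!r} (expected PNG/TIFF/NIfTI)"
            )
    except ValueError:
        raise
    except Exception as exc:  # corrupt container
        raise ValueError(f"could not decode image file {path}: {exc}") from exc
    if not np.all(np.isfinite(record.data)):
        raise ValueError(f"image {path} contains non-finite values")
    return record


def read_labels(path) -> np.ndarray:
    """Load an integer label map from PNG/TIFF/NIfTI."""
    rec = read_image(path)
    labels = np.rint(rec.data).astype(np.int64)
    return labels


def normalize_array(data: np.ndarray, mode: str) -> np.ndarray:
    """Normalize intensities of a raw array.

    ``minmax`` affinely maps intensities to [0, 1] (a constant image becomes
    all zeros, with a warning).  ``stddev`` divides by the image's intensity
    standard deviation and rescales so the maximum is 1.  ``none`` returns
    the input unchanged.
    """
    data = np.asarray(data, dtype=float)
    if mode == "none":
        return data
    if mode == "minmax":
        lo, hi = float(data.min()), float(data.max())
        if hi == lo:
            warnings.warn("constant image: min-max normalization yields all zeros", stacklevel=2)
            return np.zeros_like(data)
        return (data - lo) / (hi - lo)
    if mode == "stddev":
        sd = float(data.std())
        if sd == 0:
            warnings.warn("constant image: stddev normalization yields all zeros", stacklevel=2)
            return np.zeros_like(data)
        scaled = data / sd
        return scaled / float(scaled.max())
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_intensity(record: ImageRecord, mode: str) -> ImageRecord:
    """Normalized copy of an :class:`ImageRecord` (see :func:`normalize_array`)."""
    return ImageRecord(
        data=normalize_array(record.data, mode),
        spacing=record.spacing,
        source=record.source,
        format=record.format,
        affine=record.affine,
    )


def write_labels(labels: np.ndarray, reference: Optional[ImageRecord], path) -> None:
    """Write a finalized label map plus a per-label pixel-count sidecar.

    2D label maps go to 16-bit PNG/TIFF (32-bit TIFF when more than 65535
    labels); 3D label maps go to integer NIfTI inheriting the reference
    header.  The sidecar ``<path>.counts.csv`` lists (label, pixel count).
    """
    labels = np.asarray(labels)
    path = Path(path)
    ext = _suffix(path)
    n_labels = int(labels.max()) if labels.size else 0
    if ext in _PNG_EXT:
        if n_labels > 65535:
            raise ValueError(
                f"{n_labels} labels exceed the 16-bit PNG container; "
                "write a 32-bit TIFF or NIfTI instead"
            )
        import imageio.v3 as iio

        iio.imwrite(path, labels.astype(np.uint16))
    elif ext in _TIFF_EXT:
        import tifffile

        dtype = np.uint16 if n_labels <= 65535 else np.uint32
        tifffile.imwrite(path, labels.astype(dtype))
    elif ext in _NIFTI_EXT:
        import nibabel as nib

        affine = None
        if reference is not None and reference.affine is not None:
            affine = reference.affine
        if affine is None:
            affine = np.eye(4)
        img = nib.Nifti1Image(labels.astype(np.int32), affine)
        if reference is not None and reference.spacing is not None:
            img.header.set_zooms(reference.spacing[: labels.ndim])
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported label-map extension {ext!r}")
    sidecar = path.parent / (path.name + ".counts.csv")
    values, counts = np.unique(labels, return_counts=True)
    with open(sidecar, "w", newline="") as fh:
        fh.write("# per-label pixel counts; labels are the values stored in the image\n")
        writer = csv.writer(fh)
        writer.writerow(["label", "pixel_count"])
        for v, c in zip(values, counts):
            writer.writerow([int(v), int(c)])


def read_signal(path) -> np.ndarray:
    """Read a 1D signal from delimited text (one row per sample, one column
    per channel).  Single-channel input comes back as a 1D array."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] == 1:
        return arr[:, 0]
    return arr


def write_signal(values: np.ndarray, path) -> None:
    """Write a 1D signal or CM profile to delimited text."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, np.newaxis]
    np.savetxt(path, arr, fmt="%.12g", delimiter="\t")


def write_cm_table(field, path) -> None:
    """Dump a CM field as a debug table (tab-delimited text).

    Columns: pixel index, orientation index, CM pixel index, distance.
    All pixel indices are 0-based C-order flat indices.
    """
    table = field.to_table()
    header = (
        "pixel and CM indices are 0-based C-order flat indices\n"
        "pixel\torientation\tcm_index\tdistance"
    )
    np.savetxt(path, table, fmt=["%d", "%d", "%d", "%.6g"], delimiter="\t", header=header)


@dataclass
class RunConfig:
    """Plain-text-serializable description of one CLI segmentation run."""

    input: Optional[str] = None
    output: Optional[str] = None
    alpha: float = 100.0
    p: float = 2.0
    angular_resolution: float = 10.0
    phase1_iterations: int = 200
    max_iterations: int = 1000
    seed: int = 0
    normalization: str = "minmax"
    seeds_labels: Optional[str] = None
    freeze_seeds: bool = False

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
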