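"""Read and write volumetric scans (DICOM series, NIfTI, MetaImage) and STL meshes.

Volumes are exchanged as :class:`~vesselforge.grid.ImageVolume` under the
package axis convention (slice, row, column); meshes as
:class:`trimesh.Trimesh` with vertex coordinates in physical (x, y, z) mm.

DICOM series are sorted by Image Position (Patient) projected on the slice
normal, never by filename, and the rescale slope/intercept is applied so
returned values are Hounsfield units.  Non-uniform slice gaps beyond 1%
are an error: geometric fidelity of the printed model is the product, so
silent resampling is never acceptable.
"""

from __future__ import annotations

import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk
import trimesh
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .grid import ImageVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_stl",
    "write_stl",
    "VolumeIOError",
    "StlFormatError",
]

#: Relative tolerance on slice-gap uniformity for DICOM series.
SLICE_GAP_TOLERANCE = 0.01


class VolumeIOError(IOError):
    """Raised on unreadable, inconsistent or non-volumetric image input."""


class StlFormatError(IOError):
    """Raised on malformed STL files (truncation, facet-count mismatch)."""


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise VolumeIOError(f"cannot infer volume format from path: {path}")


def read_volume(path, format: str = "auto") -> ImageVolume:
    """Read a volumetric scan into HU values with metadata spacing.

    Parameters
    ----------
    path :
        File (NIfTI ``.nii``/``.nii.gz``, MetaImage ``.mha``/``.mhd``) or
        DICOM series directory.
    format :
        One of ``dicom_dir``, ``nifti``, ``metaimage`` or ``auto``
        (inferred from the path).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "dicom_dir":
        return _read_dicom_dir(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "metaimage":
        return _read_metaimage(path)
    raise VolumeIOError(f"unknown volume format: {fmt!r}")


def write_volume(vol: ImageVolume, path, format: str = "auto") -> None:
    """Write a volume; MetaImage and NIfTI round-trip losslessly.

    The DICOM writer emits a minimal CT series (int16 stored values with
    rescale intercept -1024) and therefore rounds HU to integers.
    """
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "dicom_dir":
        _write_dicom_dir(vol, path)
    elif fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "metaimage":
        _write_metaimage(vol, path)
    else:
        raise VolumeIOError(f"unknown volume format: {fmt!r}")


# ---------------------------------------------------------------------------
# MetaImage (SimpleITK) — the package's lossless intermediate format
# ---------------------------------------------------------------------------

def _read_metaimage(path: Path) -> ImageVolume:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def _write_metaimage(vol: ImageVolume, path: Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# NIfTI (nibabel)
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got {img.ndim}D")
    affine = img.affine
    rotation = affine[:3, :3]
    if not np.allclose(rotation - np.diag(np.diag(rotation)), 0.0, atol=1e-6):
        raise VolumeIOError(
            f"{path}: oblique (non-diagonal) NIfTI affines are not supported"
        )
    diag = np.diag(rotation)
    if np.any(diag <= 0):
        raise VolumeIOError(f"{path}: negative/zero affine scales not supported")
    data_xyz = np.asarray(img.dataobj)
    data = np.transpose(data_xyz, (2, 1, 0))  # (x, y, z) -> (z, y, x)
    spacing = (float(diag[2]), float(diag[1]), float(diag[0]))
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def _write_nifti(vol: ImageVolume, path: Path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = (
        vol.spacing[2],
        vol.spacing[1],
        vol.spacing[0],
    )
    affine[:3, 3] = (vol.origin[2], vol.origin[1], vol.origin[0])
    data_xyz = np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)))
    nib.save(nib.Nifti1Image(data_xyz, affine), str(path))


# ---------------------------------------------------------------------------
# DICOM series (pydicom)
# ---------------------------------------------------------------------------

def _read_dicom_dir(path: Path) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # non-DICOM clutter in the directory
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((f, ds))
    if not datasets:
        raise VolumeIOError(f"{path}: no readable DICOM image slices found")

    ref_file, ref = datasets[0]
    series_uid = getattr(ref, "SeriesInstanceUID", None)
    orientation = np.asarray(ref.ImageOrientationPatient, dtype=float)
    pixel_spacing = np.asarray(ref.PixelSpacing, dtype=float)
    for f, ds in datasets[1:]:
        if getattr(ds, "SeriesInstanceUID", None) != series_uid:
            raise VolumeIOError(
                f"{path}: mixed DICOM series; slice {f.name} belongs to a "
                "different SeriesInstanceUID"
            )
        if not np.allclose(ds.ImageOrientationPatient, orientation, atol=1e-6):
            raise VolumeIOError(
                f"{path}: inconsistent slice orientation at {f.name}"
            )
        if not np.allclose(ds.PixelSpacing, pixel_spacing, rtol=1e-6):
            raise VolumeIOError(
                f"{path}: inconsistent in-plane pixel spacing at {f.name}"
            )

    row_dir, col_dir = orientation[:3], orientation[3:]
    normal = np.cross(row_dir, col_dir)
    keyed = sorted(
        datasets,
        key=lambda item: float(
            np.dot(np.asarray(item[1].ImagePositionPatient, dtype=float), normal)
        ),
    )
    positions = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal) for _, ds in keyed]
    )
    if len(keyed) < 2:
        raise VolumeIOError(f"{path}: a DICOM volume needs at least 2 slices")
    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        i = int(np.argmax(gaps <= 0))
        raise VolumeIOError(
            f"{path}: duplicate or unsorted slice positions near {keyed[i + 1][0].name}"
        )
    mean_gap = float(gaps.mean())
    rel = np.abs(gaps - mean_gap) / mean_gap
    if np.any(rel > SLICE_GAP_TOLERANCE):
        i = int(np.argmax(rel))
        raise VolumeIOError(
            f"{path}: non-uniform slice spacing (gap {gaps[i]:.4f} mm vs mean "
            f"{mean_gap:.4f} mm) at slice {keyed[i + 1][0].name}; resampling is "
            "not performed"
        )

    slices = []
    for _, ds in keyed:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    data = np.stack(slices, axis=0)
    # PixelSpacing is (row spacing, column spacing) per the standard.
    spacing = (mean_gap, float(pixel_spacing[0]), float(pixel_spacing[1]))
    ipp0 = np.asarray(keyed[0][1].ImagePositionPatient, dtype=float)
    origin = (float(ipp0[2]), float(ipp0[1]), float(ipp0[0]))
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def _write_dicom_dir(vol: ImageVolume, path: Path) -> None:
    """Write a minimal axial CT series (stored int16, intercept -1024)."""
    path.mkdir(parents=True, exist_ok=True)
    intercept = -1024.0
    stored = np.round(vol.data - intercept)
    if stored.min() < 0 or stored.max() > 65535:
        raise VolumeIOError(
            "HU range not representable as unsigned 16-bit stored values"
        )
    stored = stored.astype(np.uint16)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for i in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, Dataset(), file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            vol.origin[2],
            vol.origin[1],
            vol.origin[0] + i * vol.spacing[0],
        ]
        ds.PixelSpacing = [vol.spacing[1], vol.spacing[2]]
        ds.SliceThickness = vol.spacing[0]
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = np.ascontiguousarray(stored[i]).tobytes()
        ds.save_as(str(path / f"slice_{i:04d}.dcm"), enforce_file_format=True)


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def write_stl(mesh: trimesh.Trimesh, path, dialect: str = "binary") -> None:
    """Write a triangle mesh as STL (binary by default; slicers assume mm)."""
    if len(mesh.faces) == 0:
        raise StlFormatError("refusing to write an empty mesh to STL")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect: {dialect!r}")
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    payload = mesh.export(file_type=file_type)
    mode = "wb" if isinstance(payload, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(payload)


def _validate_binary_stl(path: Path) -> None:
    size = path.stat().st_size
    if size < 84:
        raise StlFormatError(
            f"{path}: truncated STL, only {size} bytes (header needs 84); "
            f"parse failed at byte offset {size}"
        )
    with open(path, "rb") as fh:
        fh.seek(80)
        (n_facets,) = struct.unpack("<I", fh.read(4))
    expected = 84 + 50 * n_facets
    if size < expected:
        raise StlFormatError(
            f"{path}: truncated STL; header declares {n_facets} facets "
            f"({expected} bytes) but file ends at byte offset {size}"
        )
    if size > expected:
        raise StlFormatError(
            f"{path}: facet-count mismatch; header declares {n_facets} facets "
            f"({expected} bytes) but file has {size} bytes"
        )


def read_stl(path) -> trimesh.Trimesh:
    """Read an STL file, merging duplicate vertices by exact coordinate."""
    path = Path(path)
    if not path.exists():
        raise StlFormatError(f"no such file: {path}")
    with open(path, "rb") as fh:
        head = fh.read(512)
    is_ascii = head.lstrip().startswith(b"solid") and b"facet" in head
    if not is_ascii:
        _validate_binary_stl(path)
    mesh = trimesh.load(str(path), file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise StlFormatError(f"{path}: did not parse to a triangle mesh")
    mesh.merge_vertices(digits_vertex=12)
    mesh.update_faces(mesh.nondegenerate_faces())
    return mesh
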