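"""Reading and writing repeated-acquisition image stacks.

Two on-disk formats are supported:

* ``array_stack`` — one ``stack.npy`` (4D float array, HU) plus a
  ``stack.json`` sidecar with geometry and provenance; lossless and fast,
  the fixture format used by the test suite.
* ``dicom_series`` — one directory per repeat, one CT-image file per slice,
  HU stored as signed 16-bit integers with RescaleSlope/Intercept, so a
  round trip quantizes values to at most 0.5 HU.

Reads are deterministic: DICOM repeats are ordered by SeriesNumber (then
SeriesInstanceUID) and slices by InstanceNumber; array stacks preserve
their stored axis order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import GeometryError, ImageStack

__all__ = ["write_array_stack", "read_array_stack", "write_dicom_series",
           "read_dicom_series", "read_stack"]


def write_array_stack(stack: ImageStack, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "stack.npy", stack.values)
    meta = {
        "pixel_spacing_mm": stack.pixel_spacing_mm,
        "slice_thickness_mm": stack.slice_thickness_mm,
        "label": stack.label,
        "n_repeats": stack.n_repeats,
        "n_slices": stack.n_slices,
    }
    (path / "stack.json").write_text(json.dumps(meta, indent=2))


def read_array_stack(path) -> ImageStack:
    path = Path(path)
    npy = path / "stack.npy"
    sidecar = path / "stack.json"
    if not npy.exists() or not sidecar.exists():
        raise FileNotFoundError(f"array stack needs {npy} and {sidecar}")
    meta = json.loads(sidecar.read_text())
    values = np.load(npy)
    if values.ndim != 4:
        raise ValueError(f"{npy}: expected 4D (repeat, slice, row, col)")
    if values.shape[0] != meta.get("n_repeats", values.shape[0]):
        raise GeometryError(
            f"{npy}: found {values.shape[0]} repeats, sidecar says "
            f"{meta['n_repeats']}")
    return ImageStack(values=values,
                      pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
                      slice_thickness_mm=float(meta["slice_thickness_mm"]),
                      label=meta.get("label", ""))


def _ct_dataset(plane: np.ndarray, pixel_spacing: float, thickness: float,
                series_uid: str, series_number: int, instance_number: int,
                study_uid: str, frame_uid: str):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    intercept = -1024.0
    stored = np.round(plane - intercept).astype(np.int16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.FrameOfReferenceUID = frame_uid
    ds.SeriesNumber = series_number
    ds.InstanceNumber = instance_number
    ds.Rows, ds.Columns = plane.shape
    ds.PixelSpacing = [pixel_spacing, pixel_spacing]
    ds.SliceThickness = thickness
    z = (instance_number - 1) * thickness
    ds.ImagePositionPatient = [0.0, 0.0, z]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SliceLocation = z
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = intercept
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.tobytes()
    return ds


def write_dicom_series(stack: ImageStack, path) -> None:
    """One DICOM series (directory) per repeat, one file per slice."""
    from pydicom.uid import generate_uid

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    frame_uid = generate_uid()
    for r in range(stack.n_repeats):
        series_uid = generate_uid()
        rdir = path / f"repeat_{r:03d}"
        rdir.mkdir(exist_ok=True)
        for s in range(stack.n_slices):
            ds = _ct_dataset(np.asarray(stack.values[r, s], dtype=np.float64),
                             stack.pixel_spacing_mm, stack.slice_thickness_mm,
                             series_uid, r + 1, s + 1, study_uid, frame_uid)
            ds.save_as(rdir / f"slice_{s:03d}.dcm", enforce_file_format=True)


def read_dicom_series(path, expected_repeats: int | None = None) -> ImageStack:
    """Read a directory of DICOM series into a 4D HU stack.

    Repeats are grouped by SeriesInstanceUID and ordered by SeriesNumber;
    slices are ordered by InstanceNumber. Mixed geometries raise a
    :class:`GeometryError` naming the offending file.
    """
    import pydicom

    path = Path(path)
    files = sorted(path.rglob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files under {path}")
    series: dict[str, list] = {}
    for f in files:
        ds = pydicom.dcmread(f)
        series.setdefault(str(ds.SeriesInstanceUID), []).append((f, ds))
    ordered = sorted(series.values(),
                     key=lambda lst: (int(lst[0][1].get("SeriesNumber", 0)),
                                      str(lst[0][1].SeriesInstanceUID)))
    if expected_repeats is not None and len(ordered) != expected_repeats:
        raise GeometryError(
            f"expected {expected_repeats} repeats, found {len(ordered)} "
            f"DICOM series under {path}")
    first = ordered[0][0][1] if isinstance(ordered[0][0], tuple) else None
    ref = ordered[0][0][1]
    spacing = float(ref.PixelSpacing[0])
    thickness = float(ref.SliceThickness)
    shape = (int(ref.Rows), int(ref.Columns))
    n_slices = len(ordered[0])
    volumes = []
    for lst in ordered:
        if len(lst) != n_slices:
            raise GeometryError(
                f"series {lst[0][1].SeriesInstanceUID} has {len(lst)} slices, "
                f"expected {n_slices} (first file {lst[0][0]})")
        lst = sorted(lst, key=lambda t: int(t[1].InstanceNumber))
        planes = []
        for f, ds in lst:
            if (int(ds.Rows), int(ds.Columns)) != shape or \
                    not np.isclose(float(ds.PixelSpacing[0]), spacing):
                raise GeometryError(f"geometry mismatch in {f}")
            arr = ds.pixel_array.astype(np.float64)
            arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
            planes.append(arr)
        volumes.append(np.stack(planes))
    return ImageStack(values=np.stack(volumes), pixel_spacing_mm=spacing,
                      slice_thickness_mm=thickness, label=path.name)


def read_stack(path, fmt: str | None = None,
               expected_repeats: int | None = None) -> ImageStack:
    """Read a stack, auto-detecting the format if ``fmt`` is None."""
    path = Path(path)
    if fmt is None:
        fmt = "array_stack" if (path / "stack.npy").exists() else "dicom_series"
    if fmt == "array_stack":
        stack = read_array_stack(path)
        if expected_repeats is not None and stack.n_repeats != expected_repeats:
            raise GeometryError(
                f"expected {expected_repeats} repeats, found {stack.n_repeats}")
        return stack
    if fmt == "dicom_series":
        return read_dicom_series(path, expected_repeats)
    raise ValueError(f"unsupported stack format {fmt!r}")
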