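"""Read/write the formats the pipeline touches.

DICOM series in/out (minimal Secondary-Capture-style tags), binary and
ASCII STL, PLY with per-vertex deviation colors, CSV gap tables, and a
raw volume container with a JSON sidecar. All geometry is millimetres:
STL carries no units of its own, so the package fixes the DICOM mm
convention everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
import trimesh
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .volume import GrayVolume

__all__ = [
    "read_dicom_series",
    "write_dicom_series",
    "read_stl",
    "write_stl",
    "write_deviation_ply",
    "read_gap_table",
    "write_gap_table",
    "load_volume",
    "save_volume",
]

GAP_TABLE_COLUMNS = ["specimen", "section", "direction", "point", "thickness_um"]


# ---------------------------------------------------------------------------
# DICOM series


def write_dicom_series(volume: GrayVolume, directory: str | Path) -> list[Path]:
    """Write a volume as one Secondary-Capture-style DICOM file per slice.

    Intensities are linearly quantized to uint16 and the inverse mapping
    stored in Rescale Slope / Intercept. Pixel Spacing, Slice Thickness
    and Image Position (Patient) are populated so the series round-trips
    through :func:`read_dicom_series`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vox = volume.voxels.astype(np.float64)
    lo, hi = float(vox.min()), float(vox.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    intercept = lo
    pix = np.round((vox - intercept) / slope).astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    spx, spy, spz = volume.spacing
    paths = []
    for iz in range(volume.shape[2]):
        ds = Dataset()
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "OT"
        ds.PatientName = "phantom"
        ds.PatientID = "phantom"
        ds.SeriesDescription = "synthetic impression volume"
        ds.InstanceNumber = iz + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(volume.origin[0]),
            float(volume.origin[1]),
            float(volume.origin[2] + iz * spz),
        ]
        ds.PixelSpacing = [float(spy), float(spx)]  # [row, col] spacing
        ds.SliceThickness = float(spz)
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.Rows = volume.shape[1]
        ds.Columns = volume.shape[0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(pix[:, :, iz].T).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        path = directory / f"slice_{iz:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory: str | Path) -> GrayVolume:
    """Read a single-frame DICOM series into a :class:`GrayVolume`.

    Slices are sorted by position along the slice normal regardless of
    filename order; Rescale Slope / Intercept are applied. A directory
    mixing several series, non-uniform slice gaps (beyond 1%) or missing
    spacing tags raise a :class:`ValueError` naming the offending file.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        datasets.append((path, ds))
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")

    uids = sorted({str(ds.SeriesInstanceUID) for _, ds in datasets})
    if len(uids) > 1:
        raise ValueError(
            f"directory {directory} mixes {len(uids)} series: {', '.join(uids)}"
        )

    for path, ds in datasets:
        for tag in ("PixelSpacing", "ImagePositionPatient"):
            if tag not in ds:
                raise ValueError(f"{path} is missing the {tag} tag")

    first = datasets[0][1]
    orient = np.array(first.ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    positions = np.array(
        [np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal) for _, ds in datasets]
    )
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = positions[order]

    if len(datasets) < 2:
        raise ValueError(f"{directory}: a series needs at least 2 slices")
    gaps = np.diff(positions)
    mean_gap = gaps.mean()
    if mean_gap <= 0:
        raise ValueError(f"{directory}: slices share identical positions")
    bad = np.nonzero(np.abs(gaps - mean_gap) > 0.01 * mean_gap)[0]
    if bad.size:
        offending = datasets[int(bad[0]) + 1][0]
        raise ValueError(
            f"non-uniform slice gap near {offending}: "
            f"{gaps[bad[0]]:.6f} vs mean {mean_gap:.6f}"
        )

    slices = []
    for _, ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    stack = np.stack(slices, axis=-1)  # (rows=y, cols=x, z)
    voxels = np.ascontiguousarray(np.transpose(stack, (1, 0, 2)))

    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    spacing = np.array([col_sp, row_sp, mean_gap])
    origin = np.array(datasets[0][1].ImagePositionPatient, dtype=float)
    return GrayVolume(voxels, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# STL


def write_stl(mesh: trimesh.Trimesh, path: str | Path, mode: str = "binary") -> Path:
    """Write a mesh as STL; facet normals are recomputed from winding.

    Binary files are exactly ``84 + 50 * n_faces`` bytes.
    """
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    path = Path(path)
    file_type = "stl" if mode == "binary" else "stl_ascii"
    data = mesh.export(file_type=file_type)
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    return path


def read_stl(path: str | Path, merge_vertices: bool = True) -> trimesh.Trimesh:
    """Load an STL file; shared vertices are merged by default."""
    mesh = trimesh.load(str(path), file_type="stl", force="mesh", process=False)
    if merge_vertices:
        mesh.merge_vertices()
    return mesh


# ---------------------------------------------------------------------------
# PLY with deviation colors


def deviation_colors(deviations_um: np.ndarray, scale_um: float) -> np.ndarray:
    """Signed diverging blue-white-red ramp, clamped to +-scale_um.

    Zero deviation maps to the white midpoint, -scale to saturated blue
    (inside the reference), +scale to saturated red (outside).
    """
    if scale_um <= 0:
        raise ValueError("scale_um must be > 0")
    t = np.clip(np.asarray(deviations_um, dtype=float) / scale_um, -1.0, 1.0)
    rgb = np.empty((t.size, 3), dtype=np.uint8)
    pos = np.clip(t, 0, 1)
    neg = np.clip(-t, 0, 1)
    rgb[:, 0] = np.round(255 * (1 - neg))
    rgb[:, 1] = np.round(255 * (1 - np.abs(t)))
    rgb[:, 2] = np.round(255 * (1 - pos))
    return rgb


def write_deviation_ply(
    mesh: trimesh.Trimesh,
    deviations_um: np.ndarray,
    path: str | Path,
    scale_um: float = 100.0,
) -> Path:
    """Write a binary little-endian PLY with per-vertex uchar RGB colors
    mapped from signed deviations (um)."""
    if deviations_um is None:
        raise ValueError("per-vertex deviation scalars are required")
    deviations_um = np.asarray(deviations_um, dtype=float).ravel()
    if deviations_um.size != len(mesh.vertices):
        raise ValueError(
            f"got {deviations_um.size} scalars for {len(mesh.vertices)} vertices"
        )
    rgb = deviation_colors(deviations_um, scale_um)
    verts = np.asarray(mesh.vertices, dtype="<f4")
    faces = np.asarray(mesh.faces, dtype="<i4")

    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {len(verts)}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "property uchar red\n"
        "property uchar green\n"
        "property uchar blue\n"
        f"element face {len(faces)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        vert_dtype = np.dtype(
            [("xyz", "<f4", 3), ("rgb", "u1", 3)]
        )
        block = np.empty(len(verts), dtype=vert_dtype)
        block["xyz"] = verts
        block["rgb"] = rgb
        fh.write(block.tobytes())
        face_dtype = np.dtype([("n", "u1"), ("idx", "<i4", 3)])
        fblock = np.empty(len(faces), dtype=face_dtype)
        fblock["n"] = 3
        fblock["idx"] = faces
        fh.write(fblock.tobytes())
    return path


# ---------------------------------------------------------------------------
# Gap tables (CSV)


def write_gap_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a gap table with the canonical CSV header."""
    missing = [c for c in GAP_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gap table is missing columns: {missing}")
    path = Path(path)
    table[GAP_TABLE_COLUMNS].to_csv(path, index=False)
    return path


def read_gap_table(path: str | Path) -> pd.DataFrame:
    """Read a gap-table CSV (header ``specimen,section,direction,point,thickness_um``)."""
    table = pd.read_csv(path)
    missing = [c for c in GAP_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path} is missing columns: {missing}")
    return table


# ---------------------------------------------------------------------------
# Raw volume container


def save_volume(volume: GrayVolume, base_path: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.raw`` (C-order float32) plus a ``<base>.json`` sidecar
    describing shape, spacing, origin and dtype."""
    base_path = Path(base_path)
    raw = base_path.with_suffix(".raw")
    sidecar = base_path.with_suffix(".json")
    data = np.ascontiguousarray(volume.voxels, dtype=np.float32)
    raw.write_bytes(data.tobytes())
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(volume.shape),
                "spacing": volume.spacing.tolist(),
                "origin": volume.origin.tolist(),
                "dtype": "float32",
            },
            indent=2,
        )
    )
    return raw, sidecar


def load_volume(base_path: str | Path) -> GrayVolume:
    """Load a volume written by :func:`save_volume`."""
    base_path = Path(base_path)
    raw = base_path.with_suffix(".raw")
    sidecar = base_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    voxels = np.frombuffer(raw.read_bytes(), dtype=meta["dtype"]).reshape(meta["shape"])
    return GrayVolume(
        voxels.astype(np.float64), spacing=meta["spacing"], origin=meta["origin"]
    )
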