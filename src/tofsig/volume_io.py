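"""Volume container, file I/O and the center-origin world coordinate frame.

A :class:`Volume` is a 3D scalar grid of MR signal intensity (SI, arbitrary
units) indexed ``(i, j, k)`` with voxel spacings ``(dx, dy, dz)`` in mm.
All downstream geometry operates in mm world coordinates in a frame whose
origin is the *center of the volume*: voxel index ``(ci, cj, ck) =
((Ni-1)/2, (Nj-1)/2, (Nk-1)/2)`` — the midpoint of the voxel-center
lattice — maps to ``(0, 0, 0)``.  Axes are right-handed with i -> x,
j -> y, k -> z.

Readers cover NIfTI-1 files and axial DICOM series; wall-map writers cover
legacy-ASCII VTK polydata, PLY and a per-vertex CSV table.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConsistencyError, InputError, MetadataError

__all__ = [
    "Volume",
    "voxel_to_world",
    "world_to_voxel",
    "read_volume",
    "write_volume",
    "write_wall_map",
    "read_wall_map",
]


@dataclasses.dataclass(frozen=True)
class Volume:
    """3D scalar signal-intensity grid with mm voxel spacing.

    Parameters
    ----------
    data
        Scalar grid, shape ``(Ni, Nj, Nk)``, finite values.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all strictly positive.
    frame
        World-origin convention tag; only ``"center"`` is defined.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    frame: str = "center"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise InputError(f"volume data must be 3D, got ndim={data.ndim}")
        if any(n < 2 for n in data.shape):
            raise InputError(f"every axis needs >= 2 voxels, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise InputError("volume contains non-finite signal intensities")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise MetadataError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def center_index(self) -> np.ndarray:
        """Fractional index of the volume center, ``(N-1)/2`` per axis."""
        return (np.array(self.shape, dtype=float) - 1.0) / 2.0

    def axes_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis (mm)."""
        c = self.center_index
        return tuple(  # type: ignore[return-value]
            self.spacing[a] * (np.arange(self.shape[a]) - c[a]) for a in range(3)
        )

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the voxel-center bounding box in mm."""
        axes = self.axes_world()
        return (np.array([ax[0] for ax in axes]), np.array([ax[-1] for ax in axes]))


def voxel_to_world(v: Volume, index: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map (fractional) voxel indices to mm world positions.

    The map is affine: ``world = spacing * (index - center_index)``, so the
    center of the volume is the world origin.  Accepts a single ``(i, j, k)``
    triple or an ``(n, 3)`` array.
    """
    idx = np.asarray(index, dtype=float)
    return np.asarray(v.spacing) * (idx - v.center_index)


def world_to_voxel(v: Volume, position: Sequence[float] | np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (fractional indices)."""
    pos = np.asarray(position, dtype=float)
    return pos / np.asarray(v.spacing) + v.center_index


# ---------------------------------------------------------------------------
# Volume readers / writers
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a 3D scalar volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred from the path (directories are treated as DICOM series).
    Spacing is taken from file metadata; missing or zero spacing raises
    :class:`~tofsig.errors.MetadataError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise InputError(f"unknown volume format {format!r}")


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise InputError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise InputError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"NIfTI voxel spacing missing or non-positive: {zooms}")
    return Volume(data=data, spacing=tuple(float(z) for z in zooms))


def _read_dicom_series(path: Path) -> Volume:
    """Read an axial DICOM series: one slice per file, stacked along k.

    Slices are ordered by their position along the slice normal; the slice
    spacing dz is derived from consecutive slice positions and falls back to
    SliceThickness for a degenerate series.  Oblique orientations (image
    rows/columns not aligned with the patient x/y axes) are rejected rather
    than silently reinterpreted.
    """
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM clutter (DICOMDIR, notes, ...)
        if hasattr(ds, "pixel_array"):
            datasets.append(ds)
    if not datasets:
        raise InputError(f"no readable DICOM image files in {path}")

    def _zpos(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_zpos)
    first = datasets[0]

    iop = getattr(first, "ImageOrientationPatient", None)
    if iop is not None:
        iop = np.asarray([float(x) for x in iop])
        axial = np.array([1, 0, 0, 0, 1, 0], dtype=float)
        if not np.allclose(np.abs(iop), np.abs(axial), atol=1e-3):
            raise MetadataError(
                "only axis-aligned axial DICOM series are supported; "
                f"ImageOrientationPatient={iop.tolist()}"
            )

    ps = getattr(first, "PixelSpacing", None)
    if ps is None:
        raise MetadataError("DICOM series lacks PixelSpacing")
    dy, dx = float(ps[0]), float(ps[1])  # PixelSpacing is (row, column)

    if len(datasets) >= 2 and hasattr(first, "ImagePositionPatient"):
        zs = np.array([_zpos(ds) for ds in datasets])
        steps = np.diff(zs)
        if np.any(steps <= 0):
            raise MetadataError("DICOM slice positions are not strictly increasing")
        dz = float(np.mean(steps))
    else:
        dz = float(getattr(first, "SliceThickness", 0.0) or 0.0)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise MetadataError(f"non-positive DICOM spacing ({dx}, {dy}, {dz})")

    slices = []
    for ds in datasets:
        arr = np.asarray(ds.pixel_array, dtype=float)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(arr * slope + intercept)
    # pixel_array is (rows=j, cols=i); volume axes are (i, j, k)
    data = np.stack(slices, axis=-1).transpose(1, 0, 2)
    return Volume(data=data, spacing=(dx, dy, dz))


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine encoding the
    spacing and the center-origin frame (the volume center sits at world
    (0, 0, 0))."""
    import nibabel as nib

    affine = np.diag(list(v.spacing) + [1.0])
    affine[:3, 3] = -np.asarray(v.spacing) * v.center_index
    img = nib.Nifti1Image(v.data, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Wall-map (mesh + per-vertex SIG) writers
# ---------------------------------------------------------------------------

def _check_mesh(mesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    if verts.size == 0:
        raise ConsistencyError("cannot write an empty mesh")
    sig = getattr(mesh, "vertex_sig", None)
    if sig is None:
        raise ConsistencyError("mesh has no per-vertex SIG scalar to write")
    sig = np.asarray(sig, dtype=float)
    if sig.shape[0] != verts.shape[0]:
        raise ConsistencyError(
            f"SIG length {sig.shape[0]} != vertex count {verts.shape[0]}"
        )
    return verts, faces, sig


def write_wall_map(mesh, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a wall mesh with its per-vertex "SIG" scalar (SI/mm).

    Formats: ``vtk`` (legacy ASCII polydata), ``ply`` (via trimesh, SIG as a
    custom float vertex property), ``csv`` (one row per vertex:
    ``x,y,z,sig``; faces are not representable in the flat table).  When
    ``format`` is omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    verts, faces, sig = _check_mesh(mesh)

    if format == "vtk":
        _write_vtk_polydata(path, verts, faces, sig)
    elif format == "ply":
        import trimesh

        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        tm.vertex_attributes["SIG"] = sig.astype(np.float64)
        tm.export(str(path), file_type="ply", encoding="ascii")
    elif format == "csv":
        import pandas as pd

        pd.DataFrame(
            {"x": verts[:, 0], "y": verts[:, 1], "z": verts[:, 2], "sig": sig}
        ).to_csv(path, index=False)
    else:
        raise InputError(f"unknown wall-map format {format!r}")


def _write_vtk_polydata(path: Path, verts, faces, sig) -> None:
    # Legacy-ASCII VTK polydata; written directly because no installed
    # library emits this format.
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tofsig wall map\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} double\n")
        for p in verts:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"POINT_DATA {len(verts)}\n")
        fh.write("SCALARS SIG double 1\nLOOKUP_TABLE default\n")
        for s in sig:
            fh.write(f"{s:.17g}\n")


def read_wall_map(path: str | os.PathLike, format: str | None = None):
    """Read a wall map written by :func:`write_wall_map`.

    Returns ``(vertices, faces, sig)``; for CSV, ``faces`` is an empty
    array since the flat table stores vertices only.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "vtk":
        return _read_vtk_polydata(path)
    if format == "ply":
        import trimesh

        tm = trimesh.load(str(path), file_type="ply", process=False)
        sig = np.asarray(tm.metadata["_ply_raw"]["vertex"]["data"]["SIG"], dtype=float).ravel()
        return np.asarray(tm.vertices, float), np.asarray(tm.faces, int), sig
    if format == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        verts = df[["x", "y", "z"]].to_numpy(dtype=float)
        return verts, np.empty((0, 3), dtype=int), df["sig"].to_numpy(dtype=float)
    raise InputError(f"unknown wall-map format {format!r}")


def _read_vtk_polydata(path: Path):
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    it = iter(lines)
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    sig: list[float] = []
    for line in it:
        tok = line.split()
        if tok[0] == "POINTS":
            n = int(tok[1])
            while len(verts) < n:
                verts.append([float(x) for x in next(it).split()])
        elif tok[0] == "POLYGONS":
            n = int(tok[1])
            for _ in range(n):
                parts = [int(x) for x in next(it).split()]
                faces.append(parts[1:])
        elif tok[0] == "SCALARS":
            next(it)  # LOOKUP_TABLE line
            npts = len(verts)
            while len(sig) < npts:
                sig.extend(float(x) for x in next(it).split())
    return (
        np.asarray(verts, dtype=float),
        np.asarray(faces, dtype=int),
        np.asarray(sig, dtype=float),
    )
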