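"""Volume data model, NIfTI I/O, and resampling onto a common reference grid.

All field maps in the pipeline (B1+ magnitude, transceive phase, conductivity,
SAR) travel as :class:`VolumeGrid` objects: a 3D array indexed ``(x, y, z)``
with voxel spacing and origin in millimetres.  Undefined voxels are NaN;
background is encoded separately through the tissue label map.

Only grid/spacing resampling is performed — all inputs are assumed to share a
common orientation, as produced by a scanner-side interpolation step.  Full
affine registration is deliberately not attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "TissueLabelMap",
    "DEFAULT_CODE_TABLE",
    "FormatError",
    "EmptyOverlapError",
    "read_volume",
    "write_volume",
    "resample_to_reference",
]

#: Tissue integer codes used throughout the pipeline.
DEFAULT_CODE_TABLE: dict[int, str] = {
    0: "background",
    1: "gray_matter",
    2: "white_matter",
    3: "csf",
}


class FormatError(ValueError):
    """Raised for malformed volume files or invalid grid geometry."""


class EmptyOverlapError(ValueError):
    """Raised when moving and reference volumes share no physical extent."""


@dataclass
class VolumeGrid:
    """A 3D scalar or complex field on a regular grid.

    Parameters
    ----------
    data
        3D array, real or complex.  NaN marks undefined voxels.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    units
        Free-text unit tag (``"rad"``, ``"S/m"``, ``"W/kg"``, ``"a.u."``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(
                f"volume data must be 3D with every axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if np.iscomplexobj(self.data) and self.units in ("S/m", "W/kg"):
            raise FormatError(f"complex volume cannot carry units {self.units!r}")

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, units: str | None = None) -> "VolumeGrid":
        """New grid with identical geometry and replaced payload."""
        return replace(self, data=np.asarray(data), units=self.units if units is None else units)

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index -> physical mm coordinate (vectorised over rows)."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        """Physical mm coordinate -> fractional voxel index."""
        mm = np.asarray(mm, dtype=float)
        return (mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_geometry(self, other: "VolumeGrid | TissueLabelMap", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners in mm of the voxel-centre bounding box."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class TissueLabelMap:
    """Integer-coded tissue volume (background / GM / WM / CSF).

    Shares the geometry conventions of :class:`VolumeGrid` and must match the
    reference grid it annotates voxel for voxel.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    code_table: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CODE_TABLE))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise FormatError("label map must be integer-valued")
            self.labels = np.round(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise FormatError("label map must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.code_table)
        if unknown:
            raise FormatError(f"label values {sorted(unknown)} missing from code_table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        """Boolean mask of non-background voxels."""
        return self.labels != 0

    def as_grid(self, units: str = "label") -> VolumeGrid:
        return VolumeGrid(self.labels.astype(float), self.spacing, self.origin, units)

    def tissue_codes(self) -> list[int]:
        """Foreground codes present in the volume, sorted."""
        present = np.unique(self.labels)
        return [int(c) for c in present if c != 0]


# ---------------------------------------------------------------------------
# NIfTI I/O
#
# Arrays are stored in (x, y, z) index order with spacing on the affine
# diagonal; complex volumes are written as paired magnitude/phase files plus a
# JSON sidecar so everything on disk is a plain NIfTI-1 scalar volume.
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, expected_units: str = "a.u.") -> VolumeGrid:
    """Read a 3D (or single-frame 4D) NIfTI volume.

    A ``<stem>.imsar.json`` sidecar written by :func:`write_volume` for a
    complex map is honoured transparently: the magnitude/phase pair is
    recombined into a complex :class:`VolumeGrid`.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("complex"):
            mag = _read_scalar(Path(meta["magnitude"]), expected_units)
            pha = _read_scalar(Path(meta["phase"]), "rad")
            data = mag.data * np.exp(1j * pha.data)
            return VolumeGrid(data, mag.spacing, mag.origin, expected_units)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    return _read_scalar(path, expected_units)


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    return path.parent / f"{stem}.imsar.json"


def _read_scalar(path: Path, units: str) -> VolumeGrid:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise FormatError(f"{path}: 4D volume with {data.shape[3]} frames, expected 1")
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D payload, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(np.asarray(img.affine)[:3, 3].tolist())
    return VolumeGrid(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin, units)


def write_volume(v: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1.

    Complex volumes are stored as two real volumes (``<stem>_mag`` /
    ``<stem>_phase``) plus a JSON sidecar tag so :func:`read_volume` can
    reconstruct the complex values.
    """
    path = Path(path)
    if np.iscomplexobj(v.data):
        stem = path.name
        for ext in (".nii.gz", ".nii"):
            if stem.endswith(ext):
                stem, suffix = stem[: -len(ext)], ext
                break
        else:
            stem, suffix = stem, ".nii"
        mag_path = path.parent / f"{stem}_mag{suffix}"
        pha_path = path.parent / f"{stem}_phase{suffix}"
        _write_scalar(v.with_data(np.abs(v.data)), mag_path)
        _write_scalar(v.with_data(np.angle(v.data), units="rad"), pha_path)
        sidecar = _sidecar_path(path)
        sidecar.write_text(
            json.dumps(
                {"complex": True, "magnitude": str(mag_path), "phase": str(pha_path), "units": v.units},
                indent=1,
            )
        )
        return
    _write_scalar(v, path)


def _write_scalar(v: VolumeGrid, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_reference(
    moving: VolumeGrid, reference: "VolumeGrid | TissueLabelMap", mode: str = "linear"
) -> VolumeGrid:
    """Resample ``moving`` onto the grid of ``reference``.

    Interpolation is trilinear in physical (mm) space for ``mode="linear"``
    and nearest-neighbour for ``mode="nearest"`` (mandatory for label maps).
    Voxels outside the support of ``moving`` are filled with 0 (background).
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    ref_spacing = reference.spacing
    ref_origin = reference.origin
    ref_shape = reference.shape

    mlo, mhi = moving.physical_extent()
    rlo = np.asarray(ref_origin, dtype=float)
    rhi = rlo + (np.asarray(ref_shape) - 1) * np.asarray(ref_spacing)
    if np.any(rhi < mlo) or np.any(rlo > mhi):
        raise EmptyOverlapError("moving and reference volumes have disjoint physical extents")

    # Shortcut: identical geometry, no interpolation needed.
    if (
        moving.shape == tuple(ref_shape)
        and np.allclose(moving.spacing, ref_spacing)
        and np.allclose(moving.origin, ref_origin)
    ):
        return VolumeGrid(moving.data.copy(), ref_spacing, ref_origin, moving.units)

    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in ref_shape], indexing="ij")
    coords_mm = [g * s + o for g, s, o in zip(grids, ref_spacing, ref_origin)]
    coords_idx = np.stack(
        [(c - o) / s for c, s, o in zip(coords_mm, moving.spacing, moving.origin)]
    )

    order = 1 if mode == "linear" else 0

    def _interp(arr: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(arr, coords_idx, order=order, mode="constant", cval=0.0)

    if np.iscomplexobj(moving.data):
        out = _interp(moving.data.real) + 1j * _interp(moving.data.imag)
    else:
        out = _interp(np.asarray(moving.data, dtype=np.float64))
    return VolumeGrid(out, tuple(ref_spacing), tuple(ref_origin), moving.units)


def resample_labels_to_reference(moving: TissueLabelMap, reference: VolumeGrid) -> TissueLabelMap:
    """Nearest-neighbour resampling of a label map onto a reference grid."""
    as_grid = VolumeGrid(moving.labels.astype(np.float64), moving.spacing, moving.origin, "label")
    out = resample_to_reference(as_grid, reference, mode="nearest")
    return TissueLabelMap(
        np.round(out.data).astype(np.int32), out.spacing, out.origin, dict(moving.code_table)
    )
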