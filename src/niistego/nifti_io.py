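"""NIfTI-1 volume I/O and slice planning.

Thin wrapper around nibabel keeping exactly the header state the codec
needs: the affine, voxel spacing, the calibration range (``cal_min`` /
``cal_max``, which transports the volume-wide normalization range to the
blind receiver) and the free-text ``descrip`` field (which transports the
codec parameters).  Data round-trips bit-exactly in the stored dtype.

Conventions: slices run along the third array axis of the stored grid
(``m x n x S``), slice indices are 0-based, and within a slice axis 0 is the
row (m) and axis 1 the column (n).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["FormatError", "VolumeImage", "SliceImage", "read_volume", "write_volume",
           "plan_slices", "assemble_volume"]


class FormatError(ValueError):
    """Raised for files the codec cannot operate on (wrong format or shape)."""


@dataclass
class VolumeImage:
    """A 3-D voxel grid plus the header state the codec preserves."""

    data: np.ndarray
    affine: np.ndarray
    voxel_sizes: tuple[float, float, float]
    cal_min: float = 0.0
    cal_max: float = 0.0
    descrip: str = ""
    float_input: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"only 3-D volumes supported, got {self.data.ndim}-D shape {self.data.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def vmin(self) -> float:
        return float(self.data.min())

    @property
    def vmax(self) -> float:
        return float(self.data.max())

    def with_data(self, data: np.ndarray, **header_changes) -> "VolumeImage":
        """Copy of this volume with new voxel data (and optional header edits)."""
        return replace(self, data=data, **header_changes)


@dataclass
class SliceImage:
    """One m x n plane of a volume and its 0-based position on the slice axis."""

    values: np.ndarray
    index: int

    @property
    def dtype(self) -> np.dtype:
        return np.asarray(self.values).dtype


def read_volume(path: str | Path) -> VolumeImage:
    """Load a 3-D NIfTI-1 volume (``.nii`` or ``.nii.gz``).

    Integer voxel data is returned in the on-disk dtype.  Float-typed inputs
    are accepted but flagged via ``float_input`` so the pipeline can insist
    on an explicit target dtype.  4-D and higher files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad magic
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    shape = img.shape
    if len(shape) != 3:
        raise FormatError(
            f"only 3-D volumes supported, got {len(shape)}-D shape {shape} in {path}"
        )
    data = np.asanyarray(img.dataobj)
    disk_dtype = img.get_data_dtype()
    hdr = img.header
    slope, inter = hdr.get_slope_inter()
    unscaled = slope in (None, 1.0) and inter in (None, 0.0)
    if unscaled and data.dtype != disk_dtype:
        data = data.astype(disk_dtype)
    zooms = tuple(float(z) for z in hdr.get_zooms()[:3])
    return VolumeImage(
        data=data,
        affine=img.affine,
        voxel_sizes=zooms,
        cal_min=float(hdr["cal_min"]),
        cal_max=float(hdr["cal_max"]),
        descrip=bytes(hdr["descrip"]).decode("ascii", errors="replace").rstrip("\x00"),
        float_input=np.issubdtype(data.dtype, np.floating),
    )


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1; ``.nii.gz`` extensions get gzip containers.

    The stored dtype is the array dtype, and the calibration and description
    fields are written verbatim so a re-read reproduces the volume exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.set_data_dtype(vol.dtype)
    hdr = img.header
    hdr.set_zooms(vol.voxel_sizes)
    hdr["cal_min"] = vol.cal_min
    hdr["cal_max"] = vol.cal_max
    hdr["descrip"] = vol.descrip.encode("ascii", errors="replace")[:79]
    nib.save(img, path)


def plan_slices(vol: VolumeImage) -> list[SliceImage]:
    """Split a volume into its S slice planes, in ascending index order."""
    return [SliceImage(values=vol.data[:, :, k], index=k) for k in range(vol.n_slices)]


def assemble_volume(slices: list[SliceImage], template: VolumeImage) -> VolumeImage:
    """Stack slices back into a volume, borrowing header state from ``template``.

    All slices must share shape and dtype; the slice-axis dimension of the
    result is simply the number of slices supplied.
    """
    if not slices:
        raise ValueError("cannot assemble a volume from zero slices")
    first = np.asarray(slices[0].values)
    for s in slices[1:]:
        v = np.asarray(s.values)
        if v.shape != first.shape:
            raise ValueError(f"slice shape mismatch: {v.shape} vs {first.shape}")
        if v.dtype != first.dtype:
            raise ValueError(f"slice dtype mismatch: {v.dtype} vs {first.dtype}")
    data = np.stack([np.asarray(s.values) for s in slices], axis=2)
    return template.with_data(data)
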