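"""Volume-level downsampling / upsampling and size accounting.

Downsampling pairs consecutive slices — (0, 1), (2, 3), ... — and replaces
each pair by one stego slice: the even (cover) slice carrying the odd
(message) slice in its DCT detail coefficients.  An odd trailing slice
passes through unchanged with a parity flag.  The codec parameters, the
original slice count and the parity flag travel in the NIfTI ``descrip``
field, and the volume-wide normalization range in ``cal_min``/``cal_max``,
so the stego file is self-describing and upsampling is blind.

Upsampling emits, for every stego slice, the stego plane itself (standing in
for the original even slice) followed by the blindly extracted odd slice,
restoring the original slice count exactly.  The codec is deterministic:
identical input and configuration give bit-identical output.
"""

from __future__ import annotations

import gzip
import os
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nifti_io import FormatError, VolumeImage
from .quantization import QuantizationParams, embed_slice, extract_slice

__all__ = ["CodecConfig", "downsample_volume", "upsample_volume", "size_report",
           "format_metadata", "parse_metadata"]

_META_PREFIX = "qh1"
_RANGE_MODES = ("volume", "per-slice")


@dataclass
class CodecConfig:
    """Pipeline options: interval count, normalization policy and geometry.

    ``range_mode`` "volume" normalizes every slice against the volume-wide
    extrema (recorded in the calibration header; range-exact and blind);
    "per-slice" normalizes each slice by its own extrema and accepts range
    drift at extraction.  ``slice_axis`` selects which stored array axis the
    slices run along.
    """

    beta: int = 500
    range_mode: str = "volume"
    slice_axis: int = 2
    median_padding: str = "zero"
    float_dtype: str | None = None  # explicit target dtype for float inputs

    def __post_init__(self) -> None:
        if not (2 <= int(self.beta) <= 10**6):
            raise ValueError(f"beta must be in [2, 1e6], got {self.beta}")
        if self.range_mode not in _RANGE_MODES:
            raise ValueError(f"range_mode must be one of {_RANGE_MODES}")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")

    def params(self) -> QuantizationParams:
        return QuantizationParams(beta=int(self.beta))


def format_metadata(beta: int, range_mode: str, n_slices: int, parity: bool) -> str:
    """Compact self-description stored in the 80-char NIfTI descrip field."""
    rm = "v" if range_mode == "volume" else "s"
    s = f"{_META_PREFIX};b={beta};S={n_slices};rm={rm};p={int(parity)}"
    assert len(s) < 80, "codec metadata exceeds the NIfTI descrip field"
    return s


def parse_metadata(descrip: str) -> dict | None:
    """Parse codec metadata back out of a descrip string; None if absent."""
    m = re.match(rf"{_META_PREFIX};b=(\d+);S=(\d+);rm=([vs]);p=([01])", descrip)
    if m is None:
        return None
    return {
        "beta": int(m.group(1)),
        "n_slices": int(m.group(2)),
        "range_mode": "volume" if m.group(3) == "v" else "per-slice",
        "parity": bool(int(m.group(4))),
    }


def _to_slice_last(data: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(data, axis, 2)


def _scaled_zooms(zooms: tuple, axis: int, factor: float) -> tuple:
    z = list(zooms)
    z[axis] = z[axis] * factor
    return tuple(z)


def downsample_volume(vol: VolumeImage, cfg: CodecConfig) -> VolumeImage:
    """Compress a volume to ``floor(S/2) + (S mod 2)`` stego slices.

    Requires at least 2 slices and a 4x4-tileable plane.  Float-typed input
    is rejected unless ``cfg.float_dtype`` names the integer dtype to store
    stego slices in.  The output header records the codec parameters
    (descrip), the normalization range (cal_min/cal_max) and doubles the
    slice-axis voxel spacing so the file stays geometrically sensible.
    """
    data = _to_slice_last(vol.data, cfg.slice_axis)
    m, n, s = data.shape
    if s < 2:
        raise FormatError(f"need at least 2 slices to pair, got {s}")
    if m < 4 or n < 4:
        raise FormatError(f"slice plane {m}x{n} is smaller than one 4x4 block")
    if np.issubdtype(data.dtype, np.floating):
        if cfg.float_dtype is None:
            raise FormatError(
                "float-typed volume: pass an explicit integer dtype "
                "(CodecConfig.float_dtype) to quantize into"
            )
        data = np.asarray(
            np.clip(np.rint(data), np.iinfo(cfg.float_dtype).min,
                    np.iinfo(cfg.float_dtype).max),
            dtype=cfg.float_dtype,
        )

    vmin, vmax = float(data.min()), float(data.max())
    shared = (vmin, vmax) if cfg.range_mode == "volume" else (None, None)
    params = cfg.params()

    stego_slices = [
        embed_slice(data[:, :, 2 * k], data[:, :, 2 * k + 1], params,
                    lo=shared[0], hi=shared[1])
        for k in range(s // 2)
    ]
    parity = bool(s % 2)
    if parity:
        stego_slices.append(data[:, :, -1].copy())

    out = np.moveaxis(np.stack(stego_slices, axis=2), 2, cfg.slice_axis)
    return vol.with_data(
        out,
        voxel_sizes=_scaled_zooms(vol.voxel_sizes, cfg.slice_axis, 2.0),
        cal_min=vmin,
        cal_max=vmax,
        descrip=format_metadata(cfg.beta, cfg.range_mode, s, parity),
    )


def upsample_volume(stego_vol: VolumeImage, cfg: CodecConfig | None = None) -> VolumeImage:
    """Blindly reconstruct the full slice count from a stego volume.

    Codec parameters are read from the header metadata written by
    :func:`downsample_volume`; an explicit ``cfg`` overrides beta /
    range_mode / slice_axis when the metadata is absent or untrusted.
    """
    meta = parse_metadata(stego_vol.descrip)
    if meta is None and cfg is None:
        raise FormatError(
            "stego volume carries no codec metadata; supply a CodecConfig with beta"
        )
    axis = cfg.slice_axis if cfg is not None else 2
    beta = cfg.beta if cfg is not None else meta["beta"]
    range_mode = cfg.range_mode if cfg is not None else meta["range_mode"]
    median_padding = cfg.median_padding if cfg is not None else "zero"
    if meta is not None and cfg is not None:
        # header metadata wins for quantities the encoder recorded
        beta, range_mode = meta["beta"], meta["range_mode"]
    parity = meta["parity"] if meta is not None else False
    params = QuantizationParams(beta=beta)

    data = _to_slice_last(stego_vol.data, axis)
    s_stego = data.shape[2]
    n_pairs = s_stego - 1 if parity else s_stego
    if range_mode == "volume":
        lo, hi = stego_vol.cal_min, stego_vol.cal_max
        if hi <= lo:  # calibration fields missing; degrade to per-slice
            lo = hi = None
    else:
        lo = hi = None

    out_slices: list[np.ndarray] = []
    for k in range(n_pairs):
        stego = data[:, :, k]
        out_slices.append(stego)
        out_slices.append(
            extract_slice(stego, params, lo=lo, hi=hi, median_padding=median_padding)
        )
    if parity:
        out_slices.append(data[:, :, -1])

    out = np.moveaxis(np.stack(out_slices, axis=2), 2, axis)
    return stego_vol.with_data(
        out,
        voxel_sizes=_scaled_zooms(stego_vol.voxel_sizes, axis, 0.5),
        descrip="",
    )


def size_report(
    original_path: str | Path, stego_path: str | Path, include_gzip: bool = False
) -> dict:
    """Byte-size accounting for an original/stego file pair.

    Reports on-disk container sizes, raw voxel-data sizes derived from the
    headers, the stego/original ratios, and (optionally) the sizes after
    gzip recompression of each container.
    """
    import nibabel as nib

    original_path, stego_path = Path(original_path), Path(stego_path)
    for p in (original_path, stego_path):
        if not p.exists():
            raise FileNotFoundError(p)

    def raw_bytes(p: Path) -> int:
        img = nib.load(p)
        return int(np.prod(img.shape)) * img.get_data_dtype().itemsize

    report = {
        "original_disk_bytes": os.path.getsize(original_path),
        "stego_disk_bytes": os.path.getsize(stego_path),
        "original_raw_bytes": raw_bytes(original_path),
        "stego_raw_bytes": raw_bytes(stego_path),
    }
    report["disk_ratio"] = report["stego_disk_bytes"] / report["original_disk_bytes"]
    report["raw_ratio"] = report["stego_raw_bytes"] / report["original_raw_bytes"]
    if include_gzip:
        for key, p in (("original", original_path), ("stego", stego_path)):
            report[f"{key}_gzip_bytes"] = len(gzip.compress(p.read_bytes(), compresslevel=6))
        report["gzip_ratio"] = report["stego_gzip_bytes"] / report["original_gzip_bytes"]
    return report
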