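"""Quantization-index-modulation embedding and blind extraction.

The codec hides one normalized slice (the message) inside the 4x4 DCT
detail coefficients of another (the cover).  The magnitude axis of each
detail coefficient is partitioned into ``beta`` intervals of width
``2/beta``; embedding replaces the coefficient by a point inside its own
interval whose fractional position encodes the message pixel:

    stego = sign(c) * (2/beta) * (m + i),   i = floor(|c| * beta / 2)

Because the interval index ``i`` is preserved, a receiver holding only the
stego slice and ``beta`` recovers ``m`` as ``(beta/2) * (|stego| - 2i/beta)``
— the scheme is blind.  The approximation (DC) coefficient is never touched,
which keeps the stego slice visually close to the cover; at extraction the
message pixel sitting at each block's (0, 0) position is irrecoverable and
is filled with the mean of its two nearest reconstructed neighbours.

Larger ``beta`` means finer intervals, hence smaller displacement of the
cover coefficients (better stego fidelity) but also higher sensitivity of
the encoded message to the integer rounding incurred when the stego slice
is stored in the cover's dtype (worse reconstruction fidelity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .block_transform import forward_block, inverse_block, tile, untile

__all__ = [
    "QuantizationParams",
    "NormalizedSlice",
    "normalize",
    "denormalize",
    "interval_index",
    "embed_block",
    "extract_block",
    "embed_slice",
    "extract_slice",
    "median_filter_3x3",
]

#: default clamp keeping normalized message values strictly below 1; m == 1
#: exactly would land on the next interval's lower boundary and decode as 0.
DEFAULT_MSG_CLAMP_EPS = 2.0**-12


@dataclass
class QuantizationParams:
    """Codec parameters: interval count ``beta`` and the message clamp."""

    beta: int = 500
    msg_clamp_eps: float = DEFAULT_MSG_CLAMP_EPS

    def __post_init__(self) -> None:
        if not (isinstance(self.beta, (int, np.integer)) and self.beta >= 2):
            raise ValueError(f"beta must be an integer >= 2, got {self.beta!r}")
        if not (0.0 < self.msg_clamp_eps <= 2.0**-10):
            raise ValueError("msg_clamp_eps must lie in (0, 2**-10]")


@dataclass
class NormalizedSlice:
    """A slice mapped linearly into [0, 1] plus the range that produced it."""

    values: np.ndarray
    src_min: float
    src_max: float
    constant: bool = field(default=False)


def normalize(values: np.ndarray, lo: float, hi: float) -> NormalizedSlice:
    """Linear map ``(values - lo) / (hi - lo)`` clipped to [0, 1].

    The degenerate ``hi == lo`` case (constant slice) yields all zeros with
    the ``constant`` flag set so callers can skip embedding.
    """
    if hi < lo:
        raise ValueError(f"normalization range inverted: lo={lo}, hi={hi}")
    values = np.asarray(values, dtype=np.float64)
    if hi == lo:
        return NormalizedSlice(np.zeros_like(values), float(lo), float(hi), constant=True)
    out = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    return NormalizedSlice(out, float(lo), float(hi))


def denormalize(values: np.ndarray, lo: float, hi: float, dtype: np.dtype | type) -> np.ndarray:
    """Map [0, 1] values back to ``[lo, hi]``, round and clamp to ``dtype``.

    Input outside the normalized domain is clipped to [0, 1] first, so the
    output never escapes ``[lo, hi]`` (the inverse-DCT of a stego block can
    overshoot slightly).
    """
    if hi < lo:
        raise ValueError(f"denormalization range inverted: lo={lo}, hi={hi}")
    real = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0) * (hi - lo) + lo
    dtype = np.dtype(dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        real = np.clip(np.rint(real), info.min, info.max)
    return real.astype(dtype)


def interval_index(c_abs: np.ndarray | float, beta: int) -> np.ndarray | int:
    """Quantization interval of a coefficient magnitude.

    Intervals are lower-closed (``2i/beta`` belongs to interval ``i``) and the
    top interval absorbs any magnitude >= 2, so the index is always in
    ``[0, beta - 1]``.  A 1e-9 tolerance keeps magnitudes that sit exactly on
    a boundary (a zero message value lands there by construction) from
    falling into the previous interval through floating-point roundoff; the
    same rule runs at embed and extract time, so the two always agree.
    """
    pos = np.asarray(c_abs, dtype=np.float64) * beta / 2.0
    idx = np.minimum(np.floor(pos + 1e-9), beta - 1)
    idx = idx.astype(np.int64)
    return int(idx) if idx.ndim == 0 else idx


def embed_block(
    cover_cb: np.ndarray, msg_mb: np.ndarray, params: QuantizationParams
) -> np.ndarray:
    """Embed message pixels into a cover coefficient block (batched over (...,4,4)).

    The DC position (0, 0) is copied from the cover bit-exactly; each of the
    fifteen detail positions moves to the in-interval point encoding the
    corresponding message pixel.  ``sign(0)`` is taken as +1; extraction uses
    absolute values, so the choice is immaterial.
    """
    cover_cb = np.asarray(cover_cb, dtype=np.float64)
    msg = np.clip(np.asarray(msg_mb, dtype=np.float64), 0.0, 1.0 - params.msg_clamp_eps)
    sign = np.where(cover_cb >= 0.0, 1.0, -1.0)
    i = interval_index(np.abs(cover_cb), params.beta)
    stego = sign * (2.0 / params.beta) * (msg + i)
    stego[..., 0, 0] = cover_cb[..., 0, 0]
    return stego


def extract_block(stego_cb: np.ndarray, params: QuantizationParams) -> np.ndarray:
    """Recover message pixels from a stego coefficient block (batched).

    The fractional position of each detail coefficient inside its interval is
    the message value; the unrecoverable (0, 0) position is filled with the
    mean of the reconstructed values at (0, 1) and (1, 0), the nearest
    spatial neighbours.
    """
    a = np.abs(np.asarray(stego_cb, dtype=np.float64))
    i = interval_index(a, params.beta)
    msg = np.clip((params.beta / 2.0) * (a - 2.0 * i / params.beta), 0.0, 1.0)
    msg[..., 0, 0] = 0.5 * (msg[..., 0, 1] + msg[..., 1, 0])
    return msg


def _resolve_range(
    values: np.ndarray, lo: float | None, hi: float | None
) -> tuple[float, float]:
    if (lo is None) != (hi is None):
        raise ValueError("lo and hi must be given together or both omitted")
    if lo is None:
        return float(values.min()), float(values.max())
    return float(lo), float(hi)


def embed_slice(
    cover: np.ndarray,
    msg: np.ndarray,
    params: QuantizationParams,
    lo: float | None = None,
    hi: float | None = None,
    cast: bool = True,
) -> np.ndarray:
    """Produce the stego slice hiding ``msg`` inside ``cover``.

    With ``lo``/``hi`` given, both slices are normalized against that shared
    range (volume mode — the range travels in the NIfTI calibration header so
    extraction stays blind).  Without them each slice is normalized against
    its own extrema (literal per-slice mode, with range drift at extraction).

    Margins outside the 4x4 grid are copied from the cover.  A constant
    cover carries no detail coefficients to modulate, so it is returned
    unchanged.  ``cast=False`` returns the normalized float plane instead of
    denormalizing into the cover's dtype (used for float-domain analysis).
    """
    cover = np.asarray(cover)
    msg = np.asarray(msg)
    if cover.shape != msg.shape:
        raise ValueError(f"cover {cover.shape} and msg {msg.shape} shapes differ")
    if cover.dtype != msg.dtype:
        raise ValueError(f"cover {cover.dtype} and msg {msg.dtype} dtypes differ")

    c_lo, c_hi = _resolve_range(cover, lo, hi)
    m_lo, m_hi = _resolve_range(msg, lo, hi)
    ncover = normalize(cover, c_lo, c_hi)
    nmsg = normalize(msg, m_lo, m_hi)
    if ncover.constant:
        return ncover.values if not cast else cover.copy()

    cgrid = tile(ncover.values)
    mgrid = tile(nmsg.values)
    stego_coeffs = embed_block(forward_block(cgrid.blocks), mgrid.blocks, params)
    cgrid.blocks = inverse_block(stego_coeffs)
    stego_norm = untile(cgrid)
    if not cast:
        return stego_norm
    return denormalize(stego_norm, c_lo, c_hi, cover.dtype)


def extract_slice(
    stego: np.ndarray,
    params: QuantizationParams,
    lo: float | None = None,
    hi: float | None = None,
    median_padding: str = "zero",
    cast: bool = True,
    apply_median: bool = True,
) -> np.ndarray:
    """Blindly reconstruct the hidden slice from a stego slice.

    Needs only the stego plane, ``beta`` and the normalization range (shared
    volume range, or the stego's own extrema when none is given).  Margins,
    which carried no payload, are filled with the stego's values — the best
    blind estimate given strong adjacent-slice correlation.  A 3x3 median
    filter smooths the block-DC artefacts; disable it (and casting) to study
    the raw float-domain reconstruction.
    """
    stego = np.asarray(stego)
    s_lo, s_hi = _resolve_range(stego, lo, hi)
    nstego = normalize(stego, s_lo, s_hi)
    grid = tile(nstego.values)
    grid.blocks = extract_block(forward_block(grid.blocks), params)
    recon_norm = untile(grid)
    if not cast:
        return recon_norm
    recon = denormalize(recon_norm, s_lo, s_hi, stego.dtype)
    if apply_median:
        recon = median_filter_3x3(recon, padding=median_padding)
    return recon


def median_filter_3x3(values: np.ndarray, padding: str = "zero") -> np.ndarray:
    """3x3 neighbourhood median of every pixel.

    ``padding`` is ``"zero"`` (borders padded with 0) or ``"replicate"``
    (nearest edge value).
    """
    modes = {"zero": dict(mode="constant", cval=0), "replicate": dict(mode="nearest")}
    if padding not in modes:
        raise ValueError(f"padding must be one of {sorted(modes)}, got {padding!r}")
    return ndimage.median_filter(np.asarray(values), size=3, **modes[padding])
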