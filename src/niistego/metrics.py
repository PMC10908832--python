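"""Image-quality metrics for codec evaluation.

PSNR and SNR are the usual logarithmic fidelity measures; SSIM is the mean
local structural-similarity index (11x11 Gaussian window, sigma 1.5,
c1 = (0.01 L)^2, c2 = (0.03 L)^2 for peak value L); entropy is the Shannon
information of the intensity histogram after affine rescaling onto 256 bins;
BER is the fraction of differing bits between the binary sample
representations of two equal-dtype images.  Box-plot style five-number
summaries use the linear-interpolation percentile convention.

Two aggregation flavours are provided because they answer different
questions: per-slice metrics averaged over slices (how does a typical slice
fare?) and a single whole-volume metric treating the volume as one image
(how does the file fare?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["psnr", "snr", "ssim", "entropy", "ber", "five_number",
           "peak_value", "QualityReport", "slice_metrics", "volume_metrics"]


def peak_value(dtype: np.dtype | type) -> float:
    """Dynamic range of a sample dtype (65535 for uint16, 255 for uint8...)."""
    dtype = np.dtype(dtype)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.max - info.min)
    return 1.0


def _as_float_pair(f: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f, g = np.asarray(f), np.asarray(g)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    return f.astype(np.float64), g.astype(np.float64)


def psnr(f: np.ndarray, g: np.ndarray, peakval: float) -> float:
    """Peak signal-to-noise ratio in dB; infinity for identical images."""
    f, g = _as_float_pair(f, g)
    mse = np.mean((f - g) ** 2)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peakval**2 / mse))


def snr(f: np.ndarray, g: np.ndarray) -> float:
    """Signal-to-noise ratio in dB, signal power taken from the reference ``f``.

    Identical images give infinity; an all-zero reference has no defined
    signal level and returns NaN.
    """
    f, g = _as_float_pair(f, g)
    noise = np.sum((f - g) ** 2)
    signal = np.sum(f**2)
    if signal == 0.0:
        return float("nan")
    if noise == 0.0:
        return float("inf")
    return float(10.0 * np.log10(signal / noise))


def ssim(f: np.ndarray, g: np.ndarray, peakval: float) -> float:
    """Mean structural similarity index over 11x11 Gaussian windows."""
    f, g = _as_float_pair(f, g)
    if min(f.shape) < 11:
        raise ValueError(f"image {f.shape} smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            f, g, data_range=peakval, gaussian_weights=True, sigma=1.5,
            win_size=11, use_sample_covariance=False,
        )
    )


def entropy(img: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the rescaled intensity histogram.

    Intensities are affinely mapped onto ``bins`` levels before the
    histogram, matching the common image-toolbox convention; a constant
    image occupies one bin and has zero entropy.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("entropy of an empty image is undefined")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return 0.0
    levels = np.rint((img - lo) / (hi - lo) * (bins - 1)).astype(np.int64)
    counts = np.bincount(levels.ravel(), minlength=bins)
    p = counts[counts > 0] / img.size
    return float(-np.sum(p * np.log2(p)))


def ber(f: np.ndarray, g: np.ndarray) -> float:
    """Bit error rate: differing bits / total bits of the binary sample forms."""
    f, g = np.asarray(f), np.asarray(g)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    if f.dtype != g.dtype:
        raise ValueError(f"dtype mismatch: {f.dtype} vs {g.dtype}")
    if not np.issubdtype(f.dtype, np.integer):
        raise ValueError("BER is defined for integer sample types")
    xor = np.bitwise_xor(f, g)
    diff_bits = int(np.unpackbits(np.ascontiguousarray(xor).view(np.uint8)).sum())
    total_bits = f.size * f.dtype.itemsize * 8
    return diff_bits / total_bits


def five_number(values) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with linear-interpolation percentiles."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("five-number summary of an empty sequence is undefined")
    return tuple(float(v) for v in np.percentile(values, [0, 25, 50, 75, 100]))


@dataclass
class QualityReport:
    """Per-slice metric table plus per-volume aggregates and five-number summaries."""

    per_slice: pd.DataFrame          # columns: slice_index, metric, value
    aggregates: dict[str, float]     # mean over slices, per metric
    five_numbers: dict[str, tuple]   # five-number summary over slices, per metric

    def to_csv_frame(self, beta: int | None = None) -> pd.DataFrame:
        """Long-form table (metric, beta, slice_index, value) incl. aggregate rows."""
        rows = self.per_slice.copy()
        rows["slice_index"] = rows["slice_index"].astype(str)
        agg = pd.DataFrame(
            [{"slice_index": "mean", "metric": m, "value": v}
             for m, v in self.aggregates.items()]
        )
        out = pd.concat([rows, agg], ignore_index=True)
        out.insert(1, "beta", beta if beta is not None else "")
        return out[["metric", "beta", "slice_index", "value"]]


_METRIC_COLUMNS = ("psnr_db", "snr_db", "ssim", "entropy_bits", "ber_fraction")


def slice_metrics(reference: np.ndarray, test: np.ndarray,
                  peakval: float | None = None) -> QualityReport:
    """Per-slice quality of ``test`` against ``reference`` (slices on axis 2)."""
    reference, test = np.asarray(reference), np.asarray(test)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if peakval is None:
        peakval = peak_value(reference.dtype)
    records = []
    for k in range(reference.shape[2]):
        f, g = reference[:, :, k], test[:, :, k]
        vals = {
            "psnr_db": psnr(f, g, peakval),
            "snr_db": snr(f, g),
            "ssim": ssim(f, g, peakval),
            "entropy_bits": entropy(g),
            "ber_fraction": ber(f, g) if f.dtype == g.dtype
            and np.issubdtype(f.dtype, np.integer) else float("nan"),
        }
        records.extend(
            {"slice_index": k, "metric": m, "value": v} for m, v in vals.items()
        )
    table = pd.DataFrame.from_records(records)
    finite_mean = {}
    fives = {}
    for m in _METRIC_COLUMNS:
        v = table.loc[table["metric"] == m, "value"].to_numpy()
        finite = v[np.isfinite(v)]
        finite_mean[m] = float(finite.mean()) if finite.size else float("nan")
        fives[m] = five_number(finite) if finite.size else (float("nan"),) * 5
    return QualityReport(per_slice=table, aggregates=finite_mean, five_numbers=fives)


def volume_metrics(reference: np.ndarray, test: np.ndarray,
                   peakval: float | None = None) -> dict[str, float]:
    """Whole-volume single-value metrics (the volume treated as one image)."""
    reference, test = np.asarray(reference), np.asarray(test)
    if peakval is None:
        peakval = peak_value(reference.dtype)
    out = {
        "psnr_db": psnr(reference, test, peakval),
        "snr_db": snr(reference, test),
        "entropy_bits": entropy(test),
    }
    if reference.dtype == test.dtype and np.issubdtype(reference.dtype, np.integer):
        out["ber_fraction"] = ber(reference, test)
    # mean over per-slice SSIM: the windowed statistic is 2-D by construction
    out["ssim"] = float(np.mean([
        ssim(reference[:, :, k], test[:, :, k], peakval)
        for k in range(reference.shape[2])
    ]))
    return out
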