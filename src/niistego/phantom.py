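"""Deterministic synthetic MRI-like volumes for tests and demos.

A phantom is a sum of smooth ellipsoidal Gaussian blobs whose in-plane
centres and amplitudes drift slowly along the slice axis, plus optional
Gaussian noise, affinely mapped into the integer dtype range.  The point is
statistical structure, not anatomical realism: smooth intensity plateaus and
strong adjacent-slice correlation, the two properties that make embedding a
slice into its neighbour meaningful.  ``slice_drift`` tunes how fast
consecutive slices decorrelate (0 gives identical slices); the same seed
always reproduces the same volume bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nifti_io import VolumeImage, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "write_fixture_set"]


@dataclass
class PhantomSpec:
    """Recipe for one seeded phantom volume.

    ``noise_sd`` is in final intensity units; ``slice_drift`` is the
    per-slice fractional displacement of blob centres and amplitudes.
    ``value_range`` defaults to [0, min(4000, dtype max)] — real MR
    magnitudes rarely fill the stored dtype's range.
    """

    shape: tuple[int, int, int] = (64, 64, 8)
    dtype: str = "uint16"
    seed: int = 0
    n_blobs: int = 12
    noise_sd: float = 20.0
    slice_drift: float = 0.05
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        m, n, s = self.shape
        if m < 16 or n < 16 or s < 4:
            raise ValueError(f"phantom shape must be at least 16x16x4, got {self.shape}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_blobs < 1:
            raise ValueError("need at least one blob")

    def resolved_range(self) -> tuple[float, float]:
        if self.value_range is not None:
            return self.value_range
        info = np.iinfo(np.dtype(self.dtype))
        return (max(0, info.min), min(4000, info.max))


def generate_phantom(spec: PhantomSpec) -> VolumeImage:
    """Render the phantom described by ``spec`` as a NIfTI-ready volume."""
    rng = np.random.default_rng(spec.seed)
    m, n, s = spec.shape
    dtype = np.dtype(spec.dtype)

    # blob parameters in normalized [0,1] in-plane coordinates
    centers = rng.uniform(0.15, 0.85, size=(spec.n_blobs, 2))
    sigmas = rng.uniform(0.06, 0.22, size=(spec.n_blobs, 2))
    amps = rng.uniform(0.3, 1.0, size=spec.n_blobs)
    drift_dir = rng.standard_normal(size=(spec.n_blobs, 2))
    drift_dir /= np.linalg.norm(drift_dir, axis=1, keepdims=True)
    amp_drift = rng.uniform(-1.0, 1.0, size=spec.n_blobs)

    y = np.linspace(0.0, 1.0, m)[:, None]
    x = np.linspace(0.0, 1.0, n)[None, :]
    field_ = np.zeros((m, n, s), dtype=np.float64)
    for k in range(s):
        t = k * spec.slice_drift
        ck = centers + t * drift_dir
        ak = amps * np.clip(1.0 + t * amp_drift, 0.2, 2.0)
        plane = np.zeros((m, n))
        for b in range(spec.n_blobs):
            plane += ak[b] * np.exp(
                -(
                    (y - ck[b, 0]) ** 2 / (2 * sigmas[b, 0] ** 2)
                    + (x - ck[b, 1]) ** 2 / (2 * sigmas[b, 1] ** 2)
                )
            )
        field_[:, :, k] = plane

    lo, hi = spec.resolved_range()
    span = field_.max() - field_.min()
    scaled = (field_ - field_.min()) / span * (hi - lo) + lo if span > 0 else \
        np.full_like(field_, lo)
    if spec.noise_sd > 0:
        scaled = scaled + rng.normal(0.0, spec.noise_sd, size=scaled.shape)
    info = np.iinfo(dtype)
    data = np.clip(np.rint(scaled), info.min, info.max).astype(dtype)

    return VolumeImage(
        data=data,
        affine=np.diag([1.0, 1.0, 1.0, 1.0]),
        voxel_sizes=(1.0, 1.0, 1.0),
        descrip="synthetic phantom",
    )


def write_fixture_set(directory: str | Path, betas: list[int] = (100, 500, 1000),
                      base_seed: int = 0) -> dict:
    """Write the standard phantom fixture files plus a manifest JSON.

    Covers the codec's interesting cases: even slice count, odd slice count,
    a plane size that is not a multiple of four, and a constant-slice volume
    (degenerate normalization).  Returns the manifest dict; regeneration
    with the same seeds is bit-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    specs = {
        "even_slices.nii.gz": PhantomSpec(shape=(32, 32, 8), seed=base_seed),
        "odd_slices.nii.gz": PhantomSpec(shape=(32, 32, 7), seed=base_seed + 1),
        "ragged_plane.nii.gz": PhantomSpec(shape=(30, 34, 6), seed=base_seed + 2),
    }
    entries = []
    for name, spec in specs.items():
        vol = generate_phantom(spec)
        write_volume(vol, directory / name)
        entries.append({
            "path": name, "shape": list(vol.shape), "dtype": str(vol.dtype),
            "seed": spec.seed,
            "params": {"n_blobs": spec.n_blobs, "noise_sd": spec.noise_sd,
                       "slice_drift": spec.slice_drift},
        })
    # constant-slice edge case: every slice one flat value
    const = VolumeImage(
        data=np.full((16, 16, 4), 1200, dtype=np.uint16),
        affine=np.eye(4), voxel_sizes=(1.0, 1.0, 1.0),
        descrip="synthetic constant phantom",
    )
    write_volume(const, directory / "constant_slices.nii.gz")
    entries.append({
        "path": "constant_slices.nii.gz", "shape": [16, 16, 4],
        "dtype": "uint16", "seed": None, "params": {"constant_value": 1200},
    })
    manifest = {"betas": list(betas), "fixtures": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
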