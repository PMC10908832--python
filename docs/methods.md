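# Methods

## Model and procedure

`niistego` implements a quantization-index-modulation (QIM) codec for 3-D
NIfTI volumes. The volume is planned into S slices along a configurable
axis (default: the third stored array axis). Consecutive slices form
cover/message pairs — the cover is the even slice, the message the next
one. Each pair yields one stego slice:

1. **Normalization.** Both slices are mapped linearly onto [0, 1]. In the
   default `volume` range mode the volume-wide extrema (v_min, v_max) are
   used for every slice; in `per-slice` mode each slice uses its own
   extrema.
2. **Tiling.** The normalized planes are partitioned into non-overlapping
   4×4 microblocks. Residual right/bottom strips (widths m mod 4, n mod 4)
   carry no payload and pass through unchanged.
3. **Transform.** Cover blocks go to the frequency domain with the
   orthonormal 4-point DCT-II, `C = T·MB·Tᵀ`. One approximation (DC)
   coefficient and fifteen detail coefficients result.
4. **Embedding.** For each detail coefficient c with message pixel m:
   `c' = sign(c)·(2/β)·(m + i)` where `i = ⌊|c|·β/2⌋` is the coefficient's
   quantization interval (β lower-closed intervals of width 2/β covering
   magnitudes [0, 2]). The DC coefficient is copied unchanged. Since the
   interval index is preserved, the receiver can recompute i from the stego
   coefficient alone — extraction is blind.
5. **Inverse transform and storage.** Inverse DCT, reassembly with the
   cover's margins, denormalization with the cover's range, round and cast
   into the cover's integer dtype. An odd trailing slice passes through
   unchanged with a parity flag.

Extraction reverses the chain: normalize the stego slice, tile, forward
DCT, recover `m̂ = (β/2)·(|c'| − 2i/β)` clipped to [0, 1], fill each
block's DC position with the mean of the reconstructed values at (0, 1)
and (1, 0) (its nearest spatial neighbours), reassemble with the stego's
margins as the margin estimate, denormalize, and apply a 3×3 median
filter. The upsampled volume interleaves each stego slice (standing in for
the original even slice) with its extracted message slice, restoring S
exactly.

Detail coefficients of [0, 1]-valued blocks provably satisfy |c| < 2
(sampled-vertex brute force in the tests), so the [0, 2] interval span
covers every embeddable coefficient; the DC, which reaches 4, is never
embedded.

## Header bookkeeping and blindness

The paper-level contract is that upsampling needs nothing but the stego
file. Two pieces of side information make that possible, both carried in
standard, always-present NIfTI-1 header fields of the stego file:

- `cal_min` / `cal_max`: the volume-wide normalization range (volume range
  mode would otherwise be undecodable — a blind receiver cannot know the
  original extrema).
- `descrip`: a compact `qh1;b=<β>;S=<S>;rm=<v|s>;p=<0|1>` string with the
  interval count, original slice count, range mode and parity flag. The
  string is provably shorter than the field's 80 characters for all legal
  parameter values, so no sidecar file is needed.

In `per-slice` range mode extraction falls back to the stego slice's own
extrema; this follows the normalization definition literally but accepts
range drift, and is provided for comparison rather than as the default.
The slice-axis voxel spacing is doubled in the stego header (the file
remains geometrically sensible) and restored on upsampling.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 500 | number of quantization intervals on the coefficient magnitude range [0, 2]. Larger β → finer intervals → less stego distortion but noisier blind extraction once the stego slice is rounded to integers. 100–1000 is the useful sweep. |
| `range_mode` | `volume` | normalization policy, see above. |
| `slice_axis` | 2 | stored array axis the slices run along. |
| `median_padding` | `zero` | border handling of the 3×3 median filter (`zero` or `replicate`). |
| `msg_clamp_eps` | 2⁻¹² | normalized message values are clamped to ≤ 1 − ε before embedding; m = 1 exactly would sit on the next interval's boundary and decode as 0. |

## Numerical choices

- **Interval boundaries** are lower-closed with a deterministic 1e-9
  tolerance inside the index computation (`⌊|c|·β/2 + 1e-9⌋`, clamped to
  β − 1). Without the tolerance a zero message value — which lands the
  stego coefficient *exactly* on a boundary — can fall into the previous
  interval through floating-point roundoff and decode as ≈ 1. The same rule
  runs at embed and extract time, so the two always agree.
- **sign(0) := +1.** Extraction uses absolute values, so any fixed choice
  is consistent.
- **Denormalization** clips its input to [0, 1] before scaling (the
  inverse DCT of a modulated block can overshoot slightly), then rounds to
  nearest and clamps to the dtype range.
- **Constant slices** (max == min) normalize to all zeros with a flag; a
  constant cover is passed through bit-exactly since it has no detail
  coefficients to modulate.
- **Stego slices are stored in the cover's integer dtype.** The 2:1 size
  claim requires it. The induced rounding noise (≤ 0.5 intensity unit per
  pixel) perturbs the stego coefficients by O(1/range) and the extracted
  message by β/2 times that, which is exactly why reconstruction quality
  falls as β grows while stego quality rises.
- In the float domain (no casting, no median filter) embed→extract is
  exact: every non-DC, non-margin message pixel is recovered to ≤ 1e-9.

## The synthetic phantom

Tests and the acceptance script run on seeded synthetic volumes: sums of
ellipsoidal Gaussian blobs whose in-plane centres and amplitudes drift
linearly along the slice axis (`slice_drift`, default 0.05 per slice),
plus Gaussian noise (`noise_sd`, default 20 intensity units), affinely
mapped to [0, min(4000, dtype max)] — real MR magnitudes rarely fill the
stored dtype's range, and a 12-bit-ish scale is typical. At the default
drift, adjacent slices correlate at r > 0.9, matching the strong
inter-slice similarity of structural MRI that makes the margin and DC
fill-ins reasonable estimates.

The phantom emulates smoothness and adjacent-slice correlation only. It has
no anatomy, no bias field, no Rician noise floor, and no air background
occupying most of the field of view; absolute metric values on real scans
will differ (in particular, a mostly-zero background reconstructs exactly
and lowers BER dramatically). Passing tests therefore establish the codec's
contracts — exactness, blindness, shape bookkeeping, the direction of the β
trade-off — not clinical image quality.

## Problem sizes

The test suite and acceptance script use 64×64 planes with 8–20 slice
pairs, 10⁴ random blocks per β for roundtrip checks, and the β sweep
{100, 200, …, 1000}. The β-monotonicity trend is statistical and is
averaged over 20 slice pairs; the whole-cycle quality numbers use a
64×64×16 phantom at β = 500. Full-scale evaluation on a real dataset is a
matter of pointing `niistego down/up/eval` at the files (the work is
embarrassingly parallel over slice pairs).

## Known limitations

- Lossy by design: even slices are replaced by stego slices, odd slices by
  blind reconstructions; there is no lossless mode.
- No keying or encryption of the embedding, and no robustness to lossy
  recompression of the stego file — the hidden signal lives in fragile
  low-order structure.
- 4-D (e.g. fMRI) inputs are rejected rather than processed frame-wise.
- β is global; no adaptive per-block interval allocation.
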