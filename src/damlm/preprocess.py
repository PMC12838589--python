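"""MRI harmonization pipeline.

z-score intensity normalization, multiplicative bias-field correction,
skull stripping, isotropic resampling, affine alignment, channel
stacking, and sliding-window patch extraction.  All statistics are
computed within the brain mask; background voxels stay zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import SEQUENCES, LabeledVolume


class DegenerateInputError(ValueError):
    pass


@dataclass
class MultiSequenceVolume:
    """4-channel volume with geometry and fitted normalization parameters."""

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    norm_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    domain_id: int | None = None

    @classmethod
    def from_labeled(cls, vol: LabeledVolume) -> "MultiSequenceVolume":
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing
        return cls(channels={k: v.copy() for k, v in vol.channels.items()},
                   spacing=tuple(vol.spacing), brain_mask=vol.brain_mask.copy(),
                   affine=aff, domain_id=vol.domain_id)

    def copy(self) -> "MultiSequenceVolume":
        return MultiSequenceVolume(
            channels={k: v.copy() for k, v in self.channels.items()},
            spacing=tuple(self.spacing), brain_mask=self.brain_mask.copy(),
            affine=self.affine.copy(), norm_params=dict(self.norm_params),
            domain_id=self.domain_id)


@dataclass
class BiasModel:
    """Decomposition v = b * t of an observed channel (residual absorbed)."""

    field: np.ndarray       # estimated multiplicative bias b, > 0 in mask
    signal: np.ndarray      # recovered tissue signal t = v / b
    residual: np.ndarray    # identically zero under this estimator
    intensity_shift: float  # shift applied to enforce positivity, 0 if none


# ---------------------------------------------------------------- operations
def zscore_normalize(channel: np.ndarray, mask: np.ndarray):
    """Standardize in-mask intensities to mean 0, variance 1 (ddof=0).

    Out-of-mask voxels are set to 0.  Returns (normalized, mu, sigma).
    """
    m = mask.astype(bool)
    if m.sum() < 2:
        raise DegenerateInputError("mask must contain at least 2 voxels")
    vals = channel[m]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    if sigma == 0:
        raise DegenerateInputError("zero in-mask intensity variance")
    out = np.zeros_like(channel, dtype=np.float64)
    out[m] = (vals - mu) / sigma
    return out, mu, sigma


def correct_bias_field(channel: np.ndarray, mask: np.ndarray,
                       smoothness_mm: float = 8.0,
                       spacing=(1.0, 1.0, 1.0)) -> BiasModel:
    """Estimate a smooth multiplicative bias field in the log domain.

    b = exp(S(log v) - mean_mask(S(log v))) with S a masked (normalized
    convolution) Gaussian of width `smoothness_mm`; t = v / b.  Under
    this estimator the additive residual is identically zero — the
    multiplicative model absorbs it into t — so v = b * t reconstructs
    the input exactly.  Nonpositive in-mask intensities are shifted up
    first and the shift recorded.
    """
    m = mask.astype(bool)
    v = channel.astype(np.float64)
    shift = 0.0
    inmask = v[m]
    if inmask.size == 0:
        raise DegenerateInputError("empty mask")
    lo = inmask.min()
    if lo <= 0:
        shift = -lo + 1e-3 * max(np.ptp(inmask), 1.0)
        v = v + shift
        if v[m].min() <= 0:
            raise DegenerateInputError("nonpositive in-mask intensities after shift")
    logv = np.zeros_like(v)
    logv[m] = np.log(v[m])
    sigma_vox = [smoothness_mm / s for s in spacing]
    num = ndimage.gaussian_filter(logv * m, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m.astype(np.float64), sigma=sigma_vox)
    smooth = np.where(den > 1e-8, num / np.maximum(den, 1e-8), 0.0)
    smooth -= smooth[m].mean()  # mean log-bias 0 inside the mask
    b = np.exp(smooth)
    t = v / b
    return BiasModel(field=b, signal=t, residual=np.zeros_like(v),
                     intensity_shift=shift)


def skull_strip(volume: MultiSequenceVolume) -> MultiSequenceVolume:
    """Multiply every channel by the binary brain mask (V ⊙ M)."""
    out = volume.copy()
    for seq, ch in out.channels.items():
        if ch.shape != out.brain_mask.shape:
            raise ValueError("channel/mask shape mismatch")
        out.channels[seq] = ch * out.brain_mask
    return out


def resample_isotropic(volume: MultiSequenceVolume, iso_mm: float) -> MultiSequenceVolume:
    """Resample all channels to isotropic `iso_mm` spacing.

    Channels use trilinear interpolation, the mask nearest-neighbor;
    output shape per axis is round(shape * spacing / iso_mm) and the
    affine is rescaled consistently.
    """
    if iso_mm <= 0:
        raise ValueError("target spacing must be positive")
    in_shape = volume.brain_mask.shape
    out_shape = tuple(int(round(n * s / iso_mm))
                      for n, s in zip(in_shape, volume.spacing))
    zoom = [o / i for o, i in zip(out_shape, in_shape)]
    out = volume.copy()
    out.channels = {seq: ndimage.zoom(ch, zoom, order=1, mode="nearest",
                                      grid_mode=True)
                    for seq, ch in volume.channels.items()}
    out.brain_mask = ndimage.zoom(volume.brain_mask, zoom, order=0,
                                  mode="nearest", grid_mode=True).astype(np.uint8)
    out.spacing = (iso_mm, iso_mm, iso_mm)
    new_aff = volume.affine.copy()
    for i in range(3):
        new_aff[:3, i] = volume.affine[:3, i] / zoom[i]
    out.affine = new_aff
    return out


def apply_affine(volume: MultiSequenceVolume, target_affine: np.ndarray) -> MultiSequenceVolume:
    """Resample the volume into the frame defined by `target_affine`.

    Output voxel j maps to input voxel i = A_cur^-1 @ A_target @ j.
    Channels are interpolated trilinearly, the mask nearest-neighbor.
    """
    if abs(np.linalg.det(target_affine)) < 1e-12:
        raise ValueError("target affine is singular")
    M = np.linalg.inv(volume.affine) @ target_affine
    mat, off = M[:3, :3], M[:3, 3]
    out = volume.copy()
    out.channels = {seq: ndimage.affine_transform(ch, mat, offset=off, order=1)
                    for seq, ch in volume.channels.items()}
    out.brain_mask = ndimage.affine_transform(
        volume.brain_mask, mat, offset=off, order=0).astype(np.uint8)
    out.affine = target_affine.copy()
    return out


def stack_sequences(t1: np.ndarray, t1ce: np.ndarray, t2: np.ndarray,
                    flair: np.ndarray) -> np.ndarray:
    """Concatenate channels in the fixed order [T1, T1ce, T2, FLAIR]."""
    grids = (t1, t1ce, t2, flair)
    if len({g.shape for g in grids}) != 1:
        raise ValueError("all sequences must share the same shape")
    return np.stack(grids, axis=0)


def unstack_sequences(x: np.ndarray) -> dict[str, np.ndarray]:
    return {seq: x[i] for i, seq in enumerate(SEQUENCES)}


# -------------------------------------------------------------------- patches
@dataclass(frozen=True)
class Patch:
    """A fixed-shape 4-channel sub-volume with its grid origin."""

    data: np.ndarray                 # (4, h, w, d)
    origin: tuple[int, int, int]
    stride: int


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    """Sliding-window lattice plus a flush-to-end origin for full coverage."""
    if patch > extent:
        raise ValueError("patch larger than volume")
    last = extent - patch
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def patch_origins(shape, patch_shape, stride: int):
    axes = [_axis_origins(shape[i], patch_shape[i], stride) for i in range(3)]
    return [(a, b, c) for a in axes[0] for b in axes[1] for c in axes[2]]


def extract_patches(x: np.ndarray, patch_shape, stride: int) -> list[Patch]:
    """Tile a (4, X, Y, Z) tensor into overlapping patches.

    Origins per axis are {0, stride, 2*stride, ...} plus a final origin
    flush to the end when the extent is not covered, so the union of
    patch footprints equals the full grid.
    """
    if isinstance(patch_shape, int):
        patch_shape = (patch_shape,) * 3
    h, w, d = patch_shape
    out = []
    for (a, b, c) in patch_origins(x.shape[1:], patch_shape, stride):
        out.append(Patch(data=x[:, a:a + h, b:b + w, c:c + d].copy(),
                         origin=(a, b, c), stride=stride))
    return out


def reassemble_patches(patches: list[Patch], full_shape) -> np.ndarray:
    """Average overlapping patches back onto the full grid."""
    acc = np.zeros((patches[0].data.shape[0],) + tuple(full_shape))
    cnt = np.zeros(full_shape)
    for p in patches:
        a, b, c = p.origin
        _, h, w, d = p.data.shape
        acc[:, a:a + h, b:b + w, c:c + d] += p.data
        cnt[a:a + h, b:b + w, c:c + d] += 1
    return acc / cnt


# -------------------------------------------------------------- full pipeline
def preprocess_volume(vol: LabeledVolume, iso_mm: float | None = None,
                      bias_smoothness_mm: float = 8.0,
                      correct_bias: bool = True) -> MultiSequenceVolume:
    """Run the standard pipeline on one labeled phantom.

    normalize <- bias-correct <- strip, then optional isotropic
    resampling.  Returns a MultiSequenceVolume whose channels are
    z-scored tissue signals (background zero).
    """
    msv = MultiSequenceVolume.from_labeled(vol)
    msv = skull_strip(msv)
    for seq in SEQUENCES:
        ch = msv.channels[seq]
        if correct_bias:
            ch = correct_bias_field(ch, msv.brain_mask, bias_smoothness_mm,
                                    msv.spacing).signal
        normed, mu, sigma = zscore_normalize(ch, msv.brain_mask)
        msv.channels[seq] = normed
        msv.norm_params[seq] = (mu, sigma)
    if iso_mm is not None and tuple(msv.spacing) != (iso_mm,) * 3:
        msv = resample_isotropic(msv, iso_mm)
    return msv


def volume_to_patches(msv: MultiSequenceVolume, patch_shape, stride: int) -> list[Patch]:
    x = stack_sequences(*[msv.channels[s] for s in SEQUENCES])
    return extract_patches(x, patch_shape, stride)
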