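"""Voxel-resolution texture bank: 96 features per voxel.

The bank concatenates four operator groups evaluated per axial slice:

====================  =====  =========================================
group                 count  description
====================  =====  =========================================
first order            4     mean, SD, kurtosis, skewness over a window
co-occurrence          72    18 statistics x 4 offsets (0/45/90/135 deg)
Gabor                  12    3 wavelengths x 4 orientations (magnitude)
Kirsch                 8     8 compass edge kernels
====================  =====  =========================================

Each group reads one configured source channel, keeping the bank at exactly
96 columns.  Windows are clipped at image borders; statistics over a clipped
window use only its in-bounds pixels.  Zero-variance windows yield skewness
and kurtosis 0 (Fisher convention, defined as 0 when the variance is 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

from .config import VoxelFeatureConfig
from .glcm import GLCM_STAT_NAMES, glcm_statistics, quantize
from .imaging import ConfigurationError

#: in-plane co-occurrence offsets (drow, dcol) for 0, 45, 90, 135 degrees
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
GLCM_DIRECTION_NAMES: tuple[str, ...] = ("0", "45", "90", "135")

FIRST_ORDER_NAMES: tuple[str, ...] = ("mean", "sd", "kurtosis", "skewness")

#: the 8 Kirsch compass kernels (N, NW, W, SW, S, SE, E, NE)
_KIRSCH_BASE = np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]], dtype=float)
KIRSCH_DIRECTIONS: tuple[str, ...] = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def _kirsch_kernels() -> list[np.ndarray]:
    ring_idx = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    base_ring = [_KIRSCH_BASE[r, c] for r, c in ring_idx]
    kernels = []
    for k in range(8):
        ring = base_ring[-k:] + base_ring[:-k] if k else list(base_ring)
        kern = np.zeros((3, 3))
        for (r, c), v in zip(ring_idx, ring):
            kern[r, c] = v
        kernels.append(kern)
    return kernels


_KIRSCH_KERNELS = _kirsch_kernels()


def _box_power_sums(v: np.ndarray, window: int, max_power: int) -> tuple[np.ndarray, np.ndarray]:
    """Clipped-window sums of v**k (k=1..max_power) and window pixel counts.

    Exact integral-image box sums; windows are clipped at the image border.
    """
    h = window // 2
    H, W = v.shape
    sums = np.empty((max_power, H, W))
    padded = np.zeros((H + 1, W + 1))
    for k in range(1, max_power + 1):
        padded[1:, 1:] = np.cumsum(np.cumsum(v ** k, axis=0), axis=1)
        r0 = np.clip(np.arange(H) - h, 0, H)
        r1 = np.clip(np.arange(H) + h + 1, 0, H)
        c0 = np.clip(np.arange(W) - h, 0, W)
        c1 = np.clip(np.arange(W) + h + 1, 0, W)
        sums[k - 1] = (
            padded[np.ix_(r1, c1)] - padded[np.ix_(r0, c1)]
            - padded[np.ix_(r1, c0)] + padded[np.ix_(r0, c0)]
        )
    counts_r = (np.clip(np.arange(H) + h + 1, 0, H) - np.clip(np.arange(H) - h, 0, H))
    counts_c = (np.clip(np.arange(W) + h + 1, 0, W) - np.clip(np.arange(W) - h, 0, W))
    counts = counts_r[:, None] * counts_c[None, :]
    return sums, counts.astype(float)


def first_order_features(channel: np.ndarray, mask: np.ndarray, window: int = 5) -> np.ndarray:
    """Mean, population SD, Fisher kurtosis, skewness over the in-plane window
    centred at each in-mask voxel of one slice.  Returns (n_mask, 4).
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    v = np.asarray(channel, dtype=float)
    sums, counts = _box_power_sums(v, window, 4)
    m1 = sums[0] / counts
    m2 = sums[1] / counts - m1 ** 2
    m3 = sums[2] / counts - 3 * m1 * sums[1] / counts + 2 * m1 ** 3
    m4 = (sums[3] / counts - 4 * m1 * sums[2] / counts
          + 6 * m1 ** 2 * sums[1] / counts - 3 * m1 ** 4)
    scale = np.maximum(np.abs(v).max(), 1.0) ** 2
    m2 = np.maximum(m2, 0.0)
    ok = m2 > 1e-12 * scale
    sd = np.sqrt(m2)
    skew = np.where(ok, m3 / np.where(ok, sd ** 3, 1.0), 0.0)
    kurt = np.where(ok, m4 / np.where(ok, m2 ** 2, 1.0) - 3.0, 0.0)
    feats = np.stack([m1, sd, kurt, skew], axis=-1)
    return feats[np.asarray(mask, dtype=bool)]


def glcm_voxel_features(
    channel: np.ndarray,
    mask: np.ndarray,
    window: int = 5,
    levels: int = 32,
    offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS,
    chunk: int = 512,
) -> np.ndarray:
    """18 co-occurrence statistics per offset from the window centred at each
    in-mask voxel; the window is quantised to ``levels`` by its own min–max.
    Returns (n_mask, 18 * n_offsets).
    """
    if levels < 2:
        raise ConfigurationError("glcm_levels must be >= 2")
    v = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h = window // 2
    padded = np.pad(v, h, mode="constant", constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    wins = win[mask]                                   # (n, window, window)
    n = wins.shape[0]
    out = np.empty((n, 18 * len(offsets)))

    # per-offset in-window pair index pairs
    pair_idx = []
    for dr, dc in offsets:
        rs, cs = np.meshgrid(np.arange(window), np.arange(window), indexing="ij")
        r2, c2 = rs + dr, cs + dc
        ok = (r2 >= 0) & (r2 < window) & (c2 >= 0) & (c2 < window)
        pair_idx.append((rs[ok] * window + cs[ok], r2[ok] * window + c2[ok]))

    for start in range(0, n, chunk):
        w = wins[start:start + chunk]
        nb = w.shape[0]
        flat = w.reshape(nb, -1)
        finite = np.isfinite(flat)
        vmin = np.nanmin(flat, axis=1)[:, None]
        vmax = np.nanmax(flat, axis=1)[:, None]
        span = np.maximum(vmax - vmin, 0.0)
        with np.errstate(invalid="ignore"):
            q = np.floor((flat - vmin) / np.where(span > 0, span, 1.0) * levels)
        q = np.clip(np.nan_to_num(q, nan=0.0), 0, levels - 1).astype(np.intp)
        q[span[:, 0] == 0] = 0
        row = np.arange(nb)[:, None]
        for d, (ia_idx, ja_idx) in enumerate(pair_idx):
            ia = q[:, ia_idx]
            ja = q[:, ja_idx]
            valid = finite[:, ia_idx] & finite[:, ja_idx]
            counts = np.zeros((nb, levels * levels))
            lin = ia * levels + ja
            lin_t = ja * levels + ia
            np.add.at(counts, (np.broadcast_to(row, lin.shape)[valid], lin[valid]), 1.0)
            np.add.at(counts, (np.broadcast_to(row, lin.shape)[valid], lin_t[valid]), 1.0)
            total = counts.sum(axis=1, keepdims=True)
            empty = total[:, 0] == 0
            counts[empty, 0] = 1.0
            total[empty] = 1.0
            p = (counts / total).reshape(nb, levels, levels)
            out[start:start + nb, d * 18:(d + 1) * 18] = glcm_statistics(p)[..., :18]
    return out


def gabor_features(
    channel: np.ndarray,
    mask: np.ndarray,
    wavelengths: tuple[float, ...] = (3.0, 6.0, 12.0),
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
) -> np.ndarray:
    """Magnitude response of zero-mean 2-D Gabor filters per slice.

    Returns (n_mask, len(wavelengths) * len(orientations)).  The real part of
    each kernel has its mean subtracted so responses are invariant to a
    constant intensity offset.
    """
    v = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    cols = []
    for lam in wavelengths:
        for theta in orientations_deg:
            kern = gabor_kernel(frequency=1.0 / lam, theta=np.deg2rad(theta))
            kr = np.real(kern)
            kr = kr - kr.mean()
            ki = np.imag(kern)
            ki = ki - ki.mean()
            re = ndimage.convolve(v, kr, mode="nearest")
            im = ndimage.convolve(v, ki, mode="nearest")
            cols.append(np.hypot(re, im)[mask])
    return np.stack(cols, axis=-1)


def kirsch_features(channel: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Responses of the 8 Kirsch compass kernels per slice: (n_mask, 8)."""
    v = np.asarray(channel, dtype=float)
    cols = [ndimage.convolve(v, k, mode="nearest") for k in _KIRSCH_KERNELS]
    stacked = np.stack(cols, axis=-1)
    if mask is None:
        return stacked.reshape(-1, 8)
    return stacked[np.asarray(mask, dtype=bool)]


@dataclass
class VoxelFeatureMatrix:
    """Per-voxel feature bank restricted to a mask.

    ``values`` is (n_voxels, 96); ``voxel_index`` maps each row to its
    ``(row, col, slice)`` position.
    """

    values: np.ndarray
    feature_names: list[str]
    voxel_index: np.ndarray   # (n, 3) of (row, col, slice)

    def __post_init__(self) -> None:
        assert self.values.shape[1] == len(self.feature_names)


def feature_bank_names(config: VoxelFeatureConfig) -> list[str]:
    names = [f"fo_{s}_{config.channel_assignment['first_order']}" for s in FIRST_ORDER_NAMES]
    ch = config.channel_assignment["glcm"]
    for d in GLCM_DIRECTION_NAMES:
        names += [f"glcm_{s}_{d}_{ch}" for s in GLCM_STAT_NAMES]
    ch = config.channel_assignment["gabor"]
    for lam in config.gabor_wavelengths:
        for th in config.gabor_orientations_deg:
            names.append(f"gabor_l{lam:g}_t{th:g}_{ch}")
    ch = config.channel_assignment["kirsch"]
    names += [f"kirsch_{d}_{ch}" for d in KIRSCH_DIRECTIONS]
    return names


def build_voxel_feature_bank(
    channels: dict[str, np.ndarray],
    mask: np.ndarray,
    config: VoxelFeatureConfig | None = None,
) -> VoxelFeatureMatrix:
    """Evaluate the full 96-column bank over the in-mask voxels of a volume.

    ``channels`` maps channel names to 3-D volumes (axial slices along the
    last axis); ``mask`` is a 3-D binary volume.
    """
    config = config or VoxelFeatureConfig()
    for group, ch in config.channel_assignment.items():
        if ch not in channels:
            raise ConfigurationError(f"channel {ch!r} for group {group!r} not present")
    mask = np.asarray(mask, dtype=bool)
    names = feature_bank_names(config)
    n_cols = len(names)
    rows_per_slice = []
    index_per_slice = []
    for z in range(mask.shape[2]):
        m2 = mask[:, :, z]
        if not m2.any():
            continue
        blocks = [
            first_order_features(channels[config.channel_assignment["first_order"]][:, :, z],
                                 m2, config.window),
            glcm_voxel_features(channels[config.channel_assignment["glcm"]][:, :, z],
                                m2, config.window, config.glcm_levels),
            gabor_features(channels[config.channel_assignment["gabor"]][:, :, z], m2,
                           config.gabor_wavelengths, config.gabor_orientations_deg),
            kirsch_features(channels[config.channel_assignment["kirsch"]][:, :, z], m2),
        ]
        rows_per_slice.append(np.concatenate(blocks, axis=1))
        rr, cc = np.nonzero(m2)
        index_per_slice.append(np.stack([rr, cc, np.full(rr.shape, z)], axis=1))
    if rows_per_slice:
        values = np.concatenate(rows_per_slice, axis=0)
        index = np.concatenate(index_per_slice, axis=0)
    else:
        values = np.zeros((0, n_cols))
        index = np.zeros((0, 3), dtype=int)
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return VoxelFeatureMatrix(values=values, feature_names=names, voxel_index=index)
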