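"""Gray-level co-occurrence statistics.

A co-occurrence matrix is the joint histogram of quantised gray-level pairs
at a fixed pixel offset.  Matrices here are always *symmetric* (each pair is
counted in both orders) and normalised to sum to 1.  The same statistics
engine serves two consumers:

* the voxel-resolution texture bank — 18 statistics per offset over a small
  window centred on each voxel, quantised window-by-window;
* the region-resolution physiology block — 19 statistics (the 18 plus a
  normalised entropy) from one horizontal-offset matrix built globally over a
  candidate region, counting only pairs with both pixels inside the region.

Degenerate inputs (a single gray level, hence a delta co-occurrence matrix)
yield the documented finite fallbacks: energy 1, contrast 0, entropy 0,
correlation 0.

Conventions: gray levels are indexed 1..L in the statistics, logarithms are
base 2, and the variance-style statistics use the marginal mean of the
symmetric matrix.
"""

from __future__ import annotations

import numpy as np

#: the 18 second-order statistics of the voxel-resolution bank, in column order
GLCM_STAT_NAMES: tuple[str, ...] = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "idmn",
    "sum_average",
    "sum_variance",
    "entropy",
    "sum_entropy",
    "difference_entropy",
    "imc1",
    "homogeneity",
    "autocorrelation",
    "difference_variance",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "max_probability",
)

#: the region-resolution physiology block adds a normalised entropy
REGION_GLCM_STAT_NAMES: tuple[str, ...] = GLCM_STAT_NAMES + ("normalized_entropy",)


def quantize(values: np.ndarray, levels: int, vmin: float | None = None,
             vmax: float | None = None) -> np.ndarray:
    """Min–max quantise ``values`` into integer levels ``0..levels-1``.

    A constant input maps to level 0 everywhere.
    """
    values = np.asarray(values, dtype=float)
    if vmin is None:
        vmin = np.nanmin(values)
    if vmax is None:
        vmax = np.nanmax(values)
    if vmax <= vmin:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_from_pairs(ia: np.ndarray, ja: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix from pair index arrays."""
    ia = np.asarray(ia, dtype=np.intp).ravel()
    ja = np.asarray(ja, dtype=np.intp).ravel()
    if ia.size == 0:
        p = np.zeros((levels, levels), dtype=float)
        p[0, 0] = 1.0
        return p
    counts = np.bincount(ia * levels + ja, minlength=levels * levels).astype(float)
    counts += np.bincount(ja * levels + ia, minlength=levels * levels)
    p = counts.reshape(levels, levels)
    return p / p.sum()


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_statistics(p: np.ndarray) -> np.ndarray:
    """All region-level statistics (:data:`REGION_GLCM_STAT_NAMES` order) of a
    batch of symmetric normalised co-occurrence matrices.

    ``p`` has shape ``(..., L, L)``; the result has shape ``(..., 19)``.  The
    first 18 entries are the voxel-bank statistics in
    :data:`GLCM_STAT_NAMES` order.
    """
    p = np.asarray(p, dtype=float)
    L = p.shape[-1]
    i = np.arange(1, L + 1, dtype=float)
    ii = i[:, None] * np.ones((1, L))
    jj = ii.T

    px = p.sum(axis=-1)                      # marginal, shape (..., L)
    mu = (px * i).sum(axis=-1)               # marginal mean (symmetric: mu_x == mu_y)
    var = (px * (i - mu[..., None]) ** 2).sum(axis=-1)

    energy = (p ** 2).sum(axis=(-2, -1))
    contrast = (p * (ii - jj) ** 2).sum(axis=(-2, -1))
    autocorr = (p * ii * jj).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(var > 1e-15, (autocorr - mu ** 2) / np.where(var > 1e-15, var, 1.0), 0.0)
    idmn = (p / (1.0 + (ii - jj) ** 2 / L ** 2)).sum(axis=(-2, -1))
    homogeneity = (p / (1.0 + np.abs(ii - jj))).sum(axis=(-2, -1))
    dissimilarity = (p * np.abs(ii - jj)).sum(axis=(-2, -1))

    # sum (i+j) and absolute-difference |i-j| marginal distributions
    ipj = (np.arange(L)[:, None] + np.arange(L)[None, :]).ravel()   # 0 .. 2L-2
    imj = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).ravel()
    flat = p.reshape(p.shape[:-2] + (L * L,))
    p_sum = np.zeros(p.shape[:-2] + (2 * L - 1,))
    p_diff = np.zeros(p.shape[:-2] + (L,))
    np.add.at(p_sum, (..., ipj), flat)
    np.add.at(p_diff, (..., imj), flat)

    ks = np.arange(2, 2 * L + 1, dtype=float)       # i+j with 1-based levels
    kd = np.arange(0, L, dtype=float)
    sum_average = (p_sum * ks).sum(axis=-1)
    sum_variance = (p_sum * (ks - sum_average[..., None]) ** 2).sum(axis=-1)
    entropy = -_xlog2x(p).sum(axis=(-2, -1))
    sum_entropy = -_xlog2x(p_sum).sum(axis=-1)
    diff_entropy = -_xlog2x(p_diff).sum(axis=-1)
    mu_d = (p_diff * kd).sum(axis=-1)
    diff_variance = (p_diff * (kd - mu_d[..., None]) ** 2).sum(axis=-1)

    # information measure of correlation (form 1)
    hx = -_xlog2x(px).sum(axis=-1)
    pxy = px[..., :, None] * px[..., None, :]
    hxy1 = np.zeros_like(entropy)
    nz = (p > 0) & (pxy > 0)
    hxy1 = -(np.where(nz, p * np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        imc1 = np.where(hx > 1e-15, (entropy - hxy1) / np.where(hx > 1e-15, hx, 1.0), 0.0)

    shade = (p * (ii + jj - 2 * mu[..., None, None]) ** 3).sum(axis=(-2, -1))
    prominence = (p * (ii + jj - 2 * mu[..., None, None]) ** 4).sum(axis=(-2, -1))
    max_prob = p.max(axis=(-2, -1))
    norm_entropy = entropy / np.log2(float(L * L))

    return np.stack(
        [
            energy, contrast, corr, var, idmn, sum_average, sum_variance,
            entropy, sum_entropy, diff_entropy, imc1, homogeneity, autocorr,
            diff_variance, dissimilarity, shade, prominence, max_prob,
            norm_entropy,
        ],
        axis=-1,
    )
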