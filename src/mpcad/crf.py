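"""Relative-ADC-driven conditional random field refinement.

Detections from the region stage are refined at voxel resolution by
minimising a binary-label energy

    E(Y, X) = sum_i psi_u(y_i, X) + sum_{(i,j) in C} w * phi_ij * |y_i - y_j|

where the unary costs come from the region classifier's probabilities
(``psi_u(1) = -log p``, ``psi_u(0) = -log(1 - p)``), the cliques C are the
in-plane 4-neighbour pairs, and the contrast term
``phi_ij = exp(-||f_i - f_j||^2 / (2 sigma^2))`` is computed on voxel texture
features extracted from the relative-ADC channel: smoothing is strong where
the relative-ADC texture is locally uniform and suspended across feature
edges.

The binary problem is relaxed to labels in [0, 1] with the pairwise absolute
difference smoothed as ``sqrt((y_i - y_j)^2 + eps)``; the relaxation is
convex, so projected gradient descent (with step halving whenever the energy
would rise) reaches the global relaxed minimum.  The binary field is then
recovered by scanning the level sets of the relaxed minimiser and keeping the
threshold with the lowest binary energy, which preserves the exactness of the
total-variation rounding argument; the default scan includes 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CrfConfig, VoxelFeatureConfig
from .imaging import StructuralError
from .rd_std import pca_compact
from .regions import CandidateRegion
from .voxel_features import build_voxel_feature_bank

_COST_CLAMP = 1e6
_SMOOTH_EPS = 1e-4


@dataclass
class CRFProblem:
    """One per-slice labelling problem.

    ``unary`` is (H, W, 2) with costs for labels (0, 1); ``features`` is
    (H, W, u) from the relative-ADC texture bank; ``valid`` restricts the
    field (e.g. to the gland).
    """

    unary: np.ndarray
    features: np.ndarray
    pairwise_weight: float = 1.0
    sigma: float | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.unary.shape[:2] != self.features.shape[:2]:
            raise StructuralError("unary and feature fields must share a shape")
        if self.pairwise_weight < 0:
            raise StructuralError("pairwise weight must be >= 0")

    def edge_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Contrast-weighted clique strengths for vertical and horizontal
        4-neighbour pairs: ``w * exp(-||df||^2 / (2 sigma^2))``."""
        f = self.features
        dv = ((f[1:, :, :] - f[:-1, :, :]) ** 2).sum(axis=-1)
        dh = ((f[:, 1:, :] - f[:, :-1, :]) ** 2).sum(axis=-1)
        sigma = self.sigma
        if sigma is None:
            d_all = np.concatenate([np.sqrt(dv).ravel(), np.sqrt(dh).ravel()])
            pos = d_all[d_all > 0]
            sigma = float(np.median(pos)) if pos.size else 1.0
        sigma = max(sigma, 1e-12)
        wv = self.pairwise_weight * np.exp(-dv / (2 * sigma ** 2))
        wh = self.pairwise_weight * np.exp(-dh / (2 * sigma ** 2))
        if self.valid is not None:
            v = self.valid.astype(bool)
            wv = wv * (v[1:, :] & v[:-1, :])
            wh = wh * (v[:, 1:] & v[:, :-1])
        return wv, wh


def build_unary(regions: list[CandidateRegion], labels: np.ndarray, scores: np.ndarray,
                shape: tuple[int, int], slice_index: int,
                p_background: float = 0.01) -> np.ndarray:
    """Unary cost field for one slice from classified regions.

    Scores are squashed to probabilities with the logistic function; voxels
    outside every candidate region get ``p = p_background``.  Costs are
    ``-log p`` / ``-log(1-p)`` clamped at 1e6.
    """
    p = np.full(shape, p_background, dtype=float)
    for r, _lab, s in zip(regions, labels, scores):
        if r.slice_index != slice_index:
            continue
        p[r.mask] = 1.0 / (1.0 + np.exp(-float(s)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    unary = np.stack([-np.log(1.0 - p), -np.log(p)], axis=-1)
    return np.clip(unary, 0.0, _COST_CLAMP)


def crf_energy(problem: CRFProblem, Y: np.ndarray) -> float:
    """Energy of a (possibly relaxed) label field: linear interpolation of
    the unary costs plus the contrast-weighted absolute label differences."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape != problem.unary.shape[:2]:
        raise StructuralError("label field shape mismatch")
    u0 = problem.unary[..., 0]
    u1 = problem.unary[..., 1]
    if problem.valid is not None:
        v = problem.valid.astype(bool)
        unary_term = float(np.sum(((1 - Y) * u0 + Y * u1)[v]))
    else:
        unary_term = float(np.sum((1 - Y) * u0 + Y * u1))
    wv, wh = problem.edge_weights()
    pair = float(np.sum(wv * np.abs(Y[1:, :] - Y[:-1, :]))
                 + np.sum(wh * np.abs(Y[:, 1:] - Y[:, :-1])))
    return unary_term + pair


def _smoothed_energy_and_grad(Y, u0, u1, wv, wh):
    dv = Y[1:, :] - Y[:-1, :]
    dh = Y[:, 1:] - Y[:, :-1]
    sv = np.sqrt(dv ** 2 + _SMOOTH_EPS)
    sh = np.sqrt(dh ** 2 + _SMOOTH_EPS)
    energy = np.sum((1 - Y) * u0 + Y * u1) + np.sum(wv * sv) + np.sum(wh * sh)
    grad = u1 - u0
    gv = wv * dv / sv
    gh = wh * dh / sh
    grad[1:, :] += gv
    grad[:-1, :] -= gv
    grad[:, 1:] += gh
    grad[:, :-1] -= gh
    return float(energy), grad


def refine_labels(problem: CRFProblem, step: float = 0.05, max_iter: int = 2000,
                  tol: float = 1e-8, y_init: np.ndarray | None = None,
                  return_trace: bool = False):
    """Minimise the relaxed CRF energy by projected gradient descent and
    round to a binary field.

    The recorded energy trace is non-increasing (the step is halved whenever
    a step would raise the energy).  Rounding scans the level sets of the
    relaxed minimiser (plus 0.5) and keeps the binary field with the lowest
    exact energy.
    """
    if step <= 0:
        raise StructuralError("step must be > 0")
    u0 = problem.unary[..., 0].astype(float)
    u1 = problem.unary[..., 1].astype(float)
    if problem.valid is not None:
        v = problem.valid.astype(bool)
        u0 = np.where(v, u0, 0.0)
        u1 = np.where(v, u1, _COST_CLAMP)
    wv, wh = problem.edge_weights()
    Y = (np.asarray(y_init, dtype=float).copy() if y_init is not None
         else (u1 < u0).astype(float))
    energy, grad = _smoothed_energy_and_grad(Y, u0, u1, wv, wh)
    trace = [energy]
    converged = False
    for _ in range(max_iter):
        while True:
            Y_new = np.clip(Y - step * grad, 0.0, 1.0)
            e_new, g_new = _smoothed_energy_and_grad(Y_new, u0, u1, wv, wh)
            if e_new <= energy:
                break
            if step < 1e-12:
                # no descent direction left at machine precision
                Y_new, e_new, g_new = Y, energy, grad
                break
            step *= 0.5
        delta = np.max(np.abs(Y_new - Y))
        Y, energy, grad = Y_new, e_new, g_new
        trace.append(energy)
        step = min(step * 1.2, 1.0)   # recover from transient halving
        if delta < tol:
            converged = True
            break

    # level-set rounding: best exact binary energy over candidate thresholds
    levels = np.unique(np.concatenate([[0.5], np.unique(np.round(Y, 9))]))
    best_mask, best_e = None, np.inf
    for t in levels:
        cand = (Y > t).astype(float)
        e = crf_energy(problem, cand)
        if e < best_e - 1e-15:
            best_e, best_mask = e, cand
    result = best_mask.astype(bool)
    if problem.valid is not None:
        result &= problem.valid.astype(bool)
    if return_trace:
        return result, np.array(trace), converged
    return result


def voxel_features_on_radc(radc: np.ndarray, mask: np.ndarray,
                           config: VoxelFeatureConfig | None = None,
                           variance_fraction: float = 0.90) -> np.ndarray:
    """Per-voxel pairwise feature field from the relative-ADC channel.

    The full 96-column texture bank with every operator group assigned to the
    relative-ADC channel, PCA-compacted to the components explaining
    ``variance_fraction`` of the variance.  Returns a dense (H, W, Z, u)
    field (zeros outside the mask).
    """
    base = config or VoxelFeatureConfig()
    cfg = VoxelFeatureConfig(
        window=base.window, glcm_levels=base.glcm_levels,
        gabor_wavelengths=base.gabor_wavelengths,
        gabor_orientations_deg=base.gabor_orientations_deg,
        channel_assignment={g: "rADC" for g in base.channel_assignment},
    )
    bank = build_voxel_feature_bank({"rADC": radc}, mask, cfg)
    if bank.values.shape[0] == 0:
        return np.zeros(radc.shape + (1,))
    keep = bank.values.std(axis=0) > 0
    if keep.sum() == 0:
        return np.zeros(radc.shape + (1,))
    compact = pca_compact(bank.values[:, keep], variance_fraction)
    field = np.zeros(radc.shape + (compact.u,))
    idx = bank.voxel_index
    field[idx[:, 0], idx[:, 1], idx[:, 2]] = compact.values
    return field
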