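"""Derived MP-MRI channels from a diffusion-weighted acquisition.

Four channels are computed from the acquired b-value stack:

* **ADC** — per-voxel diffusivity ``D`` from the mono-exponential decay
  ``S = S0 * exp(-b * D)``, fitted by ordinary least squares on ``ln S`` vs
  ``b`` (the slope is ``-D``).
* **CHB-DWI** — a computed high-b image, extrapolating the fitted decay to a
  target b-value beyond the acquired range (default 2000 s/mm^2).
* **CDI** — correlated diffusion image: the cross-b-value signal product mixed
  over a local subvolume with a normalised isotropic Gaussian kernel.
* **relative ADC** — the ADC map normalised per candidate ROI by the median
  ADC of its dilated surround, then globally by the mean of those medians,
  correcting inter-patient ADC variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .config import SIGNAL_FLOOR


class StructuralError(ValueError):
    """Inconsistent shapes / malformed inputs."""


class ConfigurationError(ValueError):
    """Invalid parameter combination."""


@dataclass
class BValueStack:
    """An ordered DWI acquisition: one 3-D volume per b-value."""

    volumes: list[np.ndarray]
    bvalues: list[float]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.bvalues):
            raise StructuralError("one volume required per b-value")
        if len(self.bvalues) < 2:
            raise ConfigurationError("at least two b-values are required")
        b = np.asarray(self.bvalues, dtype=float)
        if np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise ConfigurationError("b-values must be non-negative and strictly increasing")
        shape = self.volumes[0].shape
        for v in self.volumes:
            if v.shape != shape:
                raise StructuralError("all DWI volumes must share one shape")
        self.volumes = [np.asarray(v, dtype=float) for v in self.volumes]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape

    def stacked(self) -> np.ndarray:
        """Signals as an array of shape (n_b, *vol_shape)."""
        return np.stack(self.volumes, axis=0)


@dataclass
class DerivedChannelSet:
    adc: np.ndarray
    chb_dwi: np.ndarray
    cdi: np.ndarray
    relative_adc: np.ndarray | None = None
    target_b: float = 2000.0
    invalid_mask: np.ndarray | None = None


@dataclass
class CandidateMaskSet:
    """Binary candidate ROI masks; 2-D masks carry their axial slice index."""

    masks: list[np.ndarray]
    slice_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.masks:
            if not np.any(m):
                raise StructuralError("candidate masks must be non-empty")


def _loglinear_fit(stack: BValueStack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of ln S on b per voxel.

    Returns ``(ln_s0, D, invalid)`` where ``invalid`` flags voxels whose
    signal sits at/below the floor at every b-value; those get ``D = 0``.
    """
    b = np.asarray(stack.bvalues, dtype=float)
    signals = stack.stacked()
    invalid = np.all(signals <= SIGNAL_FLOOR, axis=0)
    logs = np.log(np.clip(signals, SIGNAL_FLOOR, None))
    # closed-form simple linear regression, vectorised over voxels
    bbar = b.mean()
    denom = np.sum((b - bbar) ** 2)
    ybar = logs.mean(axis=0)
    slope = np.tensordot(b - bbar, logs - ybar, axes=(0, 0)) / denom
    intercept = ybar - slope * bbar
    d = -slope
    d[invalid] = 0.0
    intercept[invalid] = np.log(SIGNAL_FLOOR)
    return intercept, d, invalid


def fit_adc(stack: BValueStack) -> np.ndarray:
    """Per-voxel apparent diffusion coefficient (same units as 1/b).

    Exact on noiseless mono-exponential input; voxels with no signal at any
    b-value are set to 0.
    """
    _, d, _ = _loglinear_fit(stack)
    return d


def compute_chb_dwi(stack: BValueStack, target_b: float = 2000.0, ridge: float = 0.0) -> np.ndarray:
    """Computed high-b DWI: extrapolate the fitted decay to ``target_b``.

    ``ridge`` shrinks the fitted slope towards zero (a Gaussian prior on D);
    the default 0 is the plain least-squares extrapolation.
    """
    if target_b <= max(stack.bvalues):
        raise ConfigurationError("target_b must exceed the largest acquired b-value")
    ln_s0, d, invalid = _loglinear_fit(stack)
    if ridge > 0:
        b = np.asarray(stack.bvalues, dtype=float)
        shrink = np.sum((b - b.mean()) ** 2)
        d = d * (shrink / (shrink + ridge))
    out = np.exp(ln_s0 - target_b * d)
    out[invalid] = 0.0
    return out


def compute_cdi(stack: BValueStack, kernel_radius_mm: float = 2.0) -> np.ndarray:
    """Correlated diffusion image.

    The per-voxel product of the signals across all b-values, mixed over a
    local subvolume by a normalised isotropic Gaussian kernel of physical
    width ``kernel_radius_mm``.  Radius 0 degenerates to the plain product.
    """
    if kernel_radius_mm < 0:
        raise ConfigurationError("kernel_radius_mm must be >= 0")
    prod = np.prod(stack.stacked(), axis=0)
    if kernel_radius_mm == 0:
        return prod
    sigma_vox = [kernel_radius_mm / s for s in stack.voxel_spacing]
    return ndimage.gaussian_filter(prod, sigma=sigma_vox, mode="nearest")


def _dilate_slice(mask2d: np.ndarray, se_radius_vox: int) -> np.ndarray:
    return ndimage.binary_dilation(mask2d, structure=disk(se_radius_vox))


def compute_relative_adc(
    adc: np.ndarray,
    candidates: CandidateMaskSet,
    se_radius_vox: int = 3,
    gland_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Relative ADC map from candidate ROIs.

    Each ROI is dilated in-plane with a disk structuring element; the median
    ADC over the dilated band (surround) normalises the dilated ROI.  The
    normalised dilated ROIs are combined (overlaps resolved by the ROI with
    the nearest centroid) and the remainder of the map is divided by the mean
    of the surround medians.  With no candidates the map is normalised by the
    median ADC over ``gland_mask`` (or the whole volume).
    """
    if se_radius_vox < 1:
        raise ConfigurationError("se_radius_vox must be >= 1")
    adc = np.asarray(adc, dtype=float)
    out = np.array(adc, dtype=float)

    rois: list[tuple[np.ndarray, int, tuple[float, float]]] = []
    for k, mask in enumerate(candidates.masks):
        mask = np.asarray(mask).astype(bool)
        if mask.ndim == 2:
            z = candidates.slice_indices[k]
            sl_masks = [(z, mask)]
        else:
            sl_masks = [(z, mask[:, :, z]) for z in range(mask.shape[2]) if mask[:, :, z].any()]
        for z, m2 in sl_masks:
            rr, cc = np.nonzero(m2)
            rois.append((m2, z, (rr.mean(), cc.mean())))

    if not rois:
        ref = adc[gland_mask.astype(bool)] if gland_mask is not None else adc
        med = float(np.median(ref[ref > 0])) if np.any(ref > 0) else 0.0
        if med == 0:
            warnings.warn("degenerate reference region; relative ADC left unscaled")
            return out
        return out / med

    medians: list[float] = []
    patches: list[tuple[int, np.ndarray, np.ndarray]] = []  # (slice, dilated, normalised values)
    centroids: list[tuple[float, float]] = []
    for m2, z, centroid in rois:
        dil = _dilate_slice(m2, se_radius_vox)
        surround = dil & ~m2
        if not surround.any():
            warnings.warn("ROI surround empty after clipping; using clipped band")
            surround = dil
        med = float(np.median(adc[:, :, z][surround]))
        if med == 0:
            warnings.warn("degenerate surround (median 0); ROI skipped")
            continue
        medians.append(med)
        patches.append((z, dil, adc[:, :, z] / med))
        centroids.append(centroid)

    if not medians:
        warnings.warn("all candidate ROIs degenerate; relative ADC from reference median")
        ref = adc[gland_mask.astype(bool)] if gland_mask is not None else adc
        med = float(np.median(ref[ref > 0])) if np.any(ref > 0) else 1.0
        return adc / med

    global_med = float(np.mean(medians))
    out = adc / global_med
    # per-slice ownership by nearest ROI centroid where dilated ROIs overlap
    rows = np.arange(adc.shape[0])[:, None]
    cols = np.arange(adc.shape[1])[None, :]
    for z in sorted({z for z, _, _ in patches}):
        zpatches = [(dil, vals, c) for (pz, dil, vals), c in zip(patches, centroids) if pz == z]
        any_dil = np.zeros(adc.shape[:2], dtype=bool)
        best_dist = np.full(adc.shape[:2], np.inf)
        chosen = np.zeros(adc.shape[:2], dtype=float)
        for dil, vals, (cr, cc) in zpatches:
            dist = (rows - cr) ** 2 + (cols - cc) ** 2
            take = dil & (dist < best_dist)
            chosen[take] = vals[take]
            best_dist[take] = dist[take]
            any_dil |= dil
        out[:, :, z][any_dil] = chosen[any_dil]
    return out


def derive_channels(
    stack: BValueStack,
    target_b: float = 2000.0,
    cdi_kernel_radius_mm: float = 2.0,
    ridge: float = 0.0,
    candidates: CandidateMaskSet | None = None,
    se_radius_vox: int = 3,
    gland_mask: np.ndarray | None = None,
) -> DerivedChannelSet:
    """All derived channels from one acquisition."""
    ln_s0, d, invalid = _loglinear_fit(stack)
    adc = d.copy()
    chb = compute_chb_dwi(stack, target_b=target_b, ridge=ridge)
    cdi = compute_cdi(stack, kernel_radius_mm=cdi_kernel_radius_mm)
    radc = None
    if candidates is not None:
        radc = compute_relative_adc(adc, candidates, se_radius_vox=se_radius_vox,
                                    gland_mask=gland_mask)
    return DerivedChannelSet(adc=adc, chb_dwi=chb, cdi=cdi, relative_adc=radc,
                             target_b=target_b, invalid_mask=invalid)
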