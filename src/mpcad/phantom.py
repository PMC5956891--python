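"""Synthetic MP-MRI phantom cases.

Each case emulates the structure of a co-registered prostate MP-MRI exam:
nine channels (T2w, ADC, relative ADC, CHB-DWI, CDI and the four acquired
b-value images at b = 0, 100, 400, 1000 s/mm^2), a gland mask, and a ground
truth tumour mask.  DWI signals follow the mono-exponential decay
``S = S0 * exp(-b * D)`` with a tissue-dependent diffusivity map; tumours are
low-ADC / T2w-hypointense ellipsoidal blobs inside the gland; magnitude noise
is Rician.  Benign *mimics* — ADC-dark but T2w-normal nodules excluded from
the truth mask — emulate the false-positive candidates that the voxel stage
of a detector produces on clinical data and the region stage must prune.

Geometry is axis-aligned ellipsoids with a 2-voxel Gaussian boundary blend,
so the ground truth stays analytic.  No zonal anatomy and no scanner
artefacts (bias field, distortion) are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import DerivedChannelConfig
from .imaging import BValueStack, CandidateMaskSet, compute_relative_adc, derive_channels

#: canonical channel order I1..I9 of the region feature model
CHANNEL_ORDER: tuple[str, ...] = (
    "T2w", "ADC", "rADC", "CHB-DWI", "CDI", "b0", "b100", "b400", "b1000",
)

DEFAULT_BVALUES: tuple[float, ...] = (0.0, 100.0, 400.0, 1000.0)


class PhantomSpecError(ValueError):
    pass


@dataclass
class Lesion:
    """One ellipsoidal blob: centre (voxels), per-axis radii (voxels),
    diffusivity (mm^2/s) and multiplicative T2w contrast (<1 = hypointense)."""

    center: tuple[float, float, float]
    radius_vox: tuple[float, float, float]
    d_lesion: float = 0.7e-3
    t2w_contrast: float = 0.6


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (40, 40, 8)
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    gland_center: tuple[float, float, float] | None = None
    gland_radius_vox: tuple[float, float, float] = (13.0, 10.0, 3.0)
    tumours: list[Lesion] = field(default_factory=list)
    mimics: list[Lesion] = field(default_factory=list)
    d_background: float = 1.6e-3      # mm^2/s, peripheral-zone-like tissue
    d_outside: float = 2.4e-3         # mm^2/s, fluid-like surroundings
    s0_base: float = 800.0
    s0_variation: float = 0.10        # low-frequency multiplicative S0 texture
    t2w_base: float = 600.0
    noise_sigma: float = 15.0
    seed: int = 0
    patient_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")
        for blob in self.tumours:
            if blob.d_lesion >= self.d_background:
                raise PhantomSpecError("lesions must be ADC-dark (D_lesion < D_background)")
            if min(blob.radius_vox) < 1.5:
                raise PhantomSpecError("lesion radii must be >= 1.5 voxels")


@dataclass
class PatientCase:
    """Nine co-registered channel volumes plus gland and truth masks."""

    channels: dict[str, np.ndarray]
    gland_mask: np.ndarray
    truth_mask: np.ndarray
    patient_id: str
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    bvalues: tuple[float, ...] = DEFAULT_BVALUES

    def __post_init__(self) -> None:
        missing = set(CHANNEL_ORDER) - set(self.channels)
        if missing:
            raise PhantomSpecError(f"missing channels: {sorted(missing)}")
        if np.any(self.truth_mask & ~self.gland_mask.astype(bool)):
            raise PhantomSpecError("truth mask must lie inside the gland mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gland_mask.shape


def add_rician_noise(volume: np.ndarray, sigma: float, seed: int | np.random.Generator) -> np.ndarray:
    """Rician magnitude noise: ``sqrt((v + n1)^2 + n2^2)`` with
    ``n1, n2 ~ N(0, sigma^2)``.  ``sigma = 0`` returns the input unchanged."""
    if sigma < 0:
        raise PhantomSpecError("sigma must be >= 0")
    v = np.asarray(volume, dtype=float)
    if sigma == 0:
        return v.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=v.shape)
    n2 = rng.normal(0.0, sigma, size=v.shape)
    return np.sqrt((v + n1) ** 2 + n2 ** 2)


def _ellipsoid_field(shape, center, radius) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radius))
    return q


def _soft_blob(shape, center, radius, blend_sigma=2.0) -> np.ndarray:
    """Membership in [0, 1] of an ellipsoid with a smooth boundary."""
    hard = (_ellipsoid_field(shape, center, radius) <= 1.0).astype(float)
    if blend_sigma > 0:
        soft = ndimage.gaussian_filter(hard, sigma=(blend_sigma, blend_sigma, 0.0))
        # keep the core at full membership
        return np.maximum(soft, (_ellipsoid_field(shape, center, [max(r - 1, 1) for r in radius]) <= 1.0).astype(float))
    return hard


def generate_phantom(spec: PhantomSpec, derived: DerivedChannelConfig | None = None) -> PatientCase:
    """Deterministic synthetic patient case for a given spec and seed."""
    derived = derived or DerivedChannelConfig()
    shape = tuple(spec.shape)
    center = spec.gland_center or tuple((s - 1) / 2.0 for s in shape)
    rng = np.random.default_rng(spec.seed)

    gland_q = _ellipsoid_field(shape, center, spec.gland_radius_vox)
    gland = gland_q <= 1.0

    d_map = np.full(shape, spec.d_outside)
    d_map[gland] = spec.d_background
    t2w = np.full(shape, 0.5 * spec.t2w_base)
    t2w[gland] = spec.t2w_base

    truth = np.zeros(shape, dtype=bool)
    for blob, is_tumour in [(b, True) for b in spec.tumours] + [(b, False) for b in spec.mimics]:
        hard = _ellipsoid_field(shape, blob.center, blob.radius_vox) <= 1.0
        if is_tumour and not np.all(gland[hard]):
            raise PhantomSpecError("tumour extends outside the gland")
        w = _soft_blob(shape, blob.center, blob.radius_vox)
        d_map = d_map * (1 - w) + blob.d_lesion * w
        t2w = t2w * (1 - w) + (spec.t2w_base * blob.t2w_contrast) * w
        if is_tumour:
            truth |= hard

    # smooth multiplicative S0 texture (deterministic per seed)
    s0 = np.full(shape, spec.s0_base)
    if spec.s0_variation > 0:
        field_ = ndimage.gaussian_filter(rng.normal(size=shape), sigma=(4, 4, 1))
        field_ /= max(np.abs(field_).max(), 1e-12)
        s0 = s0 * (1.0 + spec.s0_variation * field_)

    channels: dict[str, np.ndarray] = {}
    b_names = ("b0", "b100", "b400", "b1000")
    volumes = []
    for b, name in zip(DEFAULT_BVALUES, b_names):
        clean = s0 * np.exp(-b * d_map)
        channels[name] = add_rician_noise(clean, spec.noise_sigma, rng)
        volumes.append(channels[name])
    channels["T2w"] = add_rician_noise(t2w, spec.noise_sigma, rng)

    stack = BValueStack(volumes=volumes, bvalues=list(DEFAULT_BVALUES),
                        voxel_spacing=spec.voxel_spacing)
    truth_candidates = None
    if truth.any():
        truth_candidates = CandidateMaskSet(masks=[truth])
    derived_set = derive_channels(
        stack,
        target_b=derived.target_b,
        cdi_kernel_radius_mm=derived.cdi_kernel_radius_mm,
        ridge=derived.ridge,
        candidates=truth_candidates,
        se_radius_vox=derived.se_radius_vox,
        gland_mask=gland,
    )
    channels["ADC"] = derived_set.adc
    channels["CHB-DWI"] = derived_set.chb_dwi
    channels["CDI"] = derived_set.cdi
    if derived_set.relative_adc is not None:
        channels["rADC"] = derived_set.relative_adc
    else:
        channels["rADC"] = compute_relative_adc(
            derived_set.adc, CandidateMaskSet(masks=[], slice_indices=[]),
            se_radius_vox=derived.se_radius_vox, gland_mask=gland)

    return PatientCase(channels=channels, gland_mask=gland, truth_mask=truth,
                       patient_id=spec.patient_id, voxel_spacing=spec.voxel_spacing)


def default_study_specs(n_patients: int = 10, seed: int = 0) -> list[PhantomSpec]:
    """The reference phantom cohort: ``n_patients`` cases, half with one
    tumour, all with two benign mimics.

    Tissue values: D_background 1.6e-3, D_lesion 0.7e-3, mimic D 0.85e-3
    mm^2/s; per-patient background diffusivity jitter (+-8%) emulates the
    inter-patient ADC variation that the relative-ADC channel corrects.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_patients):
        with_tumour = i % 2 == 0
        jitter = 1.0 + 0.08 * rng.uniform(-1, 1)
        cx, cy, cz = 19.5, 19.5, 3.5
        tumours = []
        if with_tumour:
            tumours.append(Lesion(
                center=(cx + rng.uniform(-4, 4), cy + rng.uniform(-3, 3), cz + rng.uniform(-0.5, 0.5)),
                radius_vox=(3.5, 3.2, 1.6),
                d_lesion=0.7e-3,
                t2w_contrast=0.55,
            ))
        mimics = []
        attempts = 0
        while len(mimics) < 2 and attempts < 500:
            attempts += 1
            c = (cx + rng.uniform(-8, 8), cy + rng.uniform(-6, 6), cz + rng.uniform(-1, 1))
            # keep mimic cores clear of the tumour and of each other in-plane
            others = [t.center for t in tumours] + [m.center for m in mimics]
            if any(np.hypot(c[0] - o[0], c[1] - o[1]) < 6.5 for o in others):
                continue
            mimics.append(Lesion(center=c, radius_vox=(2.8, 2.6, 1.4),
                                 d_lesion=0.85e-3, t2w_contrast=1.05))
        specs.append(PhantomSpec(
            tumours=tumours,
            mimics=mimics,
            d_background=1.6e-3 * jitter,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            patient_id=f"P{i:02d}",
        ))
    return specs
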