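"""Pipeline configuration.

One document holds every tunable constant of the three detection stages plus
the derived-channel and phantom defaults, so a study is reproducible from the
config file and a seed alone.  Blocks mirror the stage modules:
``voxel_features``, ``rd_std``, ``rd_fm``, ``crf``, ``evaluation``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: floor applied to DWI signals before taking logarithms
SIGNAL_FLOOR = 1e-6


@dataclass
class DerivedChannelConfig:
    """Derived MP-MRI channel computation."""

    target_b: float = 2000.0          # s/mm^2, CHB-DWI extrapolation target
    cdi_kernel_radius_mm: float = 2.0  # Gaussian mixing radius for CDI
    ridge: float = 0.0                 # optional ridge prior on the log-linear fit
    se_radius_vox: int = 3             # disk SE for relative-ADC dilation (per slice)


@dataclass
class VoxelFeatureConfig:
    """Voxel-resolution texture bank (96 features)."""

    window: int = 5
    glcm_levels: int = 32
    gabor_wavelengths: tuple[float, ...] = (3.0, 6.0, 12.0)
    gabor_orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    # operator group -> source channel; keeps the bank at exactly 96 columns
    channel_assignment: dict[str, str] = field(
        default_factory=lambda: {
            "first_order": "ADC",
            "glcm": "ADC",
            "gabor": "T2w",
            "kirsch": "CHB-DWI",
        }
    )


@dataclass
class StdConfig:
    """Statistical textural distinctiveness stage."""

    variance_fraction: float = 0.90
    n_atoms: int = 8
    # 'i' evaluates the saliency sum with the occurrence probability of the
    # atom being scored (the printed form); 'j' uses the probability of the
    # atom it is compared against, which makes rare, distinct textures salient.
    saliency_prob_index: str = "j"
    min_area_vox: int = 6


@dataclass
class FmConfig:
    """Region-resolution feature model stage."""

    se_radius_vox: int = 2
    boundary_points: int = 128
    keep_freq: int = 8
    low_freq: int = 2
    high_freq: int = 16
    asymmetry_cap: float = 10.0
    glcm_levels: int = 32
    mrmr_bins: int = 10
    criterion: str = "specificity"     # sensitivity | specificity | auc
    overlap_frac: float = 0.5          # region positive iff overlap/area >= this
    svm_c: float = 1.0
    svm_gamma: str | float = "auto"    # 'auto' = 1/n_features
    inner_folds: int = 3


@dataclass
class CrfConfig:
    """Relative-ADC conditional random field stage."""

    pairwise_weight: float = 1.0
    sigma: float | None = None         # None -> median pairwise feature distance
    p_background: float = 0.01
    step: float = 0.05
    max_iter: int = 1000
    tol: float = 1e-7


@dataclass
class EvalConfig:
    overlap_frac: float = 0.5
    patient_k_regions: int = 1


@dataclass
class PipelineConfig:
    derived: DerivedChannelConfig = field(default_factory=DerivedChannelConfig)
    voxel_features: VoxelFeatureConfig = field(default_factory=VoxelFeatureConfig)
    rd_std: StdConfig = field(default_factory=StdConfig)
    rd_fm: FmConfig = field(default_factory=FmConfig)
    crf: CrfConfig = field(default_factory=CrfConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            block = d.get(f.name, {})
            sub = f.default_factory()  # type: ignore[misc]
            for k, v in block.items():
                if not hasattr(sub, k):
                    raise KeyError(f"unknown config key {f.name}.{k}")
                if isinstance(getattr(sub, k), tuple) and isinstance(v, list):
                    v = tuple(v)
                setattr(sub, k, v)
            kwargs[f.name] = sub
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
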