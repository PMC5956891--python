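"""End-to-end three-stage detection under leave-one-patient-out CV.

Stage order per held-out patient (the output of each stage feeds the next):

1. **RD-STD** — the sparse texture model (standardisation, PCA, EM mixture)
   is fitted on the *training* patients' gland voxels only; atom occupancy is
   measured on the held-out patient and salient-atom voxels become candidate
   regions.
2. **RD-FM** — the relative-ADC channel is recomputed from the stage-1
   candidates, 242-entry region vectors are assembled, and an SVM on the
   two-stage-selected features (selection and z-scoring statistics from
   training patients only) labels the candidates.
3. **rADC-CRF** — a conditional random field on the relative-ADC texture
   field refines the positive labels at voxel resolution; a region survives
   iff part of it remains in the refined mask.

Nothing derived from the held-out patient (feature standardisation, PCA
loadings, EM atoms, mRMR ranking, classifier weights) enters its own
training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .crf import CRFProblem, build_unary, refine_labels, voxel_features_on_radc
from .evaluate import (EvalReport, evaluate_patients, evaluate_regions,
                       lesion_detection_sensitivity)
from .imaging import CandidateMaskSet, compute_relative_adc
from .phantom import PatientCase
from .rd_fm import (SelectionPlan, SingleClassTrainingError, classify_regions,
                    label_regions, region_table, two_stage_selection)
from .rd_std import (CompactFeatures, SparseTextureModel, beta_matrix,
                     compute_saliency, label_salient_voxels,
                     learn_sparse_texture_model, pca_compact)
from .regions import CandidateRegion, extract_candidate_regions
from .voxel_features import VoxelFeatureMatrix, build_voxel_feature_bank

logger = logging.getLogger("mpcad")

STAGES = ("rd_std", "rd_fm", "radc_crf")


@dataclass
class DetectionResult:
    stage: str
    patient_id: str
    regions: list[CandidateRegion]
    voxel_mask: np.ndarray

    @property
    def positive_regions(self) -> list[CandidateRegion]:
        return [r for r in self.regions if (r.label if r.label is not None else 1) == 1]


@dataclass
class TrainedModels:
    """Per-fold fitted state (trained without the held-out patient)."""

    compactor: CompactFeatures
    texture_model: SparseTextureModel
    beta: np.ndarray
    plan: SelectionPlan | None
    train_table: object | None       # pandas DataFrame of training regions
    train_labels: np.ndarray | None
    train_patient_ids: tuple[str, ...] = ()


def analysis_mask(case: PatientCase, config: PipelineConfig) -> np.ndarray:
    """Gland mask eroded in-plane by the feature-window half-width.

    Windowed texture operators centred on gland-edge voxels would mix
    extra-prostatic signal into their statistics; those partial-volume
    windows otherwise form spuriously distinct texture atoms.  Restricting
    the voxel-resolution analysis to voxels whose window lies inside the
    gland removes that boundary artefact.
    """
    from scipy import ndimage
    from skimage.morphology import disk
    h = config.voxel_features.window // 2
    se = disk(h)
    out = np.zeros_like(case.gland_mask, dtype=bool)
    for z in range(case.shape[2]):
        out[:, :, z] = ndimage.binary_erosion(case.gland_mask[:, :, z], structure=se)
    return out


def case_voxel_bank(case: PatientCase, config: PipelineConfig) -> VoxelFeatureMatrix:
    return build_voxel_feature_bank(case.channels, analysis_mask(case, config),
                                    config.voxel_features)


def fit_texture_stage(train_banks: list[VoxelFeatureMatrix], config: PipelineConfig,
                      seed: int) -> tuple[CompactFeatures, SparseTextureModel, np.ndarray]:
    X = np.concatenate([b.values for b in train_banks], axis=0)
    compact = pca_compact(X, config.rd_std.variance_fraction)
    model = learn_sparse_texture_model(compact.values, config.rd_std.n_atoms, seed)
    beta = beta_matrix(model, compact.u)
    return compact, model, beta


def rd_std_detect(case: PatientCase, bank: VoxelFeatureMatrix,
                  compact: CompactFeatures, model: SparseTextureModel,
                  beta: np.ndarray, config: PipelineConfig) -> DetectionResult:
    """Stage-1 candidates for one (held-out) patient."""
    t = compact.transform(bank.values)
    occupancy = model.occupancy(t)
    alpha = compute_saliency(beta, occupancy, config.rd_std.saliency_prob_index)
    voxel_flags = label_salient_voxels(model.assign(t), alpha)
    mask = np.zeros(case.shape, dtype=bool)
    idx = bank.voxel_index[voxel_flags]
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    regions = extract_candidate_regions(mask, config.rd_std.min_area_vox, case.patient_id)
    kept = np.zeros_like(mask)
    for r in regions:
        r.label = 1   # every stage-1 candidate is a detection
        kept[:, :, r.slice_index] |= r.mask
    logger.info("rd_std[%s]: %d salient voxels -> %d candidate regions",
                case.patient_id, int(mask.sum()), len(regions))
    return DetectionResult("rd_std", case.patient_id, regions, kept)


def radc_from_candidates(case: PatientCase, regions: list[CandidateRegion],
                         config: PipelineConfig) -> np.ndarray:
    """Recompute the relative-ADC channel from stage-1 candidate ROIs."""
    if regions:
        cand = CandidateMaskSet(masks=[r.mask for r in regions],
                                slice_indices=[r.slice_index for r in regions])
    else:
        cand = CandidateMaskSet(masks=[], slice_indices=[])
    return compute_relative_adc(case.channels["ADC"], cand,
                                se_radius_vox=config.derived.se_radius_vox,
                                gland_mask=case.gland_mask)


def run_crf_stage(case: PatientCase, regions: list[CandidateRegion],
                  labels: np.ndarray, scores: np.ndarray, radc: np.ndarray,
                  config: PipelineConfig) -> DetectionResult:
    crf_cfg = config.crf
    valid = analysis_mask(case, config)
    feats = voxel_features_on_radc(radc, valid, config.voxel_features)
    refined = np.zeros(case.shape, dtype=bool)
    slices = sorted({r.slice_index for r in regions})
    for z in slices:
        unary = build_unary(regions, labels, scores, case.shape[:2], z,
                            crf_cfg.p_background)
        problem = CRFProblem(unary=unary, features=feats[:, :, z, :],
                             pairwise_weight=crf_cfg.pairwise_weight,
                             sigma=crf_cfg.sigma, valid=valid[:, :, z])
        refined[:, :, z] = refine_labels(problem, step=crf_cfg.step,
                                         max_iter=crf_cfg.max_iter, tol=crf_cfg.tol)
    out_regions: list[CandidateRegion] = []
    final_mask = np.zeros(case.shape, dtype=bool)
    for r, lab, s in zip(regions, labels, scores):
        rr = CandidateRegion(mask=r.mask.copy(), slice_index=r.slice_index,
                             region_id=r.region_id, patient_id=r.patient_id,
                             boundary=r.boundary, score=float(s))
        if lab == 1:
            shrunk = r.mask & refined[:, :, r.slice_index]
            rr.label = int(shrunk.any())
            if rr.label:
                rr.mask = shrunk
                final_mask[:, :, r.slice_index] |= shrunk
        else:
            rr.label = 0
        out_regions.append(rr)
    logger.info("radc_crf[%s]: %d -> %d positive regions", case.patient_id,
                int(np.sum(labels == 1)),
                sum(1 for r in out_regions if r.label == 1))
    return DetectionResult("radc_crf", case.patient_id, out_regions, final_mask)


def run_mpcad(case: PatientCase, trained: TrainedModels, config: PipelineConfig,
              bank: VoxelFeatureMatrix | None = None) -> list[DetectionResult]:
    """Run the three stages on one held-out patient with pre-fitted models.

    Returns the stage-wise results in pipeline order.
    """
    if bank is None:
        bank = case_voxel_bank(case, config)
    std = rd_std_detect(case, bank, trained.compactor, trained.texture_model,
                        trained.beta, config)
    radc = radc_from_candidates(case, std.regions, config)
    case.channels["rADC"] = radc

    regions = std.regions
    if regions and trained.plan is not None:
        test_table = region_table(regions, {case.patient_id: case}, config.rd_fm)
        try:
            labels, scores = classify_regions(trained.train_table, trained.train_labels,
                                              test_table, trained.plan, config.rd_fm)
        except SingleClassTrainingError:
            only = int(np.unique(trained.train_labels)[0])
            logger.warning("rd_fm[%s]: single-class training fold; labelling all "
                           "regions %d", case.patient_id, only)
            labels = np.full(len(regions), only, dtype=int)
            scores = np.full(len(regions), 1.0 if only else -1.0)
    elif (trained.train_labels is not None and len(trained.train_labels)
          and len(np.unique(trained.train_labels)) == 1):
        only = int(trained.train_labels[0])
        labels = np.full(len(regions), only, dtype=int)
        scores = np.full(len(regions), 1.0 if only else -1.0)
    else:
        labels = np.ones(len(regions), dtype=int)
        scores = np.ones(len(regions))

    fm_regions = []
    fm_mask = np.zeros(case.shape, dtype=bool)
    for r, lab, s in zip(regions, labels, scores):
        rr = CandidateRegion(mask=r.mask, slice_index=r.slice_index,
                             region_id=r.region_id, patient_id=r.patient_id,
                             boundary=r.boundary, label=int(lab), score=float(s))
        if lab == 1:
            fm_mask[:, :, r.slice_index] |= r.mask
        fm_regions.append(rr)
    fm = DetectionResult("rd_fm", case.patient_id, fm_regions, fm_mask)
    logger.info("rd_fm[%s]: %d candidates -> %d positive", case.patient_id,
                len(regions), int(np.sum(labels == 1)))

    crf = run_crf_stage(case, regions, labels, scores, radc, config)
    return [std, fm, crf]


@dataclass
class StudyResult:
    """Everything a LOPO study produces, keyed by stage and patient."""

    detections: dict[str, dict[str, DetectionResult]]  # stage -> patient -> result
    truth: dict[str, np.ndarray]
    stage_reports: dict[str, EvalReport] = field(default_factory=dict)
    patient_report: EvalReport | None = None
    fold_training_patients: dict[str, tuple[str, ...]] = field(default_factory=dict)
    lesion_sensitivity: dict[str, tuple[float, int]] = field(default_factory=dict)


def run_lopo_study(cases: list[PatientCase], config: PipelineConfig | None = None,
                   seed: int = 0) -> StudyResult:
    """Full leave-one-patient-out study over a cohort."""
    config = config or PipelineConfig()
    banks = {c.patient_id: case_voxel_bank(c, config) for c in cases}
    by_id = {c.patient_id: c for c in cases}

    # stage-1 candidates per patient, each from its own LOPO fold
    fold_models: dict[str, TrainedModels] = {}
    std_results: dict[str, DetectionResult] = {}
    fold_training: dict[str, tuple[str, ...]] = {}
    for c in cases:
        train_ids = tuple(o.patient_id for o in cases if o.patient_id != c.patient_id)
        fold_training[c.patient_id] = train_ids
        compact, model, beta = fit_texture_stage([banks[i] for i in train_ids],
                                                 config, seed)
        fold_models[c.patient_id] = TrainedModels(
            compactor=compact, texture_model=model, beta=beta, plan=None,
            train_table=None, train_labels=None, train_patient_ids=train_ids)
        std_results[c.patient_id] = rd_std_detect(c, banks[c.patient_id], compact,
                                                  model, beta, config)

    # relative-ADC channels from each patient's own candidates
    for c in cases:
        c.channels["rADC"] = radc_from_candidates(c, std_results[c.patient_id].regions,
                                                  config)

    # region tables per patient (features depend only on that patient's data)
    tables = {}
    labels = {}
    for c in cases:
        regions = std_results[c.patient_id].regions
        tables[c.patient_id] = region_table(regions, by_id, config.rd_fm)
        labels[c.patient_id] = label_regions(regions, c.truth_mask,
                                             config.rd_fm.overlap_frac)

    detections: dict[str, dict[str, DetectionResult]] = {s: {} for s in STAGES}
    for c in cases:
        pid = c.patient_id
        train_ids = fold_training[pid]
        train_table = pd.concat([tables[i] for i in train_ids], ignore_index=True)
        train_labels = np.concatenate([labels[i] for i in train_ids])
        trained = fold_models[pid]
        trained.train_table = train_table
        trained.train_labels = train_labels
        if len(train_table) and len(np.unique(train_labels)) >= 2:
            trained.plan = two_stage_selection(train_table, train_labels, config.rd_fm)
        else:
            trained.plan = None
            logger.warning("rd_fm[%s]: degenerate training regions; no selection plan", pid)
        for res in run_mpcad(c, trained, config, bank=banks[pid]):
            detections[res.stage][pid] = res

    truth = {c.patient_id: c.truth_mask for c in cases}
    study = StudyResult(detections=detections, truth=truth,
                        fold_training_patients=fold_training)
    for stage in STAGES:
        per_patient = {pid: r.regions for pid, r in detections[stage].items()}
        study.stage_reports[stage] = evaluate_regions(
            per_patient, truth, config.evaluation.overlap_frac)
        study.lesion_sensitivity[stage] = lesion_detection_sensitivity(per_patient, truth)
    study.patient_report = evaluate_patients(
        {pid: r.regions for pid, r in detections["radc_crf"].items()},
        truth, config.evaluation.patient_k_regions)
    return study
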