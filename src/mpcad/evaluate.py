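"""Region- and patient-level detection metrics.

A classified region counts as a true positive when at least ``overlap_frac``
of its area overlaps the ground-truth mask (strict: an overlap fraction just
below the threshold counts against it).  Truth components missed by every
positive region add false negatives.  Confidence intervals on the
proportions are 95% Wilson intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from statsmodels.stats.proportion import proportion_confint

from .regions import CandidateRegion


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


@dataclass
class EvalReport:
    counts: Counts = field(default_factory=Counts)
    sensitivity: float = np.nan
    specificity: float = np.nan
    accuracy: float = np.nan
    sensitivity_ci: tuple[float, float] = (np.nan, np.nan)
    specificity_ci: tuple[float, float] = (np.nan, np.nan)
    accuracy_ci: tuple[float, float] = (np.nan, np.nan)

    def as_dict(self) -> dict:
        c = self.counts
        return {
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _rate(num: int, den: int) -> tuple[float, tuple[float, float]]:
    if den == 0:
        return np.nan, (np.nan, np.nan)
    lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
    return num / den, (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def report_from_counts(c: Counts) -> EvalReport:
    rep = EvalReport(counts=c)
    rep.sensitivity, rep.sensitivity_ci = _rate(c.tp, c.tp + c.fn)
    rep.specificity, rep.specificity_ci = _rate(c.tn, c.tn + c.fp)
    rep.accuracy, rep.accuracy_ci = _rate(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)
    if c.tp + c.fp + c.tn + c.fn == 0:
        # nothing to detect and nothing detected: perfectly specific,
        # sensitivity not applicable
        rep.specificity = 1.0
        rep.specificity_ci = (1.0, 1.0)
    return rep


def _region_overlaps(region: CandidateRegion, truth_mask: np.ndarray) -> int:
    return int(np.sum(region.mask & truth_mask[:, :, region.slice_index].astype(bool)))


def count_regions(regions: list[CandidateRegion], truth_mask: np.ndarray,
                  overlap_frac: float = 0.5) -> Counts:
    """Region-level confusion counts for one patient.

    Positive regions: TP iff overlap >= overlap_frac * area, else FP.
    Negative regions: FN iff they actually overlap truth at the threshold,
    else TN.  Each 3-D truth component (one tumour) hit by no positive
    region at all adds one FN: a missed tumour counts once, not once per
    slice it spans.
    """
    truth = truth_mask.astype(bool)
    c = Counts()
    hit = np.zeros_like(truth)
    for r in regions:
        frac_ok = _region_overlaps(r, truth) >= overlap_frac * r.area
        positive = (r.label if r.label is not None else 1) == 1
        if positive:
            c.tp += int(frac_ok)
            c.fp += int(not frac_ok)
            hit[:, :, r.slice_index] |= r.mask & truth[:, :, r.slice_index]
        else:
            c.fn += int(frac_ok)
            c.tn += int(not frac_ok)
    # tumours untouched by any positive region
    labelled = measure.label(truth, connectivity=truth.ndim)
    for lab in range(1, labelled.max() + 1):
        if not np.any(hit[labelled == lab]):
            c.fn += 1
    return c


def evaluate_regions(regions_by_patient: dict[str, list[CandidateRegion]],
                     truth_by_patient: dict[str, np.ndarray],
                     overlap_frac: float = 0.5) -> EvalReport:
    """Pooled region-level metrics over a cohort."""
    total = Counts()
    for pid, regions in regions_by_patient.items():
        c = count_regions(regions, truth_by_patient[pid], overlap_frac)
        total.tp += c.tp
        total.fp += c.fp
        total.tn += c.tn
        total.fn += c.fn
    return report_from_counts(total)


def lesion_detection_sensitivity(regions_by_patient: dict[str, list[CandidateRegion]],
                                 truth_by_patient: dict[str, np.ndarray]
                                 ) -> tuple[float, int]:
    """Fraction of true tumours (3-D truth components) overlapped by at
    least one positive region; returns ``(sensitivity, n_tumours)``."""
    detected = 0
    total = 0
    for pid, regions in regions_by_patient.items():
        truth = truth_by_patient[pid].astype(bool)
        labelled = measure.label(truth, connectivity=truth.ndim)
        hit = np.zeros_like(truth)
        for r in regions:
            if (r.label if r.label is not None else 1) == 1:
                hit[:, :, r.slice_index] |= r.mask & truth[:, :, r.slice_index]
        for lab in range(1, labelled.max() + 1):
            total += 1
            detected += int(np.any(hit[labelled == lab]))
    return (detected / total if total else np.nan), total


def patient_level_decision(regions: list[CandidateRegion], k_regions: int = 1) -> bool:
    """Patient is called positive iff at least ``k_regions`` regions are
    labelled positive."""
    if k_regions < 1:
        raise ValueError("k_regions must be >= 1")
    n_pos = sum(1 for r in regions if (r.label if r.label is not None else 1) == 1)
    return n_pos >= k_regions


def evaluate_patients(regions_by_patient: dict[str, list[CandidateRegion]],
                      truth_by_patient: dict[str, np.ndarray],
                      k_regions: int = 1) -> EvalReport:
    """Patient-level metrics: a patient is truly positive iff the truth mask
    is non-empty."""
    c = Counts()
    for pid, regions in regions_by_patient.items():
        called = patient_level_decision(regions, k_regions)
        has_cancer = bool(np.any(truth_by_patient[pid]))
        if has_cancer:
            c.tp += int(called)
            c.fn += int(not called)
        else:
            c.fp += int(called)
            c.tn += int(not called)
    return report_from_counts(c)
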