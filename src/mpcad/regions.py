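"""Candidate regions: per-slice connected components of a detection mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure


@dataclass
class CandidateRegion:
    """One 8-connected 2-D region on an axial slice.

    ``mask`` is a full-slice boolean array; ``boundary`` is the closed
    subpixel contour (N x 2 array of (row, col)) traced around the region.
    """

    mask: np.ndarray
    slice_index: int
    region_id: int = 0
    patient_id: str = ""
    boundary: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    label: int | None = None      # classifier label (1 tumour / 0 healthy)
    score: float | None = None    # classifier margin score

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


def trace_boundary(mask2d: np.ndarray) -> np.ndarray:
    """Longest closed subpixel contour around a binary region."""
    padded = np.pad(mask2d.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2))
    contour = max(contours, key=len) - 1.0
    return contour


def extract_candidate_regions(
    mask: np.ndarray,
    min_area_vox: int = 6,
    patient_id: str = "",
) -> list[CandidateRegion]:
    """Per-slice 8-connected components of a 3-D binary mask, dropping
    components smaller than ``min_area_vox``."""
    mask = np.asarray(mask, dtype=bool)
    regions: list[CandidateRegion] = []
    rid = 0
    for z in range(mask.shape[2]):
        labelled = measure.label(mask[:, :, z], connectivity=2)
        for lab in range(1, labelled.max() + 1):
            m = labelled == lab
            if m.sum() < min_area_vox:
                continue
            regions.append(CandidateRegion(
                mask=m, slice_index=z, region_id=rid, patient_id=patient_id,
                boundary=trace_boundary(m)))
            rid += 1
    return regions
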