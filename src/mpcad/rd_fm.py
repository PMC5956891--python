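"""Region-resolution radiomics feature model (RD-FM).

Each candidate region is described by 242 named features:

* 3 **morphology** features from the region boundary — the normalised area
  difference between morphological closing and opening, the normalised
  perimeter change after low-pass Fourier filtering of the boundary, and the
  Jaccard-style symmetric-difference area between a low- and a high-frequency
  Fourier reconstruction of the boundary;
* 4 **asymmetry** features — the normalised area imbalance of the two halves
  obtained by splitting the region through its centroid along the major or
  minor principal axis, normalised by the whole-region area or by the smaller
  half;
* 1 **size** feature — region area in mm^2;
* 26 **physiology** features per channel x 9 channels — 7 first-order
  intensity statistics plus 19 statistics of a single horizontal-offset
  co-occurrence matrix built globally over the region (both pixels of every
  counted pair must lie inside the region).

Morphology, asymmetry and size depend on the mask only; physiology is
repeated per imaging channel.  A two-stage feature selection (per-channel
mRMR + criterion-driven subset-size grid, then a second pass on the pooled
survivors) feeds an RBF-kernel SVM that labels regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage.draw import polygon as draw_polygon
from skimage.morphology import closing as binary_closing
from skimage.morphology import disk
from skimage.morphology import opening as binary_opening
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import FmConfig
from .glcm import REGION_GLCM_STAT_NAMES, glcm_from_pairs, glcm_statistics, quantize
from .imaging import ConfigurationError
from .phantom import CHANNEL_ORDER, PatientCase
from .regions import CandidateRegion

FIRST_ORDER_REGION_NAMES: tuple[str, ...] = (
    "mean", "median", "sd", "min", "max", "kurtosis", "skewness",
)
ASYMMETRY_NAMES: tuple[str, ...] = (
    "major_whole", "major_small", "minor_whole", "minor_small",
)


# ---------------------------------------------------------------- morphology

def morphology_f1(region: CandidateRegion, se_radius: int = 2) -> float:
    """Normalised area difference between closing and opening with an
    identical disk structuring element; 0 for blob-like regions, larger for
    spiculated boundaries."""
    se = disk(se_radius)
    m = region.mask
    pad = se_radius + 1
    mp = np.pad(m, pad)
    a_closed = binary_closing(mp, se).sum()
    a_opened = binary_opening(mp, se).sum()
    return float(a_closed - a_opened) / float(m.sum())


def _resample_closed(boundary: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed contour to ``n_points`` equidistant points."""
    pts = np.asarray(boundary, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0:
        return np.repeat(pts[:1], n_points, axis=0)
    t = np.linspace(0.0, total, n_points, endpoint=False)
    r = np.interp(t, arclen, pts[:, 0])
    c = np.interp(t, arclen, pts[:, 1])
    out = np.stack([r, c], axis=1)
    # short circular moving average: suppresses the marching-squares
    # staircase ripple, which is quantisation noise rather than shape
    if n_points >= 16:
        k = 2
        idx = (np.arange(n_points)[:, None] + np.arange(-k, k + 1)[None, :]) % n_points
        out = out[idx].mean(axis=1)
    return out


def _fourier_reconstruct(boundary: np.ndarray, keep: int, n_points: int = 128) -> np.ndarray:
    """Boundary low-pass filtered to the lowest ``keep`` harmonic pairs."""
    pts = _resample_closed(boundary, n_points)
    z = pts[:, 0] + 1j * pts[:, 1]
    Z = np.fft.fft(z)
    freqs = np.fft.fftfreq(n_points, d=1.0 / n_points)
    Z[np.abs(freqs) > keep] = 0.0
    zr = np.fft.ifft(Z)
    return np.stack([zr.real, zr.imag], axis=1)


def _perimeter(poly: np.ndarray) -> float:
    closed = np.vstack([poly, poly[:1]])
    return float(np.sqrt(((np.diff(closed, axis=0)) ** 2).sum(axis=1)).sum())


def morphology_f2(region: CandidateRegion, keep_freq: int = 8, n_points: int = 128) -> float:
    """Normalised perimeter change after removing high-frequency boundary
    components: ~0 for smooth band-limited shapes."""
    boundary = region.boundary
    if len(boundary) < 4:
        return 0.0
    p_init = _perimeter(_resample_closed(boundary, n_points))
    p_rec = _perimeter(_fourier_reconstruct(boundary, keep_freq, n_points))
    if p_init == 0:
        return 0.0
    return abs(p_init - p_rec) / p_init


def _rasterise(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if len(poly) < 3:
        return mask
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    mask[rr, cc] = True
    return mask


def morphology_f3(region: CandidateRegion, low_freq: int = 2, high_freq: int = 16) -> float:
    """Symmetric-difference over union of the filled low- and high-frequency
    Fourier reconstructions of the boundary; in [0, 1]."""
    if low_freq > high_freq:
        raise ConfigurationError("low_freq must be <= high_freq")
    boundary = region.boundary
    if len(boundary) < 4:
        return 0.0
    shape = region.mask.shape
    lo = _rasterise(_fourier_reconstruct(boundary, low_freq), shape)
    hi = _rasterise(_fourier_reconstruct(boundary, high_freq), shape)
    union = (lo | hi).sum()
    if union == 0:
        return 0.0
    return float((lo ^ hi).sum()) / float(union)


# ----------------------------------------------------------------- asymmetry

def asymmetry_features(region: CandidateRegion, cap: float = 10.0) -> np.ndarray:
    """Bilateral-symmetry imbalance for the four (split axis, normaliser)
    combinations, in :data:`ASYMMETRY_NAMES` order."""
    coords = np.argwhere(region.mask).astype(float)
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = np.cov(centred.T) if len(coords) > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    major = evecs[:, np.argmax(evals)]
    minor = evecs[:, np.argmin(evals)]
    out = []
    for axis_vec in (major, minor):
        # signed distance to the split line through the centroid along axis_vec
        normal = np.array([-axis_vec[1], axis_vec[0]])
        proj = centred @ normal
        a1 = float(np.sum(proj > 1e-9))
        a2 = float(np.sum(proj < -1e-9))
        a_large, a_small = max(a1, a2), min(a1, a2)
        whole = float(len(coords))
        diff = a_large - a_small
        out.append(diff / whole)
        if a_small == 0:
            warnings.warn("degenerate half-region; asymmetry capped")
            out.append(cap)
        else:
            out.append(min(diff / a_small, cap))
    return np.array(out)


# ---------------------------------------------------------------- physiology

def physiology_features(region: CandidateRegion, channel_slice: np.ndarray,
                        levels: int = 32) -> np.ndarray:
    """7 first-order + 19 co-occurrence statistics over the region (26).

    The co-occurrence matrix uses the horizontal offset only and counts a
    pixel pair only when both pixels lie inside the region; it is built
    globally over the region, quantised to ``levels`` by the region's own
    intensity range.
    """
    m = region.mask
    vals = np.asarray(channel_slice, dtype=float)[m]
    sd = float(vals.std())
    first = np.array([
        float(vals.mean()), float(np.median(vals)), sd,
        float(vals.min()), float(vals.max()),
        float(sstats.kurtosis(vals, fisher=True, bias=True)) if sd > 0 else 0.0,
        float(sstats.skew(vals, bias=True)) if sd > 0 else 0.0,
    ])
    q = np.zeros(m.shape, dtype=np.intp)
    q[m] = quantize(np.asarray(channel_slice, dtype=float)[m], levels)
    both = m[:, :-1] & m[:, 1:]
    ia = q[:, :-1][both]
    ja = q[:, 1:][both]
    if ia.size == 0:
        warnings.warn("region has no horizontal pixel pair; degenerate co-occurrence")
    p = glcm_from_pairs(ia, ja, levels)
    second = glcm_statistics(p)
    return np.concatenate([first, second])


# ------------------------------------------------------------------ assembly

@dataclass
class RegionFeatureVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        assert len(self.values) == len(self.names)


def region_feature_names() -> list[str]:
    names = ["morph_f1", "morph_f2", "morph_f3"]
    names += [f"asym_{n}" for n in ASYMMETRY_NAMES]
    names += ["size_mm2"]
    for ch in CHANNEL_ORDER:
        names += [f"phys_{ch}_{s}" for s in FIRST_ORDER_REGION_NAMES]
        names += [f"phys_{ch}_{s}" for s in REGION_GLCM_STAT_NAMES]
    return names


def assemble_region_vector(region: CandidateRegion, case: PatientCase,
                           config: FmConfig | None = None) -> RegionFeatureVector:
    """The full 242-entry feature vector of one region.

    The morphology/asymmetry/size block depends on the mask only and is
    shared across channels; the physiology block repeats per channel in the
    canonical I1..I9 order.
    """
    config = config or FmConfig()
    missing = set(CHANNEL_ORDER) - set(case.channels)
    if missing:
        raise ConfigurationError(f"case is missing channels: {sorted(missing)}")
    z = region.slice_index
    mas = np.concatenate([
        [morphology_f1(region, config.se_radius_vox),
         morphology_f2(region, config.keep_freq, config.boundary_points),
         morphology_f3(region, config.low_freq, config.high_freq)],
        asymmetry_features(region, config.asymmetry_cap),
        [region.area * case.voxel_spacing[0] * case.voxel_spacing[1]],
    ])
    phys = [physiology_features(region, case.channels[ch][:, :, z], config.glcm_levels)
            for ch in CHANNEL_ORDER]
    values = np.concatenate([mas] + phys)
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return RegionFeatureVector(values=values, names=region_feature_names())


def region_table(regions: list[CandidateRegion], cases: dict[str, PatientCase],
                 config: FmConfig | None = None) -> pd.DataFrame:
    """Feature table: one row per region, 242 named columns plus
    patient_id / region_id / slice."""
    rows = []
    meta = []
    for r in regions:
        vec = assemble_region_vector(r, cases[r.patient_id], config)
        rows.append(vec.values)
        meta.append((r.patient_id, r.region_id, r.slice_index))
    df = pd.DataFrame(np.array(rows) if rows else np.zeros((0, 242)),
                      columns=region_feature_names())
    md = pd.DataFrame(meta, columns=["patient_id", "region_id", "slice"]) if meta else \
        pd.DataFrame(columns=["patient_id", "region_id", "slice"])
    return pd.concat([md, df], axis=1)


def label_regions(regions: list[CandidateRegion], truth_mask: np.ndarray,
                  overlap_frac: float = 0.5) -> np.ndarray:
    """A region is positive iff at least ``overlap_frac`` of its area
    overlaps the truth mask."""
    labels = []
    for r in regions:
        overlap = np.sum(r.mask & truth_mask[:, :, r.slice_index].astype(bool))
        labels.append(int(overlap >= overlap_frac * r.area))
    return np.array(labels, dtype=int)


# ----------------------------------------------------------- feature selection

def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two small discrete label arrays."""
    a = np.asarray(a, dtype=np.intp)
    b = np.asarray(b, dtype=np.intp)
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    c = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    c /= c.sum()
    outer = c.sum(axis=1, keepdims=True) @ c.sum(axis=0, keepdims=True)
    nz = c > 0
    return float(np.sum(c[nz] * np.log(c[nz] / outer[nz])))


def _discretize(X: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; columns with few distinct values keep them."""
    out = np.empty(X.shape, dtype=int)
    for k in range(X.shape[1]):
        col = X[:, k]
        uniq = np.unique(col)
        if len(uniq) <= bins:
            out[:, k] = np.searchsorted(uniq, col)
            continue
        try:
            binned = pd.qcut(col, q=bins, labels=False, duplicates="drop")
            out[:, k] = np.nan_to_num(np.asarray(binned, dtype=float)).astype(int)
        except ValueError:
            out[:, k] = 0
    return out


def mrmr_select(X: np.ndarray, y: np.ndarray, k: int, bins: int = 10) -> list[int]:
    """Greedy maximum-relevance minimum-redundancy feature ranking.

    Features are discretised into equal-frequency bins for the mutual
    information estimates.  At each step the feature maximising
    ``MI(f; y) - mean MI(f; selected)`` is added; ties break to the lower
    column index; the first pick is the maximum-relevance feature.
    """
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    if k > n_feat:
        warnings.warn("k larger than the number of features; capped")
        k = n_feat
    # equal-frequency binning needs a handful of samples per bin
    bins = max(2, min(bins, X.shape[0] // 4))
    Xd = _discretize(X, bins)
    relevance = np.array([_mutual_info(Xd[:, j], y) for j in range(n_feat)])
    selected: list[int] = [int(np.argmax(relevance))]
    red_cache = np.zeros((n_feat, 0))
    while len(selected) < k:
        new_col = np.array([[_mutual_info(Xd[:, j], Xd[:, selected[-1]])]
                            for j in range(n_feat)])
        red_cache = np.hstack([red_cache, new_col])
        score = relevance - red_cache.mean(axis=1)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


@dataclass
class SelectionPlan:
    """Outcome of the two-stage selection: per-channel survivors, the
    morphology/asymmetry/size survivors, and the final pooled subset
    (indices into the 242-column table)."""

    per_channel_selected: dict[str, list[int]] = field(default_factory=dict)
    mas_selected: list[int] = field(default_factory=list)
    final_selected: list[int] = field(default_factory=list)
    criterion: str = "auc"

    def to_dict(self) -> dict:
        return {
            "per_channel_selected": self.per_channel_selected,
            "mas_selected": self.mas_selected,
            "final_selected": self.final_selected,
            "criterion": self.criterion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionPlan":
        return cls(**d)


def _criterion_score(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray,
                     criterion: str) -> float:
    pos = y_true == 1
    neg = ~pos
    if criterion == "sensitivity":
        return float(np.mean(y_pred[pos] == 1)) if pos.any() else np.nan
    if criterion == "specificity":
        return float(np.mean(y_pred[neg] == 0)) if neg.any() else np.nan
    if criterion == "auc":
        if pos.any() and neg.any():
            return float(roc_auc_score(y_true, scores))
        return np.nan
    raise ConfigurationError(f"unknown criterion {criterion!r}")


def _make_svm(config: FmConfig) -> SVC:
    # candidate sets are heavily imbalanced (few true tumour regions among
    # many false positives); balance the class penalties
    return SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma,
               class_weight="balanced")


def _cv_criterion(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                  criterion: str, config: FmConfig) -> float:
    """Grouped-CV criterion of an SVM on the given columns (training data
    only; groups are patients)."""
    n_groups = len(np.unique(groups))
    n_splits = min(config.inner_folds, n_groups)
    if n_splits < 2 or len(np.unique(y)) < 2:
        return np.nan
    scores = []
    for tr, te in GroupKFold(n_splits=n_splits).split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            continue
        scaler = StandardScaler().fit(X[tr])
        clf = _make_svm(config).fit(scaler.transform(X[tr]), y[tr])
        Xte = scaler.transform(X[te])
        s = _criterion_score(y[te], clf.predict(Xte), clf.decision_function(Xte), criterion)
        if not np.isnan(s):
            scores.append(s)
    return float(np.mean(scores)) if scores else np.nan


def two_stage_selection(table: pd.DataFrame, labels: np.ndarray,
                        config: FmConfig | None = None) -> SelectionPlan:
    """Two-stage criterion-driven selection over the 242-column table.

    Stage 1 ranks each channel's 26 physiology features (and the 8-entry
    morphology/asymmetry/size block) by mRMR, then grid-searches the prefix
    size that maximises the criterion of an SVM under grouped CV on the
    training patients.  Stage 2 pools the survivors and repeats ranking and
    grid search to produce the final subset.
    """
    config = config or FmConfig()
    names = region_feature_names()
    name_idx = {n: i for i, n in enumerate(names)}
    X_all = table[names].to_numpy(dtype=float)
    groups = table["patient_id"].to_numpy()
    y = np.asarray(labels, dtype=int)

    def best_prefix(idx: list[int], max_n: int) -> list[int]:
        ranked = [idx[j] for j in mrmr_select(X_all[:, idx], y, min(max_n, len(idx)),
                                              config.mrmr_bins)]
        best_score, best_n = -np.inf, 1
        for n in range(1, len(ranked) + 1):
            s = _cv_criterion(X_all[:, ranked[:n]], y, groups, config.criterion, config)
            if not np.isnan(s) and s > best_score + 1e-12:
                best_score, best_n = s, n
        return ranked[:best_n]

    plan = SelectionPlan(criterion=config.criterion)
    for ch in CHANNEL_ORDER:
        idx = [name_idx[n] for n in names if n.startswith(f"phys_{ch}_")]
        plan.per_channel_selected[ch] = best_prefix(idx, 26)
    mas_idx = [i for i, n in enumerate(names)
               if n.startswith(("morph_", "asym_", "size_"))]
    plan.mas_selected = best_prefix(mas_idx, 8)

    pooled = sorted(set(sum(plan.per_channel_selected.values(), []) + plan.mas_selected))
    if not pooled:
        raise RuntimeError("empty survivor pool after stage 1")
    plan.final_selected = best_prefix(pooled, len(pooled))
    return plan


class SingleClassTrainingError(ValueError):
    pass


def classify_regions(train_table: pd.DataFrame, train_labels: np.ndarray,
                     test_table: pd.DataFrame, plan: SelectionPlan,
                     config: FmConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Train the margin classifier on the selected features (z-scored with
    training statistics) and score the test regions.

    Returns ``(labels, scores)`` with positive scores on the tumour side.
    """
    config = config or FmConfig()
    names = region_feature_names()
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassTrainingError("training regions contain a single class")
    cols = [names[i] for i in plan.final_selected]
    Xtr = train_table[cols].to_numpy(dtype=float)
    Xte = test_table[cols].to_numpy(dtype=float)
    scaler = StandardScaler().fit(Xtr)
    clf = _make_svm(config).fit(scaler.transform(Xtr), y)
    if len(Xte) == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    scores = clf.decision_function(scaler.transform(Xte))
    return clf.predict(scaler.transform(Xte)).astype(int), scores
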