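"""Voxel-resolution statistical textural distinctiveness (RD-STD).

The 96-feature texture bank is compacted by PCA to the leading components
explaining 90% of the variance.  A sparse texture model — a small Gaussian
mixture of *texture atoms* (mean, covariance in PCA space) — is learned by
expectation maximisation on training gland voxels.  The distinctiveness of
every atom pair is scored with a KL-divergence-style statistic

    beta_ij = log(|S_j|/|S_i|) - u + tr(S_j^-1 S_i)
              + (mu_j - mu_i)^T S_j^-1 (mu_j - mu_i) / 2

(note: only the Mahalanobis term is halved).  An atom's saliency combines its
distinctiveness with the occurrence probabilities of the atoms on the test
patient; voxels of atoms with saliency above half the maximum are flagged as
suspicious and grouped into candidate regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .imaging import ConfigurationError, StructuralError
from .regions import CandidateRegion, extract_candidate_regions  # noqa: F401 (re-export)


@dataclass
class CompactFeatures:
    """PCA-compacted texture features plus the fitted transform."""

    values: np.ndarray
    u: int
    variance_fraction: float
    scaler: StandardScaler
    pca: PCA

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new feature rows with the training standardisation/loadings."""
        return self.pca.transform(self.scaler.transform(X))[:, : self.u]


@dataclass
class TextureAtom:
    mean: np.ndarray
    covariance: np.ndarray
    weight: float


@dataclass
class SparseTextureModel:
    atoms: list[TextureAtom]
    m: int
    seed: int
    mixture: GaussianMixture

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        """Posterior atom probabilities per voxel, shape (n, m)."""
        return self.mixture.predict_proba(X)

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Maximum-responsibility atom index per voxel."""
        return self.mixture.predict(X)

    def occupancy(self, X: np.ndarray) -> np.ndarray:
        """Occurrence probability of each atom in a test feature set: the
        mean posterior responsibility (sums to 1)."""
        return self.responsibilities(X).mean(axis=0)


@dataclass
class SaliencyResult:
    beta: np.ndarray
    alpha: np.ndarray
    occupancy: np.ndarray
    voxel_labels: np.ndarray


def pca_compact(values: np.ndarray, variance_fraction: float = 0.90) -> CompactFeatures:
    """Standardise columns and keep the smallest number of principal
    components whose cumulative explained variance reaches
    ``variance_fraction``."""
    X = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise StructuralError("features must be finite")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    pca = PCA(svd_solver="full").fit(Xs)
    evr = np.cumsum(pca.explained_variance_ratio_)
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if variance_fraction >= 1.0:
        u = rank
    else:
        u = int(np.searchsorted(evr, variance_fraction) + 1)
        if u > rank:
            warnings.warn("rank-deficient input; components capped at rank")
            u = rank
    u = max(u, 1)
    return CompactFeatures(values=pca.transform(Xs)[:, :u], u=u,
                           variance_fraction=variance_fraction, scaler=scaler, pca=pca)


def learn_sparse_texture_model(values: np.ndarray, m: int, seed: int = 0) -> SparseTextureModel:
    """Fit the m-atom Gaussian mixture by EM (k-means++ initialisation,
    covariance ridge 1e-6, tolerance 1e-6, at most 500 iterations)."""
    X = np.asarray(values, dtype=float)
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    if X.shape[0] < 10 * m and m > 1:
        raise ConfigurationError("need at least 10 voxels per texture atom")

    def _fit(rs: int) -> GaussianMixture:
        return GaussianMixture(
            n_components=m, covariance_type="full", reg_covar=1e-6, tol=1e-6,
            max_iter=500, init_params="k-means++", random_state=rs, n_init=1,
        ).fit(X)

    gm = _fit(seed)
    if np.any(gm.weights_ < 1e-8):
        warnings.warn("EM component collapse; re-seeding once")
        gm = _fit(seed + 1)
        if np.any(gm.weights_ < 1e-8):
            raise RuntimeError("EM collapsed twice; reduce m")
    atoms = [TextureAtom(mean=gm.means_[i].copy(), covariance=gm.covariances_[i].copy(),
                         weight=float(gm.weights_[i])) for i in range(m)]
    return SparseTextureModel(atoms=atoms, m=m, seed=seed, mixture=gm)


def kl_distinctiveness(atom_i: TextureAtom, atom_j: TextureAtom, u: int) -> float:
    """Pairwise textural distinctiveness of two atoms (see module docstring).

    Zero when the atoms coincide; grows as the Gaussians separate.
    """
    si, sj = atom_i.covariance, atom_j.covariance
    sign_j, logdet_j = np.linalg.slogdet(sj)
    sign_i, logdet_i = np.linalg.slogdet(si)
    if sign_j <= 0 or sign_i <= 0:
        raise np.linalg.LinAlgError("covariances must be positive-definite")
    sj_inv = np.linalg.inv(sj)
    dmu = atom_j.mean - atom_i.mean
    return float(logdet_j - logdet_i - u + np.trace(sj_inv @ si)
                 + dmu @ sj_inv @ dmu / 2.0)


def beta_matrix(model: SparseTextureModel, u: int) -> np.ndarray:
    """All pairwise distinctiveness values; the diagonal is exactly 0."""
    m = model.m
    beta = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                beta[i, j] = kl_distinctiveness(model.atoms[i], model.atoms[j], u)
    return beta


def compute_saliency(beta: np.ndarray, occupancy: np.ndarray,
                     prob_index: str = "i") -> np.ndarray:
    """Atom saliency from the distinctiveness matrix and atom occurrence
    probabilities.

    ``prob_index='i'`` weights each row sum by the occurrence probability of
    the atom being scored, ``alpha_i = P(t_i|Z) * sum_j beta_ij`` (the
    self-indexed form); ``prob_index='j'`` weights each term by the
    probability of the atom compared against,
    ``alpha_i = sum_j beta_ij * P(t_j|Z)``, which makes rare-but-distinct
    textures salient in a healthy-dominated gland.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if not np.isclose(occupancy.sum(), 1.0, atol=1e-6):
        raise StructuralError("occupancy must be a probability vector")
    if prob_index == "i":
        return occupancy * beta.sum(axis=1)
    if prob_index == "j":
        return beta @ occupancy
    raise ConfigurationError("prob_index must be 'i' or 'j'")


def label_salient_voxels(assignments: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Binary voxel labels: 1 iff the voxel's atom has saliency strictly
    above half the maximum."""
    alpha = np.asarray(alpha, dtype=float)
    salient_atoms = alpha > alpha.max() / 2.0
    return salient_atoms[np.asarray(assignments, dtype=int)]
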