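"""Essential dynamics: PCA of Calpha positional fluctuations.

The workflow is the classical one: iteratively least-squares superpose all
frames onto their running mean to remove rigid-body motion, build the
(unweighted) 3N x 3N covariance matrix of the Cartesian fluctuations,
diagonalise it, and project the trajectory onto the eigenvectors. The few
largest-eigenvalue modes that show markedly non-Gaussian projection
distributions form the "essential space" carrying the large, correlated
conformational motions; the remaining modes are small, Gaussian
near-constraints. The deviation-from-gaussianity score ranks the modes and
selects the essential dimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import InsufficientDataError, MetamorphError, SuperpositionError
from .trajectory import Trajectory

__all__ = [
    "EssentialBasis", "ProjectionSeries", "GaussianityReport",
    "superpose", "covariance", "eigendecompose", "project",
    "gaussianity_deviation", "select_essential_dim", "mode_components",
]


@dataclass
class EssentialBasis:
    """Mean structure plus covariance eigenvectors/eigenvalues.

    Eigenvector columns are ordered by decreasing eigenvalue (nm^2) and
    carry a deterministic sign (largest-magnitude component positive).
    """

    mean_structure: np.ndarray  # (atoms, 3), nm
    eigenvectors: np.ndarray    # (3N, 3N), columns
    eigenvalues: np.ndarray     # (3N,), nm^2, descending

    @property
    def n_atoms(self) -> int:
        return self.mean_structure.shape[0]


@dataclass
class ProjectionSeries:
    """Projections (frames x modes, nm) onto selected eigenvectors."""

    values: np.ndarray
    mode_indices: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_modes(self) -> int:
        return self.values.shape[1]


@dataclass
class GaussianityReport:
    """Per-mode deviation-from-gaussianity scores (dimensionless, >= 0)."""

    deviation: np.ndarray
    mode_indices: np.ndarray


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _kabsch_batch(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares fit every frame onto ``ref`` (rotation + translation)."""
    ref_c = ref - ref.mean(axis=0)
    centroids = coords.mean(axis=1, keepdims=True)
    x = coords - centroids
    h = np.einsum("fai,aj->fij", x, ref_c)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    # flip the smallest singular direction when the fit would be a reflection
    u[:, :, 2] *= np.sign(det)[:, None]
    rot = np.einsum("fij,fjk->fik", u, vt)
    return np.einsum("fai,fij->faj", x, rot) + ref.mean(axis=0)


def superpose(traj: Trajectory, max_iter: int = 50, tol: float = 1e-10
              ) -> tuple[Trajectory, np.ndarray]:
    """Iteratively fit all frames to the running mean structure.

    Each pass least-squares fits every frame (unweighted rotation +
    translation) onto the current mean, then recomputes the mean; it stops
    when the mean structure moves by less than ``tol`` RMS (nm) or after
    ``max_iter`` passes. The initial reference is the raw coordinate mean
    (falling back to the first frame if averaging unaligned frames collapses
    it), which makes the operation a fixed point on already-aligned input.
    Returns the aligned trajectory and the converged mean structure.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("superposition needs at least 2 frames")
    if traj.n_atoms < 3:
        raise SuperpositionError("superposition needs at least 3 atoms")
    ref = traj.coords.mean(axis=0)
    if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-9) < 2:
        ref = traj.coords[0]
    if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-9) < 2:
        raise SuperpositionError("reference structure is collinear/degenerate")
    coords = traj.coords
    aligned = coords
    for _ in range(max_iter):
        aligned = _kabsch_batch(coords, ref)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_mean - ref) ** 2)))
        ref = new_mean
        if shift < tol:
            break
    return (Trajectory(aligned, traj.atom_names, traj.residue_ids,
                       traj.residue_names, traj.frame_stride_ps), ref)


# ---------------------------------------------------------------------------
# Covariance and eigendecomposition
# ---------------------------------------------------------------------------

def covariance(aligned: Trajectory) -> np.ndarray:
    """Unweighted positional covariance C = <(x - <x>)(x - <x>)^T> (nm^2).

    The denominator is the frame count (population covariance).
    """
    if aligned.n_frames < 2:
        raise InsufficientDataError("covariance needs at least 2 frames")
    x = aligned.flat()
    x = x - x.mean(axis=0)
    return (x.T @ x) / aligned.n_frames


def eigendecompose(c: np.ndarray, mean_structure: np.ndarray | None = None
                   ) -> EssentialBasis:
    """Diagonalise a symmetric PSD covariance matrix.

    Eigenvalues are sorted descending with tiny negatives clipped to zero;
    each eigenvector's sign is fixed so its largest-magnitude component is
    positive.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise MetamorphError(f"covariance must be square, got {c.shape}")
    scale = max(np.abs(c).max(), 1.0)
    if np.abs(c - c.T).max() > 1e-8 * scale:
        raise MetamorphError("covariance matrix is not symmetric")
    evals, evecs = np.linalg.eigh((c + c.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    idx = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[idx, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    if mean_structure is None:
        mean_structure = np.zeros((c.shape[0] // 3, 3))
    return EssentialBasis(np.asarray(mean_structure, dtype=float), evecs, evals)


def project(traj: Trajectory, basis: EssentialBasis,
            mode_indices=None) -> ProjectionSeries:
    """Project centred coordinates onto selected eigenvectors (0-based)."""
    n_modes_total = basis.eigenvectors.shape[1]
    if mode_indices is None:
        mode_indices = np.arange(n_modes_total)
    mode_indices = np.atleast_1d(np.asarray(mode_indices, dtype=int))
    if mode_indices.size and (mode_indices.min() < 0 or mode_indices.max() >= n_modes_total):
        raise IndexError(f"mode indices out of range [0, {n_modes_total})")
    centred = traj.flat() - basis.mean_structure.reshape(-1)
    values = centred @ basis.eigenvectors[:, mode_indices]
    return ProjectionSeries(values, mode_indices)


# ---------------------------------------------------------------------------
# Gaussianity and dimensionality selection
# ---------------------------------------------------------------------------

def gaussianity_deviation(series: ProjectionSeries, n_bins: int = 50
                          ) -> GaussianityReport:
    """Mean absolute per-bin difference to the matched Gaussian.

    Each mode's projection is histogrammed over [mu - 4 sigma, mu + 4 sigma]
    with ``n_bins`` equal bins (mass = fraction of all frames per bin, so
    tail mass outside the window is simply absent, as for the reference).
    The reference mass is a Gaussian with the mode's sample mean and
    variance integrated over the same bins; the score is the mean over bins
    of the absolute difference. Zero-variance modes score 0 with a warning.
    """
    if series.n_frames < 100:
        raise InsufficientDataError("gaussianity deviation needs >= 100 frames")
    n_frames = series.n_frames
    scores = np.zeros(series.n_modes)
    for k in range(series.n_modes):
        x = series.values[:, k]
        mu, sigma = float(x.mean()), float(x.std())
        if sigma == 0.0:
            warnings.warn(f"mode {series.mode_indices[k]} has zero variance; "
                          "deviation set to 0")
            continue
        edges = np.linspace(mu - 4 * sigma, mu + 4 * sigma, n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
        empirical = counts / n_frames
        reference = np.diff(norm.cdf(edges, loc=mu, scale=sigma))
        scores[k] = float(np.mean(np.abs(empirical - reference)))
    return GaussianityReport(scores, series.mode_indices.copy())


def select_essential_dim(report: GaussianityReport, mode: str = "fixed",
                         k: int = 6, epsilon: float = 3e-3) -> int:
    """Pick the essential dimensionality.

    ``fixed`` returns ``k`` outright. ``threshold`` returns the smallest d
    such that every mode ranked after d scores below ``epsilon``; if even
    the first mode is sub-threshold the result is 1 with a warning.
    """
    if report.deviation.size == 0:
        raise MetamorphError("empty gaussianity report")
    if mode == "fixed":
        if not 1 <= k <= report.deviation.size:
            raise MetamorphError(f"fixed dimensionality {k} outside [1, {report.deviation.size}]")
        return k
    if mode != "threshold":
        raise ValueError(f"unknown selection mode {mode!r}")
    above = np.nonzero(report.deviation >= epsilon)[0]
    if above.size == 0:
        warnings.warn("all modes are sub-threshold; defaulting to 1 essential mode")
        return 1
    return int(above[-1]) + 1


def mode_components(basis: EssentialBasis, mode_index: int) -> np.ndarray:
    """Per-atom displacement magnitude within one eigenvector.

    Returns the Euclidean norm of each atom's 3-vector; the squared norms
    sum to 1 for a unit eigenvector.
    """
    n_modes = basis.eigenvectors.shape[1]
    if not 0 <= mode_index < n_modes:
        raise IndexError(f"mode index {mode_index} outside [0, {n_modes})")
    vec = basis.eigenvectors[:, mode_index].reshape(-1, 3)
    return np.linalg.norm(vec, axis=1)
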