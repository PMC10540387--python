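"""Principal-component characterization and GH (global distance) outlier screening.

Spectra are decomposed by PCA on the column-centered (unscaled) matrix; the
top components summarize the population structure. Each sample's GH is its
squared Mahalanobis distance in the retained k-component score space divided
by k, using the fitting-set score covariance (n-1 denominator). Samples with
GH above a threshold (default 3.0, standard NIRS practice) are flagged as
spectral outliers; flagged samples are reported, never silently removed.

With the n-1 covariance the mean GH over the fitting set is exactly
(n-1)/n — a trace identity used as a self-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .errors import DataError, ModelingError
from .spectra import SpectraSet

DEFAULT_K = 10
DEFAULT_GH_THRESHOLD = 3.0


@dataclass
class PCAModel:
    """Centered PCA of a spectra set: mean spectrum, loadings, variance shares."""

    center: np.ndarray  # mean spectrum (p,)
    loadings: np.ndarray  # (k, p), rows orthonormal
    explained_variance_ratio: np.ndarray  # (k,), non-increasing, sum <= 1
    k: int
    grid: np.ndarray  # wavenumber grid the model was fitted on
    score_cov: np.ndarray  # (k, k) covariance of fitting-set scores, ddof=1
    n_fit: int


@dataclass
class GHReport:
    """Per-sample GH distances with flags at a threshold."""

    sample_ids: list[str]
    gh: np.ndarray
    threshold: float
    flags: np.ndarray  # boolean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "GH": self.gh, "flag": self.flags})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_pca(s: SpectraSet, k: int = DEFAULT_K) -> PCAModel:
    """PCA of the column-centered spectral matrix, by descending variance.

    Sign convention: each loading's largest-magnitude element is positive,
    making the decomposition deterministic.
    """
    n, p = s.values.shape
    if n < 3:
        raise DataError("PCA needs at least 3 spectra")
    if k < 1 or k > min(n - 1, p):
        raise ModelingError(f"k={k} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    center = s.values.mean(axis=0)
    xc = s.values - center
    _, sing, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((sing**2).sum())
    if total == 0:
        raise ModelingError("spectra are all identical; PCA undefined")
    loadings = vt[:k].copy()
    # deterministic sign: largest-|.| element of each loading positive
    for j in range(k):
        idx = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, idx] < 0:
            loadings[j] *= -1.0
    t = xc @ loadings.T
    score_cov = np.cov(t, rowvar=False, ddof=1).reshape(k, k)
    return PCAModel(
        center=center,
        loadings=loadings,
        explained_variance_ratio=sing[:k] ** 2 / total,
        k=k,
        grid=s.grid.copy(),
        score_cov=score_cov,
        n_fit=n,
    )


def scores(m: PCAModel, s: SpectraSet) -> np.ndarray:
    """Project spectra on the retained loadings: (values - center) @ loadings.T."""
    if s.grid.size != m.grid.size or not np.allclose(s.grid, m.grid):
        raise DataError("spectra grid does not match the grid the PCA was fitted on")
    return (s.values - m.center) @ m.loadings.T


def reconstruct(m: PCAModel, s: SpectraSet) -> np.ndarray:
    """Rank-k reconstruction of the spectra from their scores."""
    return scores(m, s) @ m.loadings + m.center


def gh_distance(m: PCAModel, s: SpectraSet, threshold: float = DEFAULT_GH_THRESHOLD) -> GHReport:
    """GH = squared Mahalanobis distance in score space divided by k.

    The covariance is the fitting-set score covariance stored in the model;
    distances are taken about the fitting-set score mean (zero by centering).
    """
    if m.k < 2:
        raise ModelingError("GH screening needs a PCA with k >= 2 components")
    t = scores(m, s)
    try:
        chol = np.linalg.cholesky(m.score_cov)
    except np.linalg.LinAlgError as exc:
        raise ModelingError("singular fitting-set score covariance; reduce k") from exc
    w = solve_triangular(chol, t.T, lower=True)
    gh = (w**2).sum(axis=0) / m.k
    flags = gh > threshold
    return GHReport(list(s.sample_ids), gh, float(threshold), flags)


def explained_variance_frame(m: PCAModel) -> pd.DataFrame:
    """Per-component explained-variance ratios (for the PCA summary CSV)."""
    return pd.DataFrame(
        {
            "component": np.arange(1, m.k + 1),
            "explained_variance_ratio": m.explained_variance_ratio,
            "cumulative": np.cumsum(m.explained_variance_ratio),
        }
    )
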