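"""Ordination methods (PCA, PCoA, CA) and horseshoe/arch diagnostics.

All three embeddings return an :class:`OrdinationResult` with sample
coordinates, eigenvalues sorted nonincreasing, and proportions of explained
variance (inertia for CA).  Axis signs follow a fixed convention — each
axis is oriented so its largest-magnitude entry is positive — making runs
reproducible.

The diagnostics make the horseshoe claim testable:

* :func:`gradient_axis_correlation` — Spearman rank correlation between a
  known gradient and axis-1 scores; a nonsaturating metric should put the
  whole gradient on axis 1 (|rho| near 1).
* :func:`arch_test` — a quadratic-fit curvature detector on (axis 1,
  axis 2); the arch/horseshoe bends the gradient into a parabola-like
  curve, so a large normalized quadratic coefficient flags it.
* :func:`horseshoe_sign_test` — a sign test: both gradient endpoints on one
  side of the axis-2 median and the gradient midpoint on the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from skbio import DistanceMatrix

from .exceptions import DegenerateSampleError
from .tables import FeatureTable

__all__ = [
    "OrdinationResult",
    "pca",
    "pcoa",
    "ca",
    "gradient_axis_correlation",
    "arch_test",
    "horseshoe_sign_test",
]

_EIG_TOL = 1e-10  # relative cutoff for treating an eigenvalue as zero


@dataclass(frozen=True)
class OrdinationResult:
    """Sample embedding with eigenvalue bookkeeping."""

    sample_ids: tuple
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # nonincreasing, one per retained axis
    proportion_explained: np.ndarray
    method: str
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axis(self, k: int) -> np.ndarray:
        return self.coordinates[:, k]


def _orient_axes(coords: np.ndarray, loadings: np.ndarray | None = None) -> np.ndarray:
    """Flip axis signs so the largest-|value| loading (or coordinate) is positive."""
    ref = coords if loadings is None else loadings
    out = coords.copy()
    for k in range(coords.shape[1]):
        col = ref[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -out[:, k]
    return out


def pca(
    matrix: np.ndarray,
    n_axes: int = 2,
    sample_ids=None,
) -> OrdinationResult:
    """Principal-component analysis of a samples-by-features matrix.

    Columns are mean-centered; coordinates are projections onto the top
    right-singular directions scaled by the singular values, so pairwise
    coordinate distances in full dimension equal Euclidean distances of the
    centered rows.  Eigenvalues are variances ``s_k^2 / (n - 1)``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples (rows)")
    n = X.shape[0]
    ids = tuple(str(s) for s in (sample_ids if sample_ids is not None else range(n)))
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > _EIG_TOL * (s[0] if s.size else 1.0)))
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but rank is {rank}; truncating", stacklevel=2
        )
        n_axes = rank
    eig_all = s**2 / (n - 1)
    total = eig_all.sum()
    coords = U[:, :n_axes] * s[:n_axes]
    coords = _orient_axes(coords, loadings=Vt[:n_axes].T)
    return OrdinationResult(
        ids,
        coords,
        eig_all[:n_axes],
        eig_all[:n_axes] / total if total > 0 else np.zeros(n_axes),
        "pca",
    )


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal-coordinate analysis (classical MDS) of a distance matrix.

    Eigendecomposes the Gower-centered matrix ``B = -1/2 J D^2 J``.  Axes
    with positive eigenvalues carry coordinates ``v_k * sqrt(lambda_k)``;
    negative eigenvalues (non-Euclidean distances) are reported in
    ``negative_eigenvalues`` and their axes dropped — no Cailliez/Lingoes
    correction is applied, since such corrections alter the very distances
    under study.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    scale = np.max(np.abs(eigvals)) if n else 0.0
    tol = _EIG_TOL * max(scale, 1.0)
    positive = eigvals > tol
    negative = eigvals[eigvals < -tol]
    if not positive.any():
        warnings.warn("no positive eigenvalues; degenerate configuration", stacklevel=2)
        return OrdinationResult(
            tuple(dm.ids), np.zeros((n, 1)), np.zeros(1), np.zeros(1), "pcoa", -negative
        )
    lam = eigvals[positive]
    vecs = eigvecs[:, positive]
    k = min(n_axes, lam.size)
    coords = vecs[:, :k] * np.sqrt(lam[:k])
    coords = _orient_axes(coords)
    total = lam.sum()
    return OrdinationResult(
        tuple(dm.ids),
        coords,
        lam[:k],
        lam[:k] / total,
        "pcoa",
        np.abs(negative),
    )


def ca(table: FeatureTable, n_axes: int = 2) -> OrdinationResult:
    """Correspondence analysis of a feature table; samples in principal
    coordinates.

    Treating samples as the rows of a contingency table with relative
    frequencies P, sample masses r, and feature masses c, the standardized
    residuals ``S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` are decomposed by
    SVD; sample principal coordinates are ``D_r^{-1/2} U Sigma``, whose
    full-dimension pairwise distances equal the chi-squared distances
    between samples.  Eigenvalues are the principal inertias ``sigma_k^2``.
    """
    X = table.values.T.astype(float)  # samples x features
    total = X.sum()
    if total <= 0:
        raise DegenerateSampleError("table has zero grand total")
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {int((~row_ok).sum())} all-zero samples and "
            f"{int((~col_ok).sum())} all-zero features",
            stacklevel=2,
        )
    ids = tuple(s for s, ok in zip(table.sample_ids, row_ok) if ok)
    X = X[np.ix_(row_ok, col_ok)]
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int(np.sum(s > _EIG_TOL * (s[0] if s.size else 1.0)))
    k = min(n_axes, max(rank, 1))
    if n_axes > rank:
        warnings.warn(f"requested {n_axes} axes but rank is {rank}; truncating", stacklevel=2)
    coords = (U[:, :k] * s[:k]) / np.sqrt(r)[:, None]
    coords = _orient_axes(coords)
    inertia = s**2
    total_inertia = inertia.sum()
    return OrdinationResult(
        ids,
        coords,
        inertia[:k],
        inertia[:k] / total_inertia if total_inertia > 0 else np.zeros(k),
        "ca",
    )


# ---------------------------------------------------------------------------
# horseshoe / arch diagnostics
# ---------------------------------------------------------------------------

def gradient_axis_correlation(result: OrdinationResult, gradient) -> float:
    """Spearman rank correlation between axis-1 scores and a gradient."""
    rho = spearmanr(np.asarray(gradient, dtype=float), result.axis(0)).statistic
    return float(rho)


def arch_test(result: OrdinationResult, threshold: float = 0.5) -> tuple[bool, float]:
    """Quadratic-curvature arch detector on the first two axes.

    Fits ``axis2 = a * axis1^2 + b * axis1 + c`` by least squares and
    declares an arch when ``|a| * range(axis1)^2 / range(axis2) >
    threshold`` — i.e. when the fitted parabola's rise is comparable to the
    observed axis-2 spread.  This is a calibration heuristic, not a formal
    test.
    """
    if result.n_axes < 2:
        return False, 0.0
    x, y = result.axis(0), result.axis(1)
    rx, ry = np.ptp(x), np.ptp(y)
    if rx == 0 or ry == 0:
        return False, 0.0
    a, b, c = np.polyfit(x, y, 2)
    strength = abs(a) * rx**2 / ry
    return bool(strength > threshold), float(strength)


def horseshoe_sign_test(result: OrdinationResult, gradient) -> bool:
    """Sign test for the U/∩ shape of axis 2 along a known gradient.

    True when the two gradient endpoints fall on the same side of the
    axis-2 median while the gradient midpoint falls on the other side —
    the signature of a gradient bent into an arch.
    """
    if result.n_axes < 2:
        return False
    g = np.asarray(gradient, dtype=float)
    y = result.axis(1)
    lo, hi = np.argmin(g), np.argmax(g)
    mid = np.argmin(np.abs(g - np.median(g)))
    med = np.median(y)
    side = np.sign(y - med)
    return bool(side[lo] == side[hi] and side[mid] != side[lo] and side[lo] != 0)
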