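"""Multivariate cluster-separation statistics for photonic feature tables.

PCA (standardised by default, since lifetimes in ns and intensities in
counts are incommensurate) visualises per-image feature vectors; group
separation in score space is quantified classically:

* 99% covariance error ellipses per group, with semi-axes
  ``sqrt(eigenvalue * chi2_2.ppf(level))`` along the covariance
  eigenvectors;
* Mahalanobis distance between group centroids under the pooled
  covariance;
* the two-sample Hotelling T^2 statistic,
  ``T2 = n1*n2/(n1+n2) * D^2``, converted to an F statistic
  ``F = T2 * (n1+n2-p-1) / (p*(n1+n2-2))`` with (p, n1+n2-p-1) degrees
  of freedom, reported alongside the critical F at the chosen alpha and
  the p-value;
* an optional UMAP embedding (thin wrapper around umap-learn, seeded
  for reproducibility).

``pairwise_group_report`` tabulates all five statistics for every
unordered pair of groups — by default on the first two PCA scores,
matching the plotted ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PcaModel",
    "ConfidenceEllipse",
    "ClusterSeparation",
    "MultivariateError",
    "fit_pca",
    "transform",
    "covariance_ellipse",
    "mahalanobis_distance",
    "hotelling_t2",
    "umap_embed",
    "pairwise_group_report",
]


class MultivariateError(ValueError):
    """Raised for degenerate multivariate inputs."""


@dataclass(frozen=True)
class PcaModel:
    """Fitted PCA: means/scales, orthonormal loadings, scores."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (k, p) rows are loading vectors
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n, k)
    standardized: bool


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Covariance error ellipse of a 2-D score cloud."""

    centre: np.ndarray
    semi_axes: np.ndarray  # descending
    angle_rad: float  # orientation of the major axis
    level: float
    degenerate: bool


@dataclass(frozen=True)
class ClusterSeparation:
    """Separation statistics for one unordered pair of groups."""

    group1: str
    group2: str
    n1: int
    n2: int
    p: int
    mahalanobis: float
    t2: float
    f_value: float
    f_critical: float
    p_value: float
    alpha: float
    significant: bool


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(
    X: np.ndarray | pd.DataFrame,
    n_components: int | None = None,
    standardize: bool = True,
) -> PcaModel:
    """PCA of an observations x features matrix.

    Deterministic up to component sign; signs are fixed so the
    largest-magnitude loading of each component is positive.  With
    ``standardize`` the features are z-scored first (constant features
    are rejected, as they cannot be scaled).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise MultivariateError("need a 2-D matrix with >= 3 observations")
    if np.any(~np.isfinite(X)):
        raise MultivariateError("input contains missing/non-finite values")
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = list(np.flatnonzero(scale == 0))
            raise MultivariateError(f"constant feature(s) at column(s) {bad}")
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    components = pca.components_.copy()
    for k in range(components.shape[0]):  # sign convention
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
    return PcaModel(
        mean=mean, scale=scale, components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=scores, standardized=standardize,
    )


def transform(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project new observations onto a fitted PCA."""
    Z = (np.asarray(X, dtype=float) - model.mean) / model.scale
    return Z @ model.components.T


# ---------------------------------------------------------------------------
# confidence ellipses
# ---------------------------------------------------------------------------

def covariance_ellipse(
    scores: np.ndarray, level: float = 0.99
) -> ConfidenceEllipse:
    """Covariance error ellipse of 2-D scores at the given confidence level.

    Semi-axes are ``sqrt(eigenvalue * q)`` with ``q`` the chi-squared
    quantile with 2 degrees of freedom at ``level``; the orientation is
    the major-axis eigenvector.  Collinear score clouds give a flagged
    degenerate ellipse instead of an error.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise MultivariateError("scores must be an (n, 2) array")
    if scores.shape[0] < 3:
        raise MultivariateError("need >= 3 points for a covariance ellipse")
    if not 0.0 < level < 1.0:
        raise MultivariateError("level must lie in (0, 1)")
    centre = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
    q = stats.chi2.ppf(level, df=2)
    semi_axes = np.sqrt(np.maximum(evals, 0.0) * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(
        centre=centre, semi_axes=semi_axes, angle_rad=angle,
        level=level, degenerate=degenerate,
    )


def ellipse_contains(ellipse: ConfidenceEllipse, points: np.ndarray) -> np.ndarray:
    """Boolean membership of points in the ellipse (used for coverage checks)."""
    pts = np.asarray(points, dtype=float) - ellipse.centre
    c, s = np.cos(ellipse.angle_rad), np.sin(ellipse.angle_rad)
    R = np.array([[c, s], [-s, c]])
    local = pts @ R.T
    a, b = ellipse.semi_axes
    return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# Mahalanobis / Hotelling
# ---------------------------------------------------------------------------

def _pooled_cov(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    n1, n2 = g1.shape[0], g2.shape[0]
    s1 = np.cov(g1, rowvar=False, ddof=1)
    s2 = np.cov(g2, rowvar=False, ddof=1)
    return ((n1 - 1) * np.atleast_2d(s1) + (n2 - 1) * np.atleast_2d(s2)) / (
        n1 + n2 - 2
    )


def _solve_spd(S: np.ndarray, d: np.ndarray, feature_names=None) -> np.ndarray:
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        var = np.diag(S)
        bad = list(np.flatnonzero(var <= 1e-12 * max(var.max(), 1.0)))
        if feature_names is not None:
            bad = [feature_names[i] for i in bad]
        raise MultivariateError(
            f"pooled covariance is singular (near-constant features: {bad})"
        ) from None
    return np.linalg.solve(L.T, np.linalg.solve(L, d))


def mahalanobis_distance(
    group1: np.ndarray,
    group2: np.ndarray,
    covariance: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> float:
    """Pooled-covariance Mahalanobis distance between two group centroids.

    ``sqrt((m1 - m2)' S^-1 (m1 - m2))`` with S the pooled sample
    covariance unless an explicit ``covariance`` is supplied.  Symmetric
    in the groups and invariant under common invertible affine maps.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[1] != g2.shape[1]:
        raise MultivariateError("groups must share the feature dimension")
    p = g1.shape[1]
    if covariance is None:
        if g1.shape[0] + g2.shape[0] - 2 <= p:
            raise MultivariateError(
                f"n1+n2-2 must exceed p={p} for a pooled covariance"
            )
        covariance = _pooled_cov(g1, g2)
    d = g1.mean(axis=0) - g2.mean(axis=0)
    sol = _solve_spd(np.atleast_2d(covariance), d, feature_names)
    return float(np.sqrt(d @ sol))


def hotelling_t2(
    group1: np.ndarray,
    group2: np.ndarray,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("group1", "group2"),
    feature_names: Sequence[str] | None = None,
) -> ClusterSeparation:
    """Two-sample Hotelling T^2 test of equal group means.

    T^2 = n1*n2/(n1+n2) * D_Mahalanobis^2; under the null (equal means,
    common covariance) F = T^2 * (n1+n2-p-1) / (p*(n1+n2-2)) follows an
    F distribution with (p, n1+n2-p-1) degrees of freedom.  The pair is
    significant iff F exceeds the critical F at ``alpha`` (equivalently
    p-value < alpha).
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2, p = g1.shape[0], g2.shape[0], g1.shape[1]
    if n1 + n2 - p - 1 <= 0:
        raise MultivariateError("too few observations for the F conversion")
    D = mahalanobis_distance(g1, g2, feature_names=feature_names)
    t2 = n1 * n2 / (n1 + n2) * D**2
    f_value = t2 * (n1 + n2 - p - 1) / (p * (n1 + n2 - 2))
    dfn, dfd = p, n1 + n2 - p - 1
    p_value = float(stats.f.sf(f_value, dfn, dfd))
    f_critical = float(stats.f.ppf(1.0 - alpha, dfn, dfd))
    return ClusterSeparation(
        group1=labels[0], group2=labels[1], n1=n1, n2=n2, p=p,
        mahalanobis=D, t2=float(t2), f_value=float(f_value),
        f_critical=f_critical, p_value=p_value, alpha=alpha,
        significant=bool(f_value > f_critical),
    )


# ---------------------------------------------------------------------------
# UMAP wrapper
# ---------------------------------------------------------------------------

def umap_embed(
    X: np.ndarray | pd.DataFrame,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
) -> np.ndarray:
    """2-D UMAP embedding (thin, seeded wrapper around umap-learn)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise MultivariateError(
            f"need >= n_neighbors+1 = {n_neighbors + 1} observations"
        )
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X))


# ---------------------------------------------------------------------------
# pairwise report
# ---------------------------------------------------------------------------

def pairwise_group_report(
    features: pd.DataFrame,
    feature_cols: Sequence[str],
    group_col: str = "group",
    alpha: float = 0.05,
    space: str = "pca",
    n_components: int = 2,
    standardize: bool = True,
) -> pd.DataFrame:
    """Separation statistics for every unordered pair of groups.

    ``space="pca"`` (default) tests on the first ``n_components`` PCA
    scores of the jointly fitted, standardised feature matrix — the
    space in which the confidence ellipses are drawn; ``space="raw"``
    tests on the features directly.  Groups with fewer than 3
    observations are flagged and skipped, not dropped silently.
    """
    if space not in ("pca", "raw"):
        raise MultivariateError("space must be 'pca' or 'raw'")
    groups = list(dict.fromkeys(features[group_col]))
    if len(groups) < 2:
        raise MultivariateError("need >= 2 groups")
    X = features.loc[:, list(feature_cols)].to_numpy(dtype=float)
    names = list(feature_cols)
    if space == "pca":
        model = fit_pca(X, n_components=n_components, standardize=standardize)
        X = model.scores
        names = [f"PC{i + 1}" for i in range(X.shape[1])]
    labels = np.asarray(features[group_col])
    rows: list[dict] = []
    for a, b in combinations(groups, 2):
        ga, gb = X[labels == a], X[labels == b]
        base = {"group1": a, "group2": b, "n1": ga.shape[0], "n2": gb.shape[0],
                "p": X.shape[1]}
        if ga.shape[0] < 3 or gb.shape[0] < 3:
            rows.append({**base, "mahalanobis": np.nan, "t2": np.nan,
                         "f_value": np.nan, "f_critical": np.nan,
                         "p_value": np.nan, "significant": None,
                         "note": "skipped: group with n < 3"})
            continue
        sep = hotelling_t2(ga, gb, alpha=alpha, labels=(str(a), str(b)),
                           feature_names=names)
        rows.append({**base, "mahalanobis": sep.mahalanobis, "t2": sep.t2,
                     "f_value": sep.f_value, "f_critical": sep.f_critical,
                     "p_value": sep.p_value, "significant": sep.significant,
                     "note": ""})
    return pd.DataFrame(rows)
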