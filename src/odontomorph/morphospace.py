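"""Morphospace construction and two-group testing of outline shape.

The analysis chain mirrors standard outline morphometrics practice: PCA of
the normalized Fourier coefficients (covariance matrix — all coefficients
share units after size normalization), retention of the leading axes that
jointly explain at least 95% of variance, a column-wise rank transform of the
retained coordinates (the scores are generally neither normal nor
homoscedastic), and a two-group Wilks-lambda MANOVA using the exact
Wilks-to-F transform, which for two groups coincides with Hotelling's T².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from odontomorph.dataio import ClosedOutline, DomainError
from odontomorph.efa import (
    DEFAULT_HARMONICS,
    EFACoefficients,
    ShapeVariableMatrix,
    build_variable_matrix,
    eft_forward,
    eft_inverse,
    eft_normalize,
    resample_equal_arclength,
)


@dataclass(frozen=True)
class PCAResult:
    """Principal components of a shape-variable matrix.

    ``scores`` is specimens x components, ``loadings`` variables x
    components, ``mean`` the variable means used for centering. Component
    signs are fixed by forcing each component's largest-magnitude loading
    positive, so results are deterministic.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.scores.shape[1])


@dataclass(frozen=True)
class ManovaResult:
    """Two-group Wilks-lambda MANOVA summary."""

    wilks_lambda: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    n_axes_used: int


def pca(matrix: ShapeVariableMatrix | np.ndarray) -> PCAResult:
    """Covariance-matrix PCA (variables are not standardized).

    All min(n - 1, p) components are kept, so the explained fractions sum
    to one and reconstruction from all components reproduces the centered
    data.
    """
    X = matrix.X.to_numpy() if isinstance(matrix, ShapeVariableMatrix) else np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise DomainError("PCA needs at least 3 specimens")
    if not np.all(np.isfinite(X)):
        raise DomainError("non-finite values in shape-variable matrix")
    centered = X - X.mean(axis=0)
    if float(np.abs(centered).max(initial=0.0)) == 0.0:
        raise DomainError("constant matrix has no principal components")
    model = _SKPCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    model.fit(X)
    loadings = model.components_.T.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    # project explicitly so identical specimens get identical score rows
    scores = centered @ loadings
    frac = model.explained_variance_ratio_
    return PCAResult(scores=scores, loadings=loadings,
                     explained_fraction=np.asarray(frac, float),
                     mean=np.asarray(model.mean_, float))


def retain_axes_95(explained_fraction: Sequence[float], threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained fraction reaches ``threshold``."""
    frac = np.asarray(explained_fraction, dtype=float)
    if frac.size == 0:
        raise DomainError("empty explained-fraction sequence")
    cum = np.cumsum(frac)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else int(frac.size)


def rank_transform(scores: np.ndarray) -> np.ndarray:
    """Column-wise ranks (1-based, midranks for ties).

    Ranking makes the downstream MANOVA invariant to any strictly monotone
    per-column distortion of the scores.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return np.apply_along_axis(stats.rankdata, 0, arr)


def wilks_manova(scores: np.ndarray, groups: Sequence[str]) -> ManovaResult:
    """Two-group MANOVA via Wilks' lambda and its exact F transform.

    Lambda = det(W) / det(W + B) from the within- and between-group
    cross-product matrices; for two groups
    F = ((1 - Lambda) / Lambda) * ((N - p - 1) / p) with df1 = p and
    df2 = N - p - 1 exactly.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise DomainError(f"exactly two groups required, got {uniq.size}")
    N, p = X.shape
    if N != labels.size:
        raise DomainError("one group label per specimen required")
    for g in uniq:
        if np.sum(labels == g) < 2:
            raise DomainError("each group needs at least 2 specimens")
    df2 = N - p - 1
    if df2 < 1:
        raise DomainError(f"N - p - 1 = {df2} < 1; retain fewer axes")
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in uniq:
        sub = X[labels == g]
        centered = sub - sub.mean(axis=0)
        W += centered.T @ centered
        dm = (sub.mean(axis=0) - grand)[:, None]
        B += len(sub) * (dm @ dm.T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise DomainError("singular within-group matrix; retain fewer axes")
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise DomainError("singular total cross-product matrix")
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(lam, 1.0)
    f_stat = wilks_to_f(lam, p, df2)
    p_value = float(stats.f.sf(f_stat, p, df2)) if f_stat > 0 else 1.0
    return ManovaResult(wilks_lambda=lam, f_statistic=f_stat, df1=p, df2=df2,
                        p_value=p_value, n_axes_used=p)


def wilks_to_f(lam: float, df1: int, df2: int) -> float:
    """The exact two-group Wilks-to-F transform F = ((1-L)/L) * (df2/df1)."""
    if not 0.0 < lam <= 1.0:
        raise DomainError("Wilks lambda must lie in (0, 1]")
    return float((1.0 - lam) / lam * (df2 / df1))


def extreme_outlines(
    pca_result: PCAResult,
    axis: int,
    coeff_template: EFACoefficients,
    multiplier: float = 2.0,
    n_points: int = 128,
) -> tuple:
    """Reconstruct outlines at mean -/+ multiplier * sd along one component.

    ``coeff_template`` supplies the first-harmonic coefficients and perimeter
    (the PCA variables only cover harmonics 2..H). Returns the (negative,
    positive) extreme :class:`ClosedOutline` pair.
    """
    sd = float(np.std(pca_result.scores[:, axis], ddof=1))
    loading = pca_result.loadings[:, axis]
    outlines = []
    for sign in (-1.0, 1.0):
        vec = pca_result.mean + sign * multiplier * sd * loading
        harmonics = np.vstack([coeff_template.harmonics[0], vec.reshape(-1, 4)])
        coeffs = EFACoefficients(harmonics, perimeter=coeff_template.perimeter,
                                 center=coeff_template.center,
                                 normalized=coeff_template.normalized)
        outlines.append(eft_inverse(coeffs, n_points=n_points))
    return tuple(outlines)


@dataclass(frozen=True)
class OutlinePipelineConfig:
    """Settings of the end-to-end outline analysis."""

    n_points: int = 64
    n_harmonics: int | None = None          # default per tooth class (9 / 5)
    variance_threshold: float = 0.95
    average_sides: bool = True              # average outlines sharing a label
    extreme_axis: int | None = None         # default: most discriminant axis
    extreme_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise DomainError("variance threshold must lie in (0, 1]")
        if self.n_harmonics is not None and self.n_harmonics < 2:
            raise DomainError("need at least two harmonics")


@dataclass(frozen=True)
class OutlinePipelineResult:
    pca: PCAResult
    manova: ManovaResult
    matrix: ShapeVariableMatrix
    extremes: tuple
    extreme_axis: int
    n_axes_retained: int
    mean_coeffs: EFACoefficients = field(repr=False, default=None)


def _most_discriminant_axis(scores: np.ndarray, groups: np.ndarray, k: int) -> int:
    uniq = np.unique(groups)
    best, best_d = 0, -1.0
    for axis in range(k):
        x0 = scores[groups == uniq[0], axis]
        x1 = scores[groups == uniq[1], axis]
        pooled = np.sqrt((np.var(x0, ddof=1) + np.var(x1, ddof=1)) / 2.0)
        d = abs(x0.mean() - x1.mean()) / pooled if pooled > 0 else 0.0
        if d > best_d:
            best, best_d = axis, d
    return best


def outline_pipeline(
    outlines: Sequence[ClosedOutline],
    tooth_class: str = "M1_upper",
    config: OutlinePipelineConfig | None = None,
) -> OutlinePipelineResult:
    """Resample -> EFT -> normalize -> PCA -> 95% axes -> ranks -> MANOVA.

    Outlines must carry cohort labels ("WT"/"mutant"); with
    ``average_sides`` outlines sharing a specimen label are averaged in
    normalized-coefficient space so each animal contributes one observation.
    """
    config = config or OutlinePipelineConfig()
    if len(outlines) < 6:
        raise DomainError("need at least 6 outlines for a two-group analysis")
    H = config.n_harmonics or DEFAULT_HARMONICS.get(tooth_class, 9)
    coeff_rows, labels, groups, perims = [], [], [], []
    for i, outline in enumerate(outlines):
        resampled = resample_equal_arclength(outline, config.n_points)
        coeffs = eft_normalize(eft_forward(resampled, H))
        coeff_rows.append(coeffs.harmonics)
        labels.append(outline.label or f"spec{i:03d}")
        groups.append(outline.cohort)
        perims.append(coeffs.perimeter)
    if config.average_sides:
        merged: dict = {}
        for lab, grp, arr, per in zip(labels, groups, coeff_rows, perims):
            merged.setdefault(lab, {"group": grp, "arrs": [], "perims": []})
            if merged[lab]["group"] != grp:
                raise DomainError(f"label {lab!r} appears in both cohorts")
            merged[lab]["arrs"].append(arr)
            merged[lab]["perims"].append(per)
        labels = list(merged)
        groups = [merged[lab]["group"] for lab in labels]
        coeff_rows = [np.mean(merged[lab]["arrs"], axis=0) for lab in labels]
        perims = [float(np.mean(merged[lab]["perims"])) for lab in labels]
    coeff_sets = [
        EFACoefficients(arr, perimeter=per, normalized=True)
        for arr, per in zip(coeff_rows, perims)
    ]
    matrix = build_variable_matrix(coeff_sets, labels, groups, tooth_class=tooth_class)
    pca_result = pca(matrix)
    k95 = retain_axes_95(pca_result.explained_fraction, config.variance_threshold)
    # the exact F transform requires df2 = N - 1 - k >= 1
    k = min(k95, len(labels) - 2)
    ranked = rank_transform(pca_result.scores[:, :k])
    manova = wilks_manova(ranked, groups)
    grp_arr = np.asarray(groups)
    axis = (config.extreme_axis if config.extreme_axis is not None
            else _most_discriminant_axis(pca_result.scores, grp_arr, k))
    mean_coeffs = EFACoefficients(np.mean([c.harmonics for c in coeff_sets], axis=0),
                                  perimeter=float(np.mean(perims)), normalized=True)
    extremes = extreme_outlines(pca_result, axis, mean_coeffs,
                                multiplier=config.extreme_multiplier)
    return OutlinePipelineResult(pca=pca_result, manova=manova, matrix=matrix,
                                 extremes=extremes, extreme_axis=axis,
                                 n_axes_retained=k, mean_coeffs=mean_coeffs)
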