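"""Elliptic Fourier analysis of closed crown outlines.

The forward transform follows the classic chain (polygon) formulation: the
incremental changes in x and y are decomposed as functions of the cumulative
chord length along the outline, each harmonic n contributing four
coefficients (A_n, B_n for x; C_n, D_n for y). The first-harmonic ellipse
drives the normalization for size, orientation and starting point, after
which A1 = 1 and B1 = C1 = 0; the first-harmonic coefficients carry no shape
information and are dropped when building the specimen x variable matrix.

Conventions
-----------
* Outlines are counter-clockwise (enforced by :class:`ClosedOutline`), so the
  normalized D1 is positive and reflection (chirality) is *not* removed:
  mirrored outlines yield different coefficients and left/right sides must be
  reflected explicitly before joint analysis.
* The starting-point phase is defined modulo a half turn; the residual
  ambiguity (which flips the sign of even harmonics) is resolved by choosing
  the lexicographically larger coefficient vector, a deterministic and
  transformation-invariant tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from odontomorph.dataio import ClosedOutline, DomainError

#: harmonic counts retained by default for the two tooth classes
DEFAULT_HARMONICS = {"M1_upper": 9, "M1_lower": 5}


@dataclass(frozen=True)
class EFACoefficients:
    """Per-harmonic (A_n, B_n, C_n, D_n) quadruples for one outline.

    ``harmonics`` has shape (H, 4); ``perimeter`` is the outline length T in
    mm; ``center`` holds the DC terms (A0, C0) so outlines can be rebuilt in
    place. ``normalized`` marks coefficients standardized for size,
    orientation and start point.
    """

    harmonics: np.ndarray
    perimeter: float
    center: tuple = (0.0, 0.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.harmonics, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise DomainError("harmonics must be an (H >= 1, 4) array")
        if not np.all(np.isfinite(arr)):
            raise DomainError("non-finite Fourier coefficient")
        object.__setattr__(self, "harmonics", arr)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def n_harmonics(self) -> int:
        return int(self.harmonics.shape[0])


def _closed_diffs(outline: ClosedOutline):
    closed = np.vstack([outline.points, outline.points[:1]])
    deltas = np.diff(closed, axis=0)
    seg = np.linalg.norm(deltas, axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    return closed, deltas, seg, t


def resample_equal_arclength(outline: ClosedOutline, n_points: int = 64) -> ClosedOutline:
    """Resample the closed polygonal outline at equal arc-length steps.

    The first output point coincides with the first input point; successive
    points sit at arc positions k * T / n_points along the polygon.
    """
    if n_points < 8:
        raise DomainError("n_points must be >= 8")
    closed, _, _, t = _closed_diffs(outline)
    total = t[-1]
    if not total > 0:
        raise DomainError("degenerate outline with zero perimeter")
    s = total * np.arange(n_points) / n_points
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    return ClosedOutline(np.column_stack([x, y]), label=outline.label,
                         tooth_class=outline.tooth_class, cohort=outline.cohort)


def eft_forward(outline: ClosedOutline, n_harmonics: int) -> EFACoefficients:
    """Elliptic Fourier coefficients of a closed polygon (chain formulation).

    ``n_harmonics`` must satisfy 1 <= H <= n_points / 2 (the Nyquist bound of
    the sampled outline).
    """
    n_pts = outline.n_points
    if n_harmonics < 1:
        raise DomainError("need at least one harmonic")
    if n_harmonics > n_pts // 2:
        raise DomainError(
            f"{n_harmonics} harmonics exceed the Nyquist bound ({n_pts // 2}) "
            f"for a {n_pts}-point outline")
    closed, deltas, seg, t = _closed_diffs(outline)
    total = t[-1]
    if not total > 0:
        raise DomainError("degenerate outline with zero perimeter")
    dx, dy = deltas[:, 0], deltas[:, 1]
    n = np.arange(1, n_harmonics + 1)[:, None]           # (H, 1)
    phi = 2.0 * np.pi * n * t[None, :] / total           # (H, K+1)
    dcos = np.diff(np.cos(phi), axis=1)
    dsin = np.diff(np.sin(phi), axis=1)
    const = total / (2.0 * (n.ravel() ** 2) * np.pi ** 2)
    a = const * ((dx / seg)[None, :] * dcos).sum(axis=1)
    b = const * ((dx / seg)[None, :] * dsin).sum(axis=1)
    c = const * ((dy / seg)[None, :] * dcos).sum(axis=1)
    d = const * ((dy / seg)[None, :] * dsin).sum(axis=1)
    # DC terms: mean of the piecewise-linear x(t), y(t)
    a0 = float(np.sum(seg * (closed[:-1, 0] + closed[1:, 0]) / 2.0) / total)
    c0 = float(np.sum(seg * (closed[:-1, 1] + closed[1:, 1]) / 2.0) / total)
    return EFACoefficients(np.column_stack([a, b, c, d]), perimeter=float(total),
                           center=(a0, c0), normalized=False)


def _rotated(harmonics: np.ndarray, theta: float, psi: float, scale: float) -> np.ndarray:
    """Apply start-phase shift ``theta``, orientation ``psi`` and ``1/scale``."""
    out = np.empty_like(harmonics)
    left = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for idx in range(harmonics.shape[0]):
        n = idx + 1
        right = np.array([[np.cos(n * theta), -np.sin(n * theta)],
                          [np.sin(n * theta), np.cos(n * theta)]])
        mat = harmonics[idx].reshape(2, 2)
        out[idx] = (left @ mat @ right).ravel() / scale
    return out


def eft_normalize(coeffs: EFACoefficients) -> EFACoefficients:
    """Standardize coefficients for size, orientation and starting point.

    The outline is scaled by the first-harmonic semi-major axis, rotated so
    that axis lies along +x, and the start point is phase-shifted onto it.
    Two outlines differing only by rotation, uniform scaling, translation and
    start point then share coefficients to within numerical error.
    """
    if coeffs.normalized:
        return coeffs
    a1, b1, c1, d1 = coeffs.harmonics[0]
    if a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1 < 1e-30:
        raise DomainError("zero first-harmonic magnitude; cannot normalize")
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1)
    candidates = []
    for th in (theta, theta + np.pi):
        ct, st = np.cos(th), np.sin(th)
        a_star = a1 * ct + b1 * st
        c_star = c1 * ct + d1 * st
        scale = float(np.hypot(a_star, c_star))
        if scale < 1e-30:
            raise DomainError("degenerate first-harmonic ellipse")
        psi = float(np.arctan2(c_star, a_star))
        candidates.append(_rotated(coeffs.harmonics, th, psi, scale))
    # the start phase is defined modulo pi; the two candidates differ by a
    # sign flip of the even harmonics -- break the tie lexicographically
    flat0, flat1 = candidates[0].ravel(), candidates[1].ravel()
    diff = flat0 - flat1
    nz = np.nonzero(np.abs(diff) > 1e-9)[0]
    chosen = candidates[0] if (len(nz) == 0 or diff[nz[0]] > 0) else candidates[1]
    return EFACoefficients(chosen, perimeter=coeffs.perimeter, center=(0.0, 0.0),
                           normalized=True)


def eft_inverse(coeffs: EFACoefficients, n_points: int = 64) -> ClosedOutline:
    """Truncated Fourier synthesis of the outline at ``n_points`` samples."""
    if n_points < 8:
        raise DomainError("n_points must be >= 8")
    H = coeffs.n_harmonics
    t = np.arange(n_points) / n_points                   # t / T
    n = np.arange(1, H + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(phi), np.sin(phi)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.center[0] + a @ cos + b @ sin
    y = coeffs.center[1] + c @ cos + d @ sin
    return ClosedOutline(np.column_stack([x, y]))


@dataclass(frozen=True)
class ShapeVariableMatrix:
    """Specimens x Fourier-coefficient matrix for multivariate analysis.

    Columns are A2..D_H (the first harmonic is excluded); ``groups`` holds
    the per-specimen cohort labels.
    """

    X: pd.DataFrame
    groups: Sequence[str]
    tooth_class: str = "M1_upper"

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.X):
            raise DomainError("one group label per specimen required")
        if self.X.isna().any().any():
            raise DomainError("missing cells in shape-variable matrix")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def n_variables(self) -> int:
        return int(self.X.shape[1])


def build_variable_matrix(
    coeff_sets: Sequence[EFACoefficients],
    labels: Sequence[str],
    groups: Sequence[str],
    tooth_class: str = "M1_upper",
) -> ShapeVariableMatrix:
    """Stack normalized coefficients into the analysis matrix, dropping A1-D1.

    With H harmonics the matrix has 4 * (H - 1) columns: 32 for the upper
    first molar at H = 9, 16 for the lower at H = 5.
    """
    if not coeff_sets:
        raise DomainError("no coefficient sets supplied")
    if not (len(coeff_sets) == len(labels) == len(groups)):
        raise DomainError("coeff_sets, labels and groups must have equal length")
    counts = {c.n_harmonics for c in coeff_sets}
    if len(counts) != 1:
        raise DomainError(f"mixed harmonic counts: {sorted(counts)}")
    H = counts.pop()
    if H < 2:
        raise DomainError("need at least two harmonics (the first is dropped)")
    columns = [f"{letter}{n}" for n in range(2, H + 1) for letter in "ABCD"]
    rows = [c.harmonics[1:].ravel() for c in coeff_sets]
    frame = pd.DataFrame(rows, index=list(labels), columns=columns)
    return ShapeVariableMatrix(frame, groups=list(groups), tooth_class=tooth_class)
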