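"""Synthetic crown outlines, 3D crown surfaces, morphotype records and count
matrices with the statistical structure the downstream analyses assume.

Every generator is a pure function of its parameters and a seed; no global
random state is touched. Outlines are star-shaped radius functions (an
ellipse plus Gaussian cusp bumps), which guarantees simple closed curves and
is adequate for cusp-position effects. Crowns are dome-plus-Gaussian-cusp
height fields triangulated on a regular grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from odontomorph.dataio import (
    ClosedOutline,
    DomainError,
    LandmarkSet,
    MorphotypeTable,
    TriangleMesh,
)


def _wrapped_angle(theta: np.ndarray, center: float) -> np.ndarray:
    """Signed angular distance from ``center``, wrapped into (-pi, pi]."""
    return np.angle(np.exp(1j * (theta - center)))


# --------------------------------------------------------------------------
# outlines
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CuspBump:
    """One cusp expressed as a Gaussian bump on the outline's radius function."""

    theta: float          # angular position, radians
    amplitude: float      # radial height, mm
    width: float          # angular Gaussian sigma, radians

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise DomainError("cusp amplitude must be >= 0")
        if not self.width > 0:
            raise DomainError("cusp width must be > 0")


# A plausible upper first molar: about 2.2 mm long and 1.45 mm wide, with an
# anterior cusp (index 0, the one the genotype effect targets) and a ring of
# accessory cusps. Amplitudes are ~5-10% of the crown radius, commensurate
# with the subtle cusp-position differences under study.
_DEFAULT_CUSPS = (
    CuspBump(theta=0.0, amplitude=0.12, width=0.30),
    CuspBump(theta=1.3, amplitude=0.08, width=0.35),
    CuspBump(theta=2.4, amplitude=0.10, width=0.30),
    CuspBump(theta=3.6, amplitude=0.09, width=0.35),
    CuspBump(theta=4.8, amplitude=0.08, width=0.30),
)


@dataclass(frozen=True)
class OutlineModelParams:
    """Parameters of the star-shaped outline generator.

    ``delta_theta_c1`` and ``amp_scale_c1`` are the genotype effect: for the
    mutant cohort the first cusp (index 0) is shifted by ``delta_theta_c1``
    radians and its amplitude multiplied by ``amp_scale_c1``, mimicking the
    more linguo-distal first-cusp position of the mutant molar.
    """

    a: float = 1.1                       # semi-axis, mm
    b: float = 0.72                      # semi-axis, mm
    cusps: Sequence[CuspBump] = _DEFAULT_CUSPS
    delta_theta_c1: float = 0.0
    amp_scale_c1: float = 1.0
    noise_sd: float = 0.01               # radial noise, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise DomainError("semi-axes must be > 0")
        if self.noise_sd < 0:
            raise DomainError("noise sd must be >= 0")
        object.__setattr__(self, "cusps", tuple(self.cusps))

    def with_genotype_effect(self) -> "OutlineModelParams":
        """Return the mutant-cohort parameters (cusp 1 shifted and rescaled)."""
        if not self.cusps:
            return self
        c1 = self.cusps[0]
        c1 = CuspBump(c1.theta + self.delta_theta_c1,
                      c1.amplitude * self.amp_scale_c1, c1.width)
        return replace(self, cusps=(c1,) + tuple(self.cusps[1:]))


def _radius(params: OutlineModelParams, theta: np.ndarray) -> np.ndarray:
    a, b = params.a, params.b
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    for cusp in params.cusps:
        d = _wrapped_angle(theta, cusp.theta)
        r = r + cusp.amplitude * np.exp(-0.5 * (d / cusp.width) ** 2)
    return r


def simulate_outline(
    params: OutlineModelParams,
    n_points: int = 64,
    label: str = "",
    tooth_class: str = "M1_upper",
    cohort: str = "WT",
) -> ClosedOutline:
    """Sample r(theta) = ellipse + cusp bumps + radial noise at ``n_points``
    equally spaced angles."""
    if n_points < 16:
        raise DomainError("n_points must be >= 16")
    rng = np.random.default_rng(params.seed)
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    r = _radius(params, theta)
    if params.noise_sd > 0:
        r = r + rng.normal(0.0, params.noise_sd, size=n_points)
    if np.any(r <= 0):
        raise DomainError("outline radius became non-positive; reduce noise or amplitudes")
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return ClosedOutline(pts, label=label, tooth_class=tooth_class, cohort=cohort)


def simulate_outline_cohorts(
    params: OutlineModelParams,
    n_wt: int,
    n_mut: int,
    n_points: int = 64,
    seed: int | None = None,
) -> list:
    """Simulate a WT and a mutant cohort; the mutant cohort carries the
    genotype effect. Per-specimen seeds are spawned from ``seed`` (defaults
    to ``params.seed``) so the whole dataset is reproducible."""
    base = params.seed if seed is None else seed
    seeds = np.random.SeedSequence(base).generate_state(n_wt + n_mut) >> 1
    mut_params = params.with_genotype_effect()
    outlines = []
    for i in range(n_wt):
        p = replace(params, seed=int(seeds[i]))
        outlines.append(simulate_outline(p, n_points, label=f"WT{i:03d}", cohort="WT"))
    for j in range(n_mut):
        p = replace(mut_params, seed=int(seeds[n_wt + j]))
        outlines.append(simulate_outline(p, n_points, label=f"MUT{j:03d}", cohort="mutant"))
    return outlines


# --------------------------------------------------------------------------
# 3D crowns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CuspPeak:
    """One cusp of the 3D crown model: a Gaussian peak on the dome."""

    center: tuple        # (x, y), mm
    height: float        # mm
    width: float         # Gaussian sigma, mm


@dataclass(frozen=True)
class CrownModelParams:
    """Dome-plus-cusp crown surface on a regular grid.

    z(x, y) = h * max(0, 1 - (x/a)^2 - (y/b)^2) + sum of Gaussian cusps.
    ``cusp_shift`` maps cusp names to (dx, dy) genotype displacements used by
    :func:`simulate_crown_mesh` when ``cohort="mutant"``.
    """

    a: float = 1.1
    b: float = 0.72
    h: float = 0.5
    cusps: Mapping[str, CuspPeak] = field(default_factory=dict)
    cusp_shift: Mapping[str, tuple] = field(default_factory=dict)
    resolution: int = 48        # grid points per axis
    noise_sd: float = 0.0       # vertical noise, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise DomainError("dome height must be > 0")
        if self.resolution < 16:
            raise DomainError("resolution must be >= 16 per axis")
        object.__setattr__(self, "cusps", dict(self.cusps))
        object.__setattr__(self, "cusp_shift", dict(self.cusp_shift))


def default_mouse_crown() -> CrownModelParams:
    """A four-cusp crown with the mouse distal-cusp names (c5, c6, c8, c9)."""
    return CrownModelParams(
        h=0.3,
        cusps={
            "c5": CuspPeak((-0.45, 0.25), 0.35, 0.15),
            "c6": CuspPeak((0.45, 0.25), 0.32, 0.15),
            "c8": CuspPeak((-0.45, -0.25), 0.33, 0.15),
            "c9": CuspPeak((0.45, -0.25), 0.30, 0.15),
        },
        cusp_shift={"c9": (0.2, 0.1)},
    )


def _crown_height(params: CrownModelParams, x: np.ndarray, y: np.ndarray,
                  cusps: Mapping[str, CuspPeak]) -> np.ndarray:
    dome = params.h * np.clip(1.0 - (x / params.a) ** 2 - (y / params.b) ** 2, 0.0, None)
    z = dome
    for cusp in cusps.values():
        d2 = (x - cusp.center[0]) ** 2 + (y - cusp.center[1]) ** 2
        z = z + cusp.height * np.exp(-0.5 * d2 / cusp.width ** 2)
    return z


def _analytic_apex(params: CrownModelParams, cusps: Mapping[str, CuspPeak],
                   name: str) -> np.ndarray:
    """Apex of the full height function near the named cusp (the dome slope
    pulls the maximum slightly off the Gaussian center)."""
    cusp = cusps[name]

    def neg_z(p):
        return -float(_crown_height(params, np.array(p[0]), np.array(p[1]), cusps))

    res = minimize(neg_z, x0=np.asarray(cusp.center, dtype=float), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    x, y = res.x
    z = float(_crown_height(params, np.array(x), np.array(y), cusps))
    return np.array([x, y, z])


def simulate_crown_mesh(
    params: CrownModelParams, cohort: str = "WT"
) -> tuple:
    """Triangulate the crown height field on its grid.

    Returns ``(TriangleMesh, LandmarkSet)``; landmarks sit at the analytic
    apices of the named cusps. For ``cohort="mutant"`` the cusp centers
    listed in ``params.cusp_shift`` are displaced first.
    """
    cusps = dict(params.cusps)
    if cohort == "mutant":
        for name, (dx, dy) in params.cusp_shift.items():
            if name in cusps:
                c = cusps[name]
                cusps[name] = CuspPeak((c.center[0] + dx, c.center[1] + dy),
                                       c.height, c.width)
    n = params.resolution
    margin = 1.15
    x = np.linspace(-params.a * margin, params.a * margin, n)
    y = np.linspace(-params.b * margin, params.b * margin, n)
    xx, yy = np.meshgrid(x, y)
    zz = _crown_height(params, xx, yy, cusps)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        zz = zz + rng.normal(0.0, params.noise_sd, size=zz.shape)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a00, a01 = idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel()
    a10, a11 = idx[1:, :-1].ravel(), idx[1:, 1:].ravel()
    faces = np.concatenate([
        np.column_stack([a00, a01, a11]),
        np.column_stack([a00, a11, a10]),
    ])
    mesh = TriangleMesh(verts, faces)
    landmarks = LandmarkSet({name: _analytic_apex(params, cusps, name) for name in cusps})
    return mesh, landmarks


# --------------------------------------------------------------------------
# morphotype records
# --------------------------------------------------------------------------

# trait frequencies matching the packaged upper-molar survey
DEFAULT_TRAIT_PROBS = {
    "WT": {"m1_c1c2_profile": 0.0, "m2_spur": 0.0, "m3_c1": 0.0},
    "mutant": {"m1_c1c2_profile": 0.6, "m2_spur": 0.6, "m3_c1": 0.3},
}
# the "variant" state each Bernoulli probability refers to
_VARIANT_STATE = {"m1_c1c2_profile": ("U", "V"), "m2_spur": ("absent", "present"),
                  "m3_c1": ("reduced", "normal")}


def simulate_morphotypes(
    n_wt: int,
    n_mut: int,
    trait_probs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> MorphotypeTable:
    """Draw per-side independent Bernoulli morphotype records.

    ``trait_probs[cohort][trait]`` is the probability of the variant state
    (U-shaped profile / absent spur / reduced c1) on any scored side.
    """
    probs = DEFAULT_TRAIT_PROBS if trait_probs is None else trait_probs
    for cohort_probs in probs.values():
        for p in cohort_probs.values():
            if not 0.0 <= p <= 1.0:
                raise DomainError("trait probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, count, prefix in (("WT", n_wt, "SWT"), ("mutant", n_mut, "SMU")):
        for i in range(count):
            for side in ("right", "left"):
                row = {"specimen": f"{prefix}{i:04d}", "cohort": cohort,
                       "side": side, "abnormal_cusp": ""}
                for trait, (variant, normal) in _VARIANT_STATE.items():
                    p = probs.get(cohort, {}).get(trait, 0.0)
                    row[trait] = variant if rng.random() < p else normal
                rows.append(row)
    columns = ["specimen", "cohort", "side", "m1_c1c2_profile", "m2_spur",
               "m3_c1", "abnormal_cusp"]
    return MorphotypeTable(pd.DataFrame(rows, columns=columns))


# --------------------------------------------------------------------------
# count matrices
# --------------------------------------------------------------------------


def simulate_counts(
    n_genes: int = 2000,
    n_per_group: int = 4,
    nb_mean: float = 100.0,
    nb_dispersion: float = 0.1,
    de_fraction: float = 0.1,
    log2fc: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Negative-binomial count matrix with a spiked-in differential subset.

    Variance follows mean + dispersion * mean^2; as dispersion -> 0 the draws
    approach Poisson. A ``de_fraction`` of genes has its group-B mean
    multiplied by 2**log2fc (alternating sign so both directions occur).

    Returns ``(counts, labels, truth)``: a genes x samples DataFrame, the
    per-sample group labels, and the boolean truth vector of spiked genes.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise DomainError("de_fraction must lie in [0, 1]")
    if nb_dispersion < 0:
        raise DomainError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    n_de = int(round(de_fraction * n_genes))
    truth = np.zeros(n_genes, dtype=bool)
    truth[:n_de] = True
    sign = np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0)
    lfc = np.where(truth, sign * log2fc, 0.0)
    mean_a = np.full(n_genes, float(nb_mean))
    mean_b = mean_a * 2.0 ** lfc

    def draw(mean: np.ndarray) -> np.ndarray:
        mean_mat = np.tile(mean[:, None], (1, n_per_group))
        if nb_dispersion == 0:
            return rng.poisson(mean_mat)
        size = 1.0 / nb_dispersion
        p = size / (size + mean_mat)
        return rng.negative_binomial(size, p)

    counts = np.hstack([draw(mean_a), draw(mean_b)])
    samples = [f"A{i+1}" for i in range(n_per_group)] + [f"B{i+1}" for i in range(n_per_group)]
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    frame = pd.DataFrame(counts, index=[f"gene{i:05d}" for i in range(n_genes)],
                         columns=samples)
    return frame, labels, truth
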