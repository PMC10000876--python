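"""Landmark-guided 3D crown morphing and displacement-field transfer.

The procedure mirrors how a wild-type crown surface is deformed onto its
mutant counterpart and the deformation re-used on a homologous tooth:

1.  height-map scans of a crown are superimposed and averaged into a
    representative surface (:func:`average_surfaces`);
2.  source and target meshes are brought into a common frame by a
    least-squares similarity fit of paired cusp landmarks
    (:func:`align_by_landmarks`), optionally refined by point-to-plane ICP;
3.  every source vertex is paired with a target surface point by casting
    along its normal (nearest-point fallback, graph interpolation for the
    remainder) — :func:`dense_correspondence`;
4.  the per-vertex transformation vectors form a displacement field, pinned
    to zero near the cervical margin (:func:`build_displacement_field`);
5.  the field is applied to the source (:func:`apply_morph`) or transferred
    onto a third mesh via the cusp homology pairing (:func:`transfer_morph`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata
from skimage.registration import optical_flow_ilk, phase_cross_correlation

from odontomorph._geom import SurfaceIndex
from odontomorph.dataio import (
    DomainError,
    HeightMap,
    LandmarkSet,
    OdontomorphError,
    TriangleMesh,
)


class CorrespondenceError(OdontomorphError):
    """Raised when no usable correspondence exists between two meshes."""


class AveragingError(OdontomorphError):
    """Raised when height maps cannot be superimposed for averaging."""


# --------------------------------------------------------------------------
# similarity alignment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidSimilarityTransform:
    """x -> scale * R @ x + t with R a proper rotation and scale > 0."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not self.scale > 0:
            raise DomainError("similarity scale must be > 0")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise DomainError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidSimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Transform direction vectors (rotation and scale, no translation)."""
        return self.scale * np.atleast_2d(vectors) @ self.rotation.T

    def inverse(self) -> "RigidSimilarityTransform":
        Rinv = self.rotation.T
        return RigidSimilarityTransform(
            Rinv, -(Rinv @ self.translation) / self.scale, 1.0 / self.scale)

    def compose(self, other: "RigidSimilarityTransform") -> "RigidSimilarityTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidSimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale)


def _paired_arrays(source: LandmarkSet, target: LandmarkSet,
                   pairing: Mapping[str, str] | None):
    if pairing is None:
        names = [n for n in source.names if n in target.entries]
        pairing = {n: n for n in names}
    pairs = [(s, t) for s, t in pairing.items()
             if s in source.entries and t in target.entries]
    if len(pairs) < 3:
        raise DomainError(f"need at least 3 paired landmarks, got {len(pairs)}")
    src = np.array([source[s] for s, _ in pairs])
    tgt = np.array([target[t] for _, t in pairs])
    return src, tgt


def align_by_landmarks(
    source: LandmarkSet,
    target: LandmarkSet,
    pairing: Mapping[str, str] | None = None,
    allow_scale: bool = True,
) -> RigidSimilarityTransform:
    """Least-squares similarity transform mapping source landmarks onto
    target landmarks (Umeyama closed form).

    ``pairing`` maps source landmark names to target names; by default names
    common to both sets are paired. Collinear landmark configurations are
    rejected.
    """
    src, tgt = _paired_arrays(source, target, pairing)
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    cs, ct = src - mu_s, tgt - mu_t
    var_s = float(np.mean(np.sum(cs ** 2, axis=1)))
    if var_s <= 0:
        raise DomainError("degenerate landmark configuration: coincident points")
    cov = ct.T @ cs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    if D[1] < 1e-12 * max(D[0], 1e-300):
        raise DomainError("degenerate landmark configuration: collinear points")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S) / var_s) if allow_scale else 1.0
    if not scale > 0:
        raise DomainError("degenerate landmark configuration: non-positive scale")
    t = mu_t - scale * R @ mu_s
    return RigidSimilarityTransform(R, t, scale)


def landmark_rms(transform: RigidSimilarityTransform, source: LandmarkSet,
                 target: LandmarkSet, pairing: Mapping[str, str] | None = None) -> float:
    src, tgt = _paired_arrays(source, target, pairing)
    resid = transform.apply(src) - tgt
    return float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))


# --------------------------------------------------------------------------
# ICP refinement
# --------------------------------------------------------------------------


def refine_by_icp(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidSimilarityTransform | None = None,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    max_points: int = 500,
) -> RigidSimilarityTransform:
    """Point-to-plane iterative-closest-point refinement of an alignment.

    The per-iteration RMS point-to-surface distance is non-increasing: an
    update that would raise it is rejected and iteration stops. Scale is
    inherited from ``init`` and not re-estimated.
    """
    transform = init or RigidSimilarityTransform.identity()
    target_tm = target.to_trimesh()
    index = SurfaceIndex(target.vertices, target.faces)
    pts_all = source.vertices
    if len(pts_all) > max_points:
        idx = np.linspace(0, len(pts_all) - 1, max_points).astype(int)
        pts_all = pts_all[idx]

    def rms_of(tr: RigidSimilarityTransform) -> float:
        moved = tr.apply(pts_all)
        _, dist, _ = index.closest_point(moved)
        return float(np.sqrt(np.mean(dist ** 2)))

    best_rms = rms_of(transform)
    for _ in range(max_iterations):
        moved = transform.apply(pts_all)
        closest, _, tri = index.closest_point(moved)
        normals = np.asarray(target_tm.face_normals)[tri]
        resid = np.sum((moved - closest) * normals, axis=1)
        # linearized small-motion solve: rows [p x n, n] @ [omega; t] = -resid
        A = np.hstack([np.cross(moved, normals), normals])
        sol, *_ = np.linalg.lstsq(A, -resid, rcond=None)
        omega, delta_t = sol[:3], sol[3:]
        angle = np.linalg.norm(omega)
        if angle < 1e-15:
            R_step = np.eye(3)
        else:
            axis = omega / angle
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R_step = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        candidate = RigidSimilarityTransform(
            R_step, delta_t, 1.0).compose(transform)
        cand_rms = rms_of(candidate)
        if cand_rms > best_rms + 1e-15:
            break
        improved = best_rms - cand_rms
        transform, best_rms = candidate, cand_rms
        if improved < tolerance:
            break
    return transform


# --------------------------------------------------------------------------
# dense correspondence and displacement fields
# --------------------------------------------------------------------------

KIND_PROJECTED, KIND_CLOSEST, KIND_INTERPOLATED = "projected", "closest", "interpolated"


@dataclass(frozen=True)
class CorrespondenceMap:
    """Per source-vertex match on the target surface.

    ``kind`` is "projected" (normal-ray hit), "closest" (nearest surface
    point within the cutoff) or "interpolated" (filled by graph-neighbor
    relaxation); ``matched`` is True for the first two.
    """

    target_points: np.ndarray
    kind: np.ndarray
    source: TriangleMesh = field(repr=False, default=None)

    @property
    def matched(self) -> np.ndarray:
        return self.kind != KIND_INTERPOLATED


def _vertex_neighbors(mesh: TriangleMesh) -> list:
    neighbors = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    return [np.fromiter(s, dtype=np.int64) for s in neighbors]


def _relax_unmatched(values: np.ndarray, fixed: np.ndarray, neighbors: list,
                     tol: float = 1e-9, max_iter: int = 10000) -> np.ndarray:
    """Jacobi relaxation: free entries become the mean of their neighbors."""
    values = values.copy()
    free = np.nonzero(~fixed)[0]
    for _ in range(max_iter):
        new = values.copy()
        for v in free:
            nb = neighbors[v]
            if nb.size:
                new[v] = values[nb].mean(axis=0)
        change = float(np.max(np.abs(new[free] - values[free]))) if free.size else 0.0
        values = new
        if change < tol:
            break
    return values


def dense_correspondence(
    source: TriangleMesh,
    target: TriangleMesh,
    cutoff: float = 5.0,
) -> CorrespondenceMap:
    """Pair every source vertex with a target-surface point.

    Rays are cast from each source vertex along both directions of its
    vertex normal; the nearest intersection within ``cutoff`` mean source
    edge lengths wins ("projected"). Vertices without a hit fall back to the
    nearest target-surface point within the cutoff ("closest"); the rest are
    "interpolated": their target points are filled by iterative neighbor
    averaging over the source mesh graph until convergence (max change
    < 1e-9).
    """
    src_tm = source.to_trimesh()
    verts = source.vertices
    n = len(verts)
    cutoff_abs = cutoff * source.mean_edge_length()
    normals = np.asarray(src_tm.vertex_normals)

    target_points = verts.copy()
    kind = np.full(n, KIND_INTERPOLATED, dtype=object)

    index = SurfaceIndex(target.vertices, target.faces)
    # one line query covers projection along both +normal and -normal
    hit_points, _, hit = index.line_intersections(verts, normals, max_dist=cutoff_abs)
    target_points[hit] = hit_points[hit]
    kind[hit] = KIND_PROJECTED

    unhit = np.nonzero(kind == KIND_INTERPOLATED)[0]
    if unhit.size:
        closest, dist, _ = index.closest_point(verts[unhit])
        ok = dist <= cutoff_abs
        target_points[unhit[ok]] = closest[ok]
        kind[unhit[ok]] = KIND_CLOSEST

    matched = kind != KIND_INTERPOLATED
    if not matched.any():
        raise CorrespondenceError(
            "no source vertex found a target correspondence within the cutoff; "
            "the meshes do not overlap spatially")
    if (~matched).any():
        neighbors = _vertex_neighbors(source)
        target_points = _relax_unmatched(target_points, matched, neighbors)
    return CorrespondenceMap(target_points=target_points,
                             kind=np.asarray(kind, dtype=object), source=source)


@dataclass(frozen=True)
class DisplacementField:
    """Per source-vertex transformation vectors (mm).

    ``pinned`` marks boundary vertices constrained to zero displacement
    (near the cervical margin, below the functional crown surface).
    """

    vectors: np.ndarray
    pinned: np.ndarray
    source: TriangleMesh = field(repr=False, default=None)

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=float)
        pin = np.asarray(self.pinned, dtype=bool)
        if vec.ndim != 2 or vec.shape[1] != 3 or len(vec) != len(pin):
            raise DomainError("displacement field needs (n, 3) vectors and an n-mask")
        if np.any(np.abs(vec[pin]) > 0):
            raise DomainError("pinned vertices must carry zero displacement")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "pinned", pin)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


def cervical_margin_vertices(mesh: TriangleMesh, height_fraction: float = 0.15) -> np.ndarray:
    """Indices of vertices in the lowest ``height_fraction`` of the crown
    height — the proxy for the cervical-margin boundary band."""
    if not 0.0 <= height_fraction < 1.0:
        raise DomainError("height fraction must lie in [0, 1)")
    z = mesh.vertices[:, 2]
    zmin, zmax = float(z.min()), float(z.max())
    return np.nonzero(z <= zmin + height_fraction * (zmax - zmin))[0]


def build_displacement_field(
    corr: CorrespondenceMap,
    boundary: Sequence[int] | None = None,
) -> DisplacementField:
    """Transformation vectors target_point - source_vertex, with boundary
    vertices pinned to zero and interpolated vertices re-smoothed."""
    source = corr.source
    vectors = corr.target_points - source.vertices
    pinned = np.zeros(len(vectors), dtype=bool)
    if boundary is not None:
        pinned[np.asarray(list(boundary), dtype=int)] = True
        vectors[pinned] = 0.0
    interp = ~corr.matched & ~pinned
    if interp.any():
        neighbors = _vertex_neighbors(source)
        vectors = _relax_unmatched(vectors, ~interp, neighbors)
        vectors[pinned] = 0.0
    return DisplacementField(vectors=vectors, pinned=pinned, source=source)


def apply_morph(mesh: TriangleMesh, field: DisplacementField) -> TriangleMesh:
    """Move every vertex by its displacement vector; topology is unchanged."""
    if len(field.vectors) != mesh.n_vertices:
        raise DomainError("displacement field does not match the mesh")
    return TriangleMesh(mesh.vertices + field.vectors, mesh.faces)


def _barycentric_weights(tri_pts: np.ndarray, pts: np.ndarray) -> np.ndarray:
    v0 = tri_pts[:, 1] - tri_pts[:, 0]
    v1 = tri_pts[:, 2] - tri_pts[:, 0]
    v2 = pts - tri_pts[:, 0]
    d00 = np.sum(v0 * v0, axis=1)
    d01 = np.sum(v0 * v1, axis=1)
    d11 = np.sum(v1 * v1, axis=1)
    d20 = np.sum(v2 * v0, axis=1)
    d21 = np.sum(v2 * v1, axis=1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    return np.clip(np.column_stack([u, v, w]), 0.0, 1.0)


def _sample_field(source: TriangleMesh, vectors: np.ndarray, points: np.ndarray,
                  faces_subset: np.ndarray | None = None):
    """Sample per-vertex vectors at the nearest source-surface points."""
    faces = source.faces if faces_subset is None else source.faces[faces_subset]
    index = SurfaceIndex(source.vertices, faces)
    closest, dist, tri = index.closest_point(points)
    tri_vidx = faces[tri]
    weights = _barycentric_weights(source.vertices[tri_vidx], closest)
    sampled = np.einsum("nk,nkd->nd", weights, vectors[tri_vidx])
    return sampled, dist


def transfer_morph(
    field: DisplacementField,
    source_landmarks: LandmarkSet,
    third_mesh: TriangleMesh,
    third_landmarks: LandmarkSet,
    pairing: Mapping[str, str] | None = None,
    cutoff: float = 5.0,
    mode: str = "global",
) -> TriangleMesh:
    """Carry the source displacement field onto a homologous third mesh.

    The third mesh is aligned into the source frame by the landmark pairing
    (third name -> source name, e.g. protocone -> c5). Each aligned vertex
    samples the field at its nearest source-surface point (barycentric over
    the source triangle); the displacement is divided by the alignment scale
    and rotated back into the third mesh's native frame. Vertices farther
    than ``cutoff`` source mean edge lengths from the source surface stay
    put. ``mode="per_cusp"`` partitions both surfaces by nearest paired
    landmark and samples each region independently.
    """
    if mode not in ("global", "per_cusp"):
        raise DomainError(f"unknown transfer mode {mode!r}")
    source = field.source
    transform = align_by_landmarks(third_landmarks, source_landmarks, pairing)
    aligned = transform.apply(third_mesh.vertices)
    cutoff_abs = cutoff * source.mean_edge_length()

    if mode == "global":
        sampled, dist = _sample_field(source, field.vectors, aligned)
    else:
        if pairing is None:
            pairing = {n: n for n in third_landmarks.names
                       if n in source_landmarks.entries}
        third_names = list(pairing)
        src_lm = np.array([source_landmarks[pairing[n]] for n in third_names])
        # region of each aligned third vertex: nearest paired source landmark
        v_region = np.argmin(np.linalg.norm(
            aligned[:, None, :] - src_lm[None, :, :], axis=2), axis=1)
        centroids = source.vertices[source.faces].mean(axis=1)
        f_region = np.argmin(np.linalg.norm(
            centroids[:, None, :] - src_lm[None, :, :], axis=2), axis=1)
        sampled = np.zeros_like(aligned)
        dist = np.full(len(aligned), np.inf)
        for region in range(len(third_names)):
            vsel = np.nonzero(v_region == region)[0]
            fsel = np.nonzero(f_region == region)[0]
            if vsel.size == 0 or fsel.size == 0:
                continue
            s, d = _sample_field(source, field.vectors, aligned[vsel], fsel)
            sampled[vsel], dist[vsel] = s, d
    sampled[dist > cutoff_abs] = 0.0
    native = sampled @ transform.rotation / transform.scale
    return TriangleMesh(third_mesh.vertices + native, third_mesh.faces)


# --------------------------------------------------------------------------
# height-map averaging
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AverageSurface:
    """Mean crown surface with the per-cell number of contributing scans."""

    heightmap: HeightMap
    counts: np.ndarray


def _fill(z: np.ndarray) -> np.ndarray:
    filled = z.copy()
    invalid = ~np.isfinite(filled)
    if invalid.any():
        filled[invalid] = np.nanmin(filled) if np.isfinite(filled).any() else 0.0
    return filled


def average_surfaces(
    maps: Sequence[HeightMap],
    reference: int = 0,
    mode: str = "correspondence",
) -> AverageSurface:
    """Average height-map scans into a representative surface.

    Each map is (1) superimposed on the reference map by an in-plane shift
    (phase correlation) plus a least-squares z offset, (2) non-rigidly
    registered to the reference with a regularized dense 2D displacement
    estimate (iterative Lucas-Kanade optical flow), and (3) the corresponding x, y, z
    coordinates are averaged and regridded onto the reference lattice. The
    rigid offsets removed in step 1 are re-centered so the result sits at
    the barycenter of the inputs.

    ``mode="cellwise"`` skips the correspondence step and averages z values
    cell by cell — it attenuates and doubles shifted features and exists for
    comparison.
    """
    if len(maps) < 2:
        raise AveragingError("need at least 2 height maps")
    shapes = {m.z.shape for m in maps}
    spacings = {m.spacing for m in maps}
    if len(shapes) != 1 or len(spacings) != 1:
        raise AveragingError("height maps must share grid shape and spacing")
    ref = maps[reference]
    ref_valid = ref.mask

    aligned, shifts, z_offsets = [], [], []
    for m in maps:
        overlap = ref_valid & m.mask
        if not overlap.any():
            raise AveragingError("disjoint valid regions; cannot superimpose")
        if m is ref:
            aligned.append(ref.z.copy())
            shifts.append(np.zeros(2))
            z_offsets.append(0.0)
            continue
        shift, _, _ = phase_cross_correlation(
            _fill(ref.z), _fill(m.z), upsample_factor=10, normalization=None)
        moved = ndimage.shift(_fill(m.z), shift, order=1, mode="nearest")
        dz = float(np.mean(ref.z[overlap]) - np.mean(moved[overlap]))
        aligned.append(moved + dz)
        shifts.append(np.asarray(shift, dtype=float))
        z_offsets.append(dz)

    ny, nx = ref.z.shape
    if mode == "cellwise":
        stack = np.stack(aligned)
        mean_z = stack.mean(axis=0) - float(np.mean(z_offsets))
        counts = np.full((ny, nx), len(maps))
        return AverageSurface(HeightMap(mean_z, spacing=ref.spacing, origin=ref.origin),
                              counts=counts)
    if mode != "correspondence":
        raise AveragingError(f"unknown averaging mode {mode!r}")

    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    sum_x = np.zeros((ny, nx))
    sum_y = np.zeros((ny, nx))
    sum_z = np.zeros((ny, nx))
    ref_filled = _fill(ref.z)
    for z_al in aligned:
        if np.allclose(z_al, ref_filled, atol=1e-12):
            v = u = np.zeros((ny, nx))
            z_corr = z_al
        else:
            v, u = optical_flow_ilk(ref_filled, z_al, radius=8)
            z_corr = ndimage.map_coordinates(z_al, [rows + v, cols + u],
                                             order=1, mode="nearest")
        sum_x += (cols + u) * ref.spacing + ref.origin[0]
        sum_y += (rows + v) * ref.spacing + ref.origin[1]
        sum_z += z_corr
    k = len(aligned)
    mean_x, mean_y = sum_x / k, sum_y / k
    mean_z = sum_z / k - float(np.mean(z_offsets))

    grid_x, grid_y = ref.xy_grids()
    pts = np.column_stack([mean_x.ravel(), mean_y.ravel()])
    z_grid = griddata(pts, mean_z.ravel(), (grid_x, grid_y), method="linear")
    counts = np.where(np.isfinite(z_grid), k, 0)
    return AverageSurface(HeightMap(z_grid, spacing=ref.spacing, origin=ref.origin),
                          counts=counts)
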