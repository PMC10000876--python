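import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from odontomorph._geom import surface_distance
from odontomorph.dataio import DomainError, HeightMap, LandmarkSet, TriangleMesh
from odontomorph.morph import (
    AveragingError,
    CorrespondenceError,
    DisplacementField,
    RigidSimilarityTransform,
    align_by_landmarks,
    apply_morph,
    average_surfaces,
    build_displacement_field,
    cervical_margin_vertices,
    dense_correspondence,
    landmark_rms,
    refine_by_icp,
    transfer_morph,
)
from odontomorph.simulate import CrownModelParams, CuspPeak, simulate_crown_mesh


def known_similarity(seed=0, scale=1.7):
    rng = np.random.default_rng(seed)
    R = Rotation.from_rotvec(rng.normal(0, 0.5, 3)).as_matrix()
    t = rng.normal(0, 2.0, 3)
    return RigidSimilarityTransform(R, t, scale)


class TestLandmarkAlignment:
    def test_identity_on_copies(self, crown_pair):
        lms = crown_pair[1]
        transform = align_by_landmarks(lms, lms)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-9)
        assert transform.scale == pytest.approx(1.0, abs=1e-9)
        assert landmark_rms(transform, lms, lms) < 1e-12

    def test_recovers_known_similarity(self, crown_pair):
        lms = crown_pair[1]
        true = known_similarity(seed=1)
        target = LandmarkSet({n: true.apply(p)[0] for n, p in lms.entries.items()})
        rec = align_by_landmarks(lms, target)
        np.testing.assert_allclose(rec.rotation, true.rotation, atol=1e-6)
        np.testing.assert_allclose(rec.translation, true.translation, atol=1e-6)
        assert rec.scale == pytest.approx(true.scale, abs=1e-6)

    def test_matches_trimesh_procrustes(self, crown_pair):
        trimesh_reg = pytest.importorskip("trimesh.registration")
        lms = crown_pair[1]
        true = known_similarity(seed=2, scale=0.6)
        names = lms.names
        src = lms.as_array(names)
        tgt = true.apply(src)
        target = LandmarkSet(dict(zip(names, tgt)))
        ours = align_by_landmarks(lms, target)
        matrix, _, _ = trimesh_reg.procrustes(src, tgt, reflection=False,
                                              translation=True, scale=True)
        ours_h = np.eye(4)
        ours_h[:3, :3] = ours.scale * ours.rotation
        ours_h[:3, 3] = ours.translation
        np.testing.assert_allclose(ours_h, matrix, atol=1e-6)

    def test_noisy_landmarks_bounded_rms(self, crown_pair):
        lms = crown_pair[1]
        sd = 0.01
        rng = np.random.default_rng(4)
        true = known_similarity(seed=5, scale=1.0)
        target = LandmarkSet({n: true.apply(p)[0] + rng.normal(0, sd, 3)
                              for n, p in lms.entries.items()})
        rec = align_by_landmarks(lms, target)
        assert landmark_rms(rec, lms, target) <= 3 * sd

    def test_collinear_landmarks_rejected(self):
        a = LandmarkSet({"p": [0, 0, 0], "q": [1, 0, 0], "r": [2, 0, 0]})
        with pytest.raises(DomainError):
            align_by_landmarks(a, a)

    def test_too_few_landmarks_rejected(self):
        a = LandmarkSet({"p": [0, 0, 0], "q": [1, 0, 0]})
        with pytest.raises(DomainError):
            align_by_landmarks(a, a)


class TestICP:
    def test_no_motion_when_aligned(self, crown_pair):
        wt = crown_pair[0]
        transform = refine_by_icp(wt, wt, max_points=200)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-6)

    def test_recovers_small_rigid_motion(self, crown_pair):
        wt = crown_pair[0]
        R = Rotation.from_rotvec([0.03, 0.02, -0.04]).as_matrix()  # ~3 degrees
        pert = RigidSimilarityTransform(R, np.array([0.02, -0.01, 0.03]), 1.0)
        moved = TriangleMesh(pert.apply(wt.vertices), wt.faces)
        rec = refine_by_icp(moved, wt, max_points=300)
        resid = rec.apply(moved.vertices) - wt.vertices
        assert np.sqrt(np.mean(np.sum(resid ** 2, axis=1))) < 1e-3


class TestDenseCorrespondence:
    def test_identity_on_same_mesh(self, crown_pair):
        wt = crown_pair[0]
        corr = dense_correspondence(wt, wt)
        assert corr.matched.all()
        np.testing.assert_allclose(corr.target_points, wt.vertices, atol=1e-9)

    def test_rigid_offset_recovered(self, crown_pair):
        wt = crown_pair[0]
        shifted = TriangleMesh(wt.vertices + [0.0, 0.0, 0.3], wt.faces)
        corr = dense_correspondence(wt, shifted)
        disp = corr.target_points - wt.vertices
        # normal projection returns the rigid offset exactly where the
        # surface is flat; on slopes the projected distance shortens by the
        # slope cosine, so restrict to near-vertical normals
        normals = np.asarray(wt.to_trimesh().vertex_normals)
        flat = corr.matched & (np.abs(normals[:, 2]) > 0.999)
        assert flat.sum() > 10
        # a normal within 2.6 degrees of vertical can deflect the projected
        # point laterally by up to 0.3 * tan(2.6 deg) ~ 0.014
        np.testing.assert_allclose(
            disp[flat], np.tile([0.0, 0.0, 0.3], (int(flat.sum()), 1)), atol=0.015)

    def test_raised_cusp_peaks_at_cusp_center(self):
        flat = CrownModelParams(cusps={}, resolution=32, h=0.3)
        bumped = CrownModelParams(cusps={"c": CuspPeak((0.3, 0.1), 0.25, 0.15)},
                                  resolution=32, h=0.3)
        dome, _ = simulate_crown_mesh(flat)
        dome_b, _ = simulate_crown_mesh(bumped)
        corr = dense_correspondence(dome, dome_b)
        field = build_displacement_field(corr)
        peak_vertex = dome.vertices[np.argmax(field.magnitudes)]
        spacing = 2 * flat.a * 1.15 / 31
        assert np.linalg.norm(peak_vertex[:2] - [0.3, 0.1]) < spacing

    def test_disjoint_meshes_rejected(self, crown_pair):
        wt = crown_pair[0]
        far = TriangleMesh(wt.vertices + [100.0, 0.0, 0.0], wt.faces)
        with pytest.raises(CorrespondenceError):
            dense_correspondence(wt, far)


class TestDisplacementField:
    def test_identity_correspondence_zero_field(self, crown_pair):
        wt = crown_pair[0]
        corr = dense_correspondence(wt, wt)
        field = build_displacement_field(corr)
        np.testing.assert_allclose(field.vectors, 0.0, atol=1e-9)

    def test_constant_offset_field(self, crown_pair):
        wt = crown_pair[0]
        shifted = TriangleMesh(wt.vertices + [0.1, -0.05, 0.2], wt.faces)
        from odontomorph.morph import CorrespondenceMap

        corr = CorrespondenceMap(target_points=shifted.vertices,
                                 kind=np.full(wt.n_vertices, "closest", dtype=object),
                                 source=wt)
        field = build_displacement_field(corr)
        np.testing.assert_allclose(
            field.vectors, np.tile([0.1, -0.05, 0.2], (wt.n_vertices, 1)), atol=1e-12)

    def test_magnitudes_match_norms(self, crown_pair):
        wt, _, mut, _ = crown_pair
        corr = dense_correspondence(wt, mut)
        field = build_displacement_field(corr)
        np.testing.assert_allclose(field.magnitudes,
                                   np.sqrt((field.vectors ** 2).sum(axis=1)),
                                   atol=1e-12)

    def test_boundary_pinned_to_zero(self, crown_pair):
        wt, _, mut, _ = crown_pair
        boundary = cervical_margin_vertices(wt, 0.15)
        assert boundary.size > 0
        field = build_displacement_field(dense_correspondence(wt, mut),
                                         boundary=boundary)
        np.testing.assert_array_equal(field.vectors[boundary], 0.0)


class TestApplyMorph:
    def test_zero_field_is_identity(self, crown_pair):
        wt = crown_pair[0]
        field = DisplacementField(np.zeros((wt.n_vertices, 3)),
                                  np.zeros(wt.n_vertices, bool), wt)
        morphed = apply_morph(wt, field)
        np.testing.assert_array_equal(morphed.vertices, wt.vertices)
        np.testing.assert_array_equal(morphed.faces, wt.faces)

    def test_constant_field_translates(self, crown_pair):
        wt = crown_pair[0]
        vec = np.tile([0.0, 0.2, -0.1], (wt.n_vertices, 1))
        morphed = apply_morph(wt, DisplacementField(vec, np.zeros(wt.n_vertices, bool), wt))
        np.testing.assert_allclose(morphed.vertices, wt.vertices + [0.0, 0.2, -0.1])

    def test_morph_reduces_surface_distance(self, crown_pair):
        wt, _, mut, _ = crown_pair
        corr = dense_correspondence(wt, mut)
        morphed = apply_morph(wt, build_displacement_field(corr))
        before = surface_distance(wt, mut)
        after = surface_distance(morphed, mut)
        assert after <= 0.2 * before  # >= 80% reduction


@pytest.fixture(scope="module")
def human_pair(crown_params):
    """A homologous third crown: the same four cusps under their human
    names, at twice the linear size."""
    from odontomorph.dataio import DEFAULT_CUSP_PAIRING

    params = CrownModelParams(
        a=2 * crown_params.a, b=2 * crown_params.b, h=2 * crown_params.h,
        cusps={h: CuspPeak((2 * c.center[0], 2 * c.center[1]),
                           2 * c.height, 2 * c.width)
               for h, m in DEFAULT_CUSP_PAIRING.items()
               for c in [crown_params.cusps[m]]},
        resolution=crown_params.resolution)
    return simulate_crown_mesh(params)


class TestTransfer:
    def test_zero_field_leaves_mesh_unchanged(self, crown_pair, human_pair):
        from odontomorph.dataio import DEFAULT_CUSP_PAIRING

        wt, wt_lms = crown_pair[0], crown_pair[1]
        human, human_lms = human_pair
        field = DisplacementField(np.zeros((wt.n_vertices, 3)),
                                  np.zeros(wt.n_vertices, bool), wt)
        out = transfer_morph(field, wt_lms, human, human_lms,
                             pairing=DEFAULT_CUSP_PAIRING)
        np.testing.assert_allclose(out.vertices, human.vertices, atol=1e-12)

    def test_identity_alignment_matches_apply_morph(self, crown_pair):
        wt, wt_lms, mut, _ = crown_pair
        corr = dense_correspondence(wt, mut)
        field = build_displacement_field(corr)
        direct = apply_morph(wt, field)
        via_transfer = transfer_morph(field, wt_lms, wt, wt_lms, cutoff=5.0)
        np.testing.assert_allclose(via_transfer.vertices, direct.vertices, atol=1e-9)

    @pytest.mark.parametrize("mode", ["global", "per_cusp"])
    def test_homologous_cusp_shift_scales(self, crown_pair, human_pair, mode):
        from odontomorph.dataio import DEFAULT_CUSP_PAIRING

        wt, wt_lms = crown_pair[0], crown_pair[1]
        human, human_lms = human_pair
        c9 = wt_lms["c9"][:2]
        w = np.exp(-0.5 * np.sum((wt.vertices[:, :2] - c9) ** 2, axis=1) / 0.15 ** 2)
        field = DisplacementField(np.outer(w, [0.2, 0.1, 0.0]),
                                  np.zeros(wt.n_vertices, bool), wt)
        out = transfer_morph(field, wt_lms, human, human_lms,
                             pairing=DEFAULT_CUSP_PAIRING, mode=mode)
        shift = out.vertices - human.vertices
        i = np.argmin(np.linalg.norm(human.vertices - human_lms["hypocone"], axis=1))
        # landmark frame is 2x larger, so the cusp shift doubles
        np.testing.assert_allclose(shift[i][:2], [0.4, 0.2], rtol=0.1)
        j = np.argmin(np.linalg.norm(human.vertices - human_lms["protocone"], axis=1))
        assert np.linalg.norm(shift[j]) < 0.05


def make_dome_map(bump_x, sigma=0.2, n=64, spacing=0.05, bump_h=0.3):
    x = spacing * (np.arange(n) - n / 2)
    xx, yy = np.meshgrid(x, x)
    z = 0.3 * np.clip(1 - (xx / 1.4) ** 2 - (yy / 1.4) ** 2, 0, None) \
        + bump_h * np.exp(-0.5 * ((xx - bump_x) ** 2 + yy ** 2) / sigma ** 2)
    return HeightMap(z, spacing=spacing, origin=(x[0], x[0]))


def bump_height_above_dome(hmap: HeightMap) -> float:
    n = hmap.z.shape[0]
    x = hmap.spacing * (np.arange(n) - n / 2)
    xx, yy = np.meshgrid(x, x)
    dome = 0.3 * np.clip(1 - (xx / 1.4) ** 2 - (yy / 1.4) ** 2, 0, None)
    return float(np.nanmax(hmap.z - dome))


class TestSurfaceAveraging:
    def test_identical_maps_average_exactly(self):
        m = make_dome_map(-0.2)
        avg = average_surfaces([m, m, m])
        np.testing.assert_allclose(avg.heightmap.z, m.z, atol=1e-9)

    def test_pure_z_offsets_give_midsurface(self):
        m = make_dome_map(0.0)
        lo = HeightMap(m.z - 0.1, spacing=m.spacing, origin=m.origin)
        hi = HeightMap(m.z + 0.1, spacing=m.spacing, origin=m.origin)
        avg = average_surfaces([lo, hi])
        np.testing.assert_allclose(avg.heightmap.z, m.z, atol=1e-9)

    def test_correspondence_preserves_shifted_bump(self):
        m1, m2 = make_dome_map(-0.2), make_dome_map(+0.2)
        corr = average_surfaces([m1, m2], mode="correspondence")
        naive = average_surfaces([m1, m2], mode="cellwise")
        assert bump_height_above_dome(corr.heightmap) >= 0.9 * 0.3
        assert bump_height_above_dome(naive.heightmap) < 0.9 * 0.3

    def test_disjoint_regions_rejected(self):
        m = make_dome_map(0.0)
        left = HeightMap(np.where(np.arange(64)[None, :] < 30, m.z, np.nan),
                         spacing=m.spacing, origin=m.origin)
        right = HeightMap(np.where(np.arange(64)[None, :] >= 34, m.z, np.nan),
                          spacing=m.spacing, origin=m.origin)
        with pytest.raises(AveragingError):
            average_surfaces([left, right])

    def test_single_map_rejected(self):
        with pytest.raises(AveragingError):
            average_surfaces([make_dome_map(0.0)])
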