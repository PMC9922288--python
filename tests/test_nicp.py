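import numpy as np
import pytest

from cardioflow.correspondence import nearest_correspondences
from cardioflow.mesh_core import build_incidence_matrix
from cardioflow.nicp import (RegistrationConfig, TransformStack,
                             assemble_system, make_stiffness_schedule,
                             optimal_step_solve, register_surfaces)
from cardioflow.nicp import _NormalEquationCache
from cardioflow.primitives import icosphere


def random_instance(rng, n_target=None, landmarks=False, bidir=False):
    """Small random registration instance built on an icosahedron."""
    src = icosphere(1.0, 0)          # 12 vertices
    tgt_pts = src.vertices + rng.normal(scale=0.1, size=src.vertices.shape)
    lm_idx = np.array([0, 5]) if landmarks else np.empty(0, dtype=int)
    corr = nearest_correspondences(src.vertices, tgt_pts, lm_idx)
    if bidir:
        corr.reverse_source_idx = rng.integers(0, src.n_vertices, size=4)
        corr.reverse_targets = rng.normal(size=(4, 3))
    lm = (lm_idx, rng.normal(size=(len(lm_idx), 3))) if landmarks else None
    cfg = RegistrationConfig(alpha_schedule=np.array([3.0]),
                             lambda_bidir=0.5 if bidir else 0.0,
                             gamma=1.0, beta=10.0)
    return src, corr, lm, cfg


def hand_summed_cost(src, corr, lm, cfg, alpha, X):
    """The four squared-residual terms summed explicitly, term by term."""
    n = src.n_vertices
    blocks = X.reshape(n, 4, 3)
    homo = np.hstack([src.vertices, np.ones((n, 1))])
    positions = np.einsum("nk,nkj->nj", homo, blocks)

    # stiffness: alpha^2 * sum over edges of ||G (X_i - X_j)||_F^2
    G = np.diag([1.0, 1.0, 1.0, cfg.gamma])
    stiff = 0.0
    for i, j in src.edges:
        stiff += np.sum((G @ (blocks[j] - blocks[i])) ** 2)
    stiff *= alpha ** 2

    dist = float(np.sum(corr.forward_weights[:, None]
                        * (positions - corr.forward_targets) ** 2))

    lm_cost = 0.0
    if lm is not None and len(lm[0]):
        lm_cost = cfg.beta ** 2 * float(
            np.sum((positions[lm[0]] - lm[1]) ** 2))

    bidir = 0.0
    if len(corr.reverse_source_idx):
        bidir = cfg.lambda_bidir ** 2 * float(np.sum(
            (positions[corr.reverse_source_idx] - corr.reverse_targets) ** 2))

    return stiff + dist + lm_cost + bidir


class TestStiffnessSchedule:
    def test_chambers(self):
        s = make_stiffness_schedule("chambers")
        assert len(s) == 100
        assert s[0] == 100.0 and s[-1] == 1.0

    def test_laa(self):
        s = make_stiffness_schedule("laa")
        assert len(s) == 20
        assert s[0] == 100.0 and s[-1] == 10.0

    @pytest.mark.parametrize("region", ["chambers", "laa"])
    def test_linear_spacing_and_decrease(self, region):
        s = make_stiffness_schedule(region)
        deltas = np.diff(s)
        assert np.allclose(deltas, deltas[0])
        assert np.all(deltas < 0)

    def test_unknown_region(self):
        with pytest.raises(ValueError, match="unknown region"):
            make_stiffness_schedule("mitral")


class TestAssembleSystem:
    def test_row_count_no_landmarks(self, rng):
        src, corr, _, cfg = random_instance(rng)
        system = assemble_system(src, corr, None, 3.0, cfg)
        e, n = len(src.edges), src.n_vertices
        assert system.A.shape == (4 * e + n, 4 * n)

    def test_row_blocks_with_all_terms(self, rng):
        src, corr, lm, cfg = random_instance(rng, landmarks=True, bidir=True)
        system = assemble_system(src, corr, lm, 3.0, cfg)
        e, n = len(src.edges), src.n_vertices
        assert system.A.shape == (4 * e + n + 2 + 4, 4 * n)
        assert set(system.block_rows) == {"stiffness", "distance", "landmark",
                                          "bidirectional"}

    def test_identity_zero_distance_residual(self):
        src = icosphere(1.0, 0)
        corr = nearest_correspondences(src, src)
        cfg = RegistrationConfig(alpha_schedule=np.array([1.0]))
        system = assemble_system(src, corr, None, 1.0, cfg)
        X = TransformStack.identity(src.n_vertices)
        assert system.block_cost(X, "distance") == pytest.approx(0.0, abs=1e-20)
        assert system.block_cost(X, "stiffness") == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("landmarks,bidir", [(False, False), (True, False),
                                                 (False, True), (True, True)])
    def test_cost_decomposition_oracle(self, rng, landmarks, bidir):
        src, corr, lm, cfg = random_instance(rng, landmarks=landmarks,
                                             bidir=bidir)
        alpha = 2.5
        system = assemble_system(src, corr, lm, alpha, cfg)
        X = rng.normal(size=(4 * src.n_vertices, 3))
        assert system.cost(X) == pytest.approx(
            hand_summed_cost(src, corr, lm, cfg, alpha, X), rel=1e-10)

    def test_nonpositive_alpha_raises(self, rng):
        src, corr, _, cfg = random_instance(rng)
        with pytest.raises(ValueError, match="alpha"):
            assemble_system(src, corr, None, 0.0, cfg)


class TestOptimalStepSolve:
    @pytest.mark.parametrize("landmarks,bidir", [(False, False), (True, False),
                                                 (False, True), (True, True)])
    def test_matches_dense_least_squares(self, landmarks, bidir):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            src, corr, lm, cfg = random_instance(rng, landmarks=landmarks,
                                                 bidir=bidir)
            system = assemble_system(src, corr, lm, 3.0, cfg)
            X = optimal_step_solve(system).X
            X_dense, *_ = np.linalg.lstsq(system.A.toarray(), system.b,
                                          rcond=None)
            assert np.allclose(X, X_dense, rtol=1e-8, atol=1e-10)

    def test_fast_path_equals_stacked_path(self, rng):
        src, corr, lm, cfg = random_instance(rng, landmarks=True, bidir=True)
        system = assemble_system(src, corr, lm, 3.0, cfg)
        X_stacked = optimal_step_solve(system).X
        cache = _NormalEquationCache(src, cfg, build_incidence_matrix(src))
        X_fast = cache.solve(corr, lm, 3.0).X
        assert np.allclose(X_stacked, X_fast, rtol=1e-10, atol=1e-12)

    def test_cost_not_above_previous_iterate(self, rng):
        src, corr, lm, cfg = random_instance(rng, landmarks=True)
        system = assemble_system(src, corr, lm, 3.0, cfg)
        X_prev = TransformStack.identity(src.n_vertices)
        X_opt = optimal_step_solve(system)
        assert system.cost(X_opt) <= system.cost(X_prev) + 1e-12


class TestRegisterSurfaces:
    def test_identity_fixed_point(self):
        src = icosphere(1.0, 2)
        cfg = RegistrationConfig(
            alpha_schedule=make_stiffness_schedule("chambers", n_steps=5))
        res = register_surfaces(src, src, None, cfg)
        assert np.abs(res.positions - src.vertices).max() < 1e-6 * 2.0

    def test_rigid_translation_is_free(self):
        src = icosphere(1.0, 2)
        tgt = icosphere(1.0, 2, center=(0.08, -0.05, 0.03))
        cfg = RegistrationConfig(
            alpha_schedule=make_stiffness_schedule("chambers", n_steps=5))
        res = register_surfaces(src, tgt, None, cfg)
        disp = res.positions - src.vertices
        assert np.allclose(disp, [0.08, -0.05, 0.03], atol=1e-6)

    def test_stiffness_limit_equal_blocks(self):
        src = icosphere(1.0, 1)
        tgt = icosphere(1.0, 1, center=(0.1, 0.0, 0.0))
        cfg = RegistrationConfig(alpha_schedule=np.array([1e6]))
        res = register_surfaces(src, tgt, None, cfg)
        B = res.transforms.blocks()
        assert np.abs(B - B.mean(axis=0)).max() < 1e-6

    def test_scaled_target_converges(self):
        src = icosphere(1.0, 2)
        tgt = icosphere(1.1, 3)
        cfg = RegistrationConfig(
            alpha_schedule=make_stiffness_schedule("chambers", n_steps=25))
        res = register_surfaces(src, tgt, None, cfg)
        assert res.mean_distance < 0.02 * 2.2
        assert res.mean_distance <= res.initial_mean_distance

    def test_landmarks_stay_put(self):
        src = icosphere(1.0, 2)
        tgt = icosphere(1.15, 3)
        lm_idx = np.array([0, 7, 23])
        lm = (lm_idx, src.vertices[lm_idx])
        cfg = RegistrationConfig(
            alpha_schedule=make_stiffness_schedule("chambers", n_steps=15))
        res = register_surfaces(src, tgt, lm, cfg)
        lm_disp = np.linalg.norm(res.positions[lm_idx] - src.vertices[lm_idx],
                                 axis=1)
        assert lm_disp.max() < 0.01 * 2.3

    def test_clean_phantom_registration_quality(self, coarse_phantom):
        # analog of the reported ~0.5 mm mean tracking distance on clean
        # targets: final mean distance < 2% of unit-cube scale
        from cardioflow.mesh_core import Region, extract_by_labels
        from cardioflow.tracking import (_CHAMBER_LABELS,
                                         _submesh_landmark_indices,
                                         normalize_to_unit_cube)
        data = coarse_phantom
        normed, _ = normalize_to_unit_cube(
            [data.source, data.targets_chambers[1]])
        srcn, tgt = normed
        sub, idx = extract_by_labels(srcn, data.labels, _CHAMBER_LABELS)
        ring = _submesh_landmark_indices(idx, data.labels, Region.BOUNDARY_RING)
        cfg = RegistrationConfig(
            alpha_schedule=make_stiffness_schedule("chambers", n_steps=15),
            prune_border_targets=True)
        res = register_surfaces(sub, tgt, (ring, sub.vertices[ring]), cfg)
        assert res.mean_distance < 0.02


class TestConfigValidation:
    def test_increasing_schedule_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(alpha_schedule=np.array([1.0, 10.0]))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(alpha_schedule=np.array([10.0, 0.0]))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(alpha_schedule=np.array([1.0]), beta=-1.0)
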