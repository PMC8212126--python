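import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saxstool.fixtures import SyntheticSystemSpec, make_two_domain_system
from saxstool.geometry import quat_to_matrix, random_quat, rotation_about_axis
from saxstool.som import (
    Descriptor7,
    PoseReference,
    SOMConfig,
    SOMError,
    assign,
    cluster_components,
    make_descriptor,
    project,
    reconstruct_pose,
    som_distance,
    train_som,
)


@pytest.fixture(scope="module")
def bodies():
    mol = make_two_domain_system(SyntheticSystemSpec(linker_length=0, seed=0))
    fixed = mol.subset(np.where(mol.rigid_group == 0)[0])
    mobile = mol.subset(np.where(mol.rigid_group == 1)[0])
    return fixed, mobile


@pytest.fixture(scope="module")
def reference(bodies):
    fixed, mobile = bodies
    return PoseReference(
        fixed_coords=fixed.coords - fixed.coords.mean(axis=0),
        mobile_coords=mobile.coords - mobile.coords.mean(axis=0),
    )


def _random_descriptors(rng, n, com_center, spread=3.0, quat=None):
    out = np.empty((n, 7))
    for i in range(n):
        out[i, :3] = com_center + rng.normal(0, spread, 3)
        q = random_quat(rng) if quat is None else quat + rng.normal(0, 0.02, 4)
        q /= np.linalg.norm(q)
        out[i, 3:] = q
    return out


class TestMakeDescriptor:
    def test_template_pose_gives_identity_quaternion(self, bodies, reference):
        fixed, mobile = bodies
        d = make_descriptor(fixed.coords, mobile.coords, reference)
        expected_com = mobile.coords.mean(axis=0) - fixed.coords.mean(axis=0)
        np.testing.assert_allclose(d.com, expected_com, atol=1e-8)
        assert abs(abs(d.quat[0]) - 1.0) < 1e-8

    def test_half_turn_about_z(self, bodies, reference):
        fixed, mobile = bodies
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi)
        com = mobile.coords.mean(axis=0)
        rotated = (mobile.coords - com) @ R.T + com
        d = make_descriptor(fixed.coords, rotated, reference)
        np.testing.assert_allclose(np.abs(d.quat), [0, 0, 0, 1], atol=1e-8)

    def test_invariant_under_global_rigid_motion(self, bodies, reference, rng):
        fixed, mobile = bodies
        d0 = make_descriptor(fixed.coords, mobile.coords, reference)
        R = quat_to_matrix(random_quat(rng))
        t = rng.uniform(-30, 30, 3)
        d1 = make_descriptor(fixed.coords @ R.T + t, mobile.coords @ R.T + t, reference)
        np.testing.assert_allclose(d1.com, d0.com, atol=1e-8)
        assert abs(abs(np.dot(d1.quat, d0.quat)) - 1.0) < 1e-8

    def test_wrong_fixed_body_raises(self, bodies, reference, rng):
        fixed, mobile = bodies
        with pytest.raises(SOMError, match="RMSD"):
            make_descriptor(fixed.coords + rng.normal(0, 1.0, fixed.coords.shape), mobile.coords, reference)


class TestSomDistance:
    def test_identical_descriptors_distance_zero(self, rng):
        d = Descriptor7(com=rng.normal(size=3), quat=random_quat(rng))
        assert som_distance(d, d, dmax=40.0) == 0.0

    def test_quaternion_sign_invariance(self, rng):
        a = Descriptor7(com=np.zeros(3), quat=random_quat(rng))
        b = Descriptor7(com=np.zeros(3), quat=-a.quat)
        assert som_distance(a, b, dmax=40.0) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_quaternions_cost_dmax(self):
        a = Descriptor7(com=np.zeros(3), quat=[1, 0, 0, 0])
        b = Descriptor7(com=np.zeros(3), quat=[0, 1, 0, 0])
        assert som_distance(a, b, dmax=37.0) == pytest.approx(37.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_premetric(self, seed):
        rng = np.random.default_rng(seed)
        a = np.concatenate([rng.normal(0, 10, 3), random_quat(rng)])
        b = np.concatenate([rng.normal(0, 10, 3), random_quat(rng)])
        dab = som_distance(a, b, dmax=25.0)
        assert dab == pytest.approx(som_distance(b, a, dmax=25.0))
        assert dab >= 0.0
        # simultaneous sign flip leaves the distance unchanged
        b_flipped = np.concatenate([b[:3], -b[3:]])
        assert som_distance(a, b_flipped, dmax=25.0) == pytest.approx(dab)


class TestTrainSom:
    def test_single_repeated_descriptor_attracts_neurons(self, rng):
        x = np.concatenate([[5.0, -3.0, 2.0], random_quat(rng)])
        X = np.tile(x, (50, 1))
        som = train_som(X, (4, 4), SOMConfig(epochs=10, seed=0))
        assert som.quantization_error(X) < 0.5
        assert som.hits.sum() == 50

    def test_two_separated_pose_clusters_resolved(self, rng):
        qa, qb = random_quat(rng), random_quat(rng)
        A = _random_descriptors(rng, 120, np.array([0.0, 0.0, 0.0]), quat=qa)
        B = _random_descriptors(rng, 120, np.array([40.0, 0.0, 0.0]), quat=qb)
        X = np.vstack([A, B])
        truth = np.array([0] * 120 + [1] * 120)
        som = train_som(X, (10, 10), SOMConfig(seed=1))
        labels = cluster_components(som, threshold=10.0)
        sample_labels = labels[assign(som, X)]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, sample_labels) > 0.9

    def test_training_reproducible(self, rng):
        X = _random_descriptors(rng, 60, np.zeros(3), spread=10.0)
        s1 = train_som(X, (6, 6), SOMConfig(seed=3))
        s2 = train_som(X, (6, 6), SOMConfig(seed=3))
        np.testing.assert_array_equal(s1.coms, s2.coms)
        np.testing.assert_array_equal(s1.quats, s2.quats)

    def test_neuron_quats_stay_unit_norm(self, rng):
        X = _random_descriptors(rng, 80, np.zeros(3), spread=15.0)
        som = train_som(X, (7, 7), SOMConfig(seed=2))
        np.testing.assert_allclose(np.linalg.norm(som.quats, axis=1), 1.0, atol=1e-9)

    def test_quantization_error_improves_over_epochs(self, rng):
        X = _random_descriptors(rng, 100, np.zeros(3), spread=12.0)
        qe = [
            train_som(X, (6, 6), SOMConfig(epochs=e, seed=5)).quantization_error(X)
            for e in (1, 5, 15)
        ]
        assert qe[-1] < qe[0]

    def test_empty_input_rejected(self):
        with pytest.raises(SOMError):
            train_som(np.zeros((0, 7)), (4, 4))


class TestProject:
    def test_constant_values_everywhere(self, rng):
        X = _random_descriptors(rng, 40, np.zeros(3), spread=8.0)
        som = train_som(X, (5, 5), SOMConfig(seed=0))
        grid = project(som, X, np.full(40, 3.14))
        vals = grid[~np.isnan(grid)]
        assert vals.size > 0
        np.testing.assert_allclose(vals, 3.14)

    def test_min_reducer_bounded_by_mean(self, rng):
        X = _random_descriptors(rng, 60, np.zeros(3), spread=8.0)
        som = train_som(X, (5, 5), SOMConfig(seed=0))
        values = rng.uniform(0, 10, 60)
        lo = project(som, X, values, reducer="min")
        avg = project(som, X, values, reducer="mean")
        mask = ~np.isnan(lo)
        assert np.all(lo[mask] <= avg[mask] + 1e-12)

    def test_tiny_map_matches_manual_bmu_bookkeeping(self, rng):
        X = _random_descriptors(rng, 3, np.zeros(3), spread=20.0)
        som = train_som(X, (2, 2), SOMConfig(seed=1))
        values = np.array([1.0, 2.0, 3.0])
        grid = project(som, X, values, reducer="min").ravel()
        manual = {}
        for x, v in zip(X, values):
            k = som.bmu(x)
            manual[k] = min(manual.get(k, np.inf), v)
        for k in range(4):
            if k in manual:
                assert grid[k] == pytest.approx(manual[k])
            else:
                assert np.isnan(grid[k])


class TestReconstructPose:
    def test_round_trip_through_descriptor(self, bodies, reference, rng):
        fixed, mobile = bodies
        R = quat_to_matrix(random_quat(rng))
        com = mobile.coords.mean(axis=0)
        posed = (mobile.coords - com) @ R.T + com + rng.uniform(-5, 5, 3)
        d = make_descriptor(fixed.coords, posed, reference)
        mol, _clash = reconstruct_pose(d, fixed, mobile)
        # reconstruction reproduces the pose in the reference frame
        d2 = make_descriptor(
            mol.coords[: len(fixed)], mol.coords[len(fixed):], reference
        )
        np.testing.assert_allclose(d2.com, d.com, atol=1e-6)
        assert abs(abs(np.dot(d2.quat, d.quat)) - 1.0) < 1e-9

    def test_overlapping_com_sets_clash_flag(self, bodies):
        fixed, mobile = bodies
        d = Descriptor7(com=np.zeros(3), quat=[1, 0, 0, 0])  # mobile on top of fixed
        _, clash = reconstruct_pose(d, fixed, mobile)
        assert clash

    def test_far_translation_is_clash_free(self, bodies):
        fixed, mobile = bodies
        d = Descriptor7(com=np.array([80.0, 0.0, 0.0]), quat=[1, 0, 0, 0])
        mol, clash = reconstruct_pose(d, fixed, mobile)
        assert not clash
        np.testing.assert_allclose(mol.coords[len(fixed):].mean(axis=0), d.com, atol=1e-9)
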