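"""Basis-system learner: similarity kernel, updates, training, persistence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flowbasis as fb
from flowbasis.basis_model import ModelFormatError

from conftest import TRAIN_SEEDS, naive_predict


def _random_model(rng, n=8, k=1.0, eta=0.1):
    return fb.BasisSystem(
        positions=rng.normal(size=(n, 3)),
        velocities=rng.normal(size=(n, 3)),
        shape_constant=k,
        learning_rate=eta,
    )


class TestInit:
    def test_full_sample_is_permutation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 3))
        m = fb.init_bases((x, y), 12, seed=5)
        order = np.lexsort(m.positions.T)
        ref = np.lexsort(x.T)
        assert np.array_equal(m.positions[order], x[ref])
        assert np.array_equal(m.velocities[order], y[ref])

    def test_same_seed_identical(self):
        rng = np.random.default_rng(1)
        pairs = (rng.normal(size=(50, 3)), rng.normal(size=(50, 3)))
        a = fb.init_bases(pairs, 10, seed=3)
        b = fb.init_bases(pairs, 10, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_sampling_matches_documented_generator(self):
        # contract: indices drawn by default_rng(seed).choice(n, size, replace=False)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 3))
        y = rng.normal(size=(100, 3))
        m = fb.init_bases((x, y), 4, seed=17)
        idx = np.random.default_rng(17).choice(100, size=4, replace=False)
        assert np.array_equal(m.positions, x[idx])
        assert np.array_equal(m.velocities, y[idx])

    def test_too_many_bases_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fb.init_bases((np.zeros((3, 3)), np.zeros((3, 3))), 4, seed=0)


class TestSimilarity:
    def test_zero_distance_gives_one(self):
        m = _random_model(np.random.default_rng(0))
        w = fb.similarities(m, m.positions[3])
        assert w.raw[3] == pytest.approx(1.0)
        assert w.winner_index == 3

    def test_single_basis_distance_two(self):
        m = fb.BasisSystem(
            positions=[[0.0, 0.0, 0.0]], velocities=[[0.0, 0.0, 0.0]],
            shape_constant=1.0, learning_rate=0.1,
        )
        w = fb.similarities(m, [2.0, 0.0, 0.0])
        assert w.raw[0] == pytest.approx(math.exp(-4.0), rel=1e-12)
        assert w.normalized[0] == 1.0

    def test_two_basis_normalization(self):
        # raw values (e^-1, e^-4) -> normalized (0.952574, 0.047426)
        m = fb.BasisSystem(
            positions=[[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
            velocities=np.zeros((2, 3)),
            shape_constant=1.0, learning_rate=0.1,
        )
        w = fb.similarities(m, [0.0, 0.0, 0.0])
        expect = np.array([math.exp(-1.0), math.exp(-4.0)])
        assert w.raw == pytest.approx(expect, rel=1e-12)
        assert w.normalized == pytest.approx(expect / expect.sum(), rel=1e-12)
        assert w.normalized[0] == pytest.approx(0.952574, abs=1e-6)

    def test_tie_broken_by_lowest_index(self):
        m = fb.BasisSystem(
            positions=[[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]],
            velocities=np.zeros((2, 3)),
            shape_constant=1.0, learning_rate=0.1,
        )
        assert fb.similarities(m, [0.0, 0.0, 0.0]).winner_index == 0

    def test_underflow_far_query_falls_back_to_nearest(self):
        m = fb.BasisSystem(
            positions=[[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]],
            velocities=[[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
            shape_constant=10.0, learning_rate=0.1,
        )
        w = fb.similarities(m, [105.0, 0.0, 0.0])  # all kernels underflow
        assert w.normalized.tolist() == [0.0, 1.0]
        assert fb.predict_velocity(m, [105.0, 0.0, 0.0]) == pytest.approx([2.0, 0.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(
        st.floats(0.0, 126.0), st.floats(0.0, 44.0), st.floats(0.0, 3.5)
    ))
    def test_normalized_weights_sum_to_one(self, query):
        m = _random_model(np.random.default_rng(8), n=16)
        m.positions = np.abs(m.positions) * [30.0, 10.0, 1.0]
        w = fb.similarities(m, np.asarray(query))
        assert abs(w.normalized.sum() - 1.0) < 1e-12
        assert (w.normalized >= 0).all()
        assert w.raw[w.winner_index] == w.raw.max()


class TestWinnerUpdate:
    def test_moves_by_learning_rate(self):
        m = fb.BasisSystem(
            positions=[[0.0, 0.0, 0.0]], velocities=[[5.0, 0.0, 0.0]],
            shape_constant=1.0, learning_rate=0.1,
        )
        fb.update_winner_position(m, [1.0, 0.0, 0.0])
        assert m.positions[0] == pytest.approx([0.1, 0.0, 0.0], rel=1e-15)

    def test_sample_at_winner_is_fixed_point(self):
        m = _random_model(np.random.default_rng(3))
        before = m.positions.copy()
        fb.update_winner_position(m, before[2])
        assert np.array_equal(m.positions, before)

    def test_only_winner_moves_velocities_untouched(self):
        m = _random_model(np.random.default_rng(4))
        pos, vel = m.positions.copy(), m.velocities.copy()
        x = m.positions[1] + 0.01
        fb.update_winner_position(m, x)
        assert np.array_equal(m.velocities, vel)
        moved = np.nonzero((m.positions != pos).any(axis=1))[0]
        assert moved.tolist() == [1]

    def test_contraction_factor_one_minus_eta(self):
        m = _random_model(np.random.default_rng(5), eta=0.1)
        x = np.array([10.0, -3.0, 0.5])
        w = fb.similarities(m, x)
        d_before = np.linalg.norm(m.positions[w.winner_index] - x)
        fb.update_winner_position(m, x)
        d_after = np.linalg.norm(m.positions[w.winner_index] - x)
        assert d_after == pytest.approx((1.0 - 0.1) * d_before, rel=1e-12)


class TestVelocityUpdate:
    def test_zero_residual_is_noop(self):
        m = fb.BasisSystem(
            positions=[[0.0, 0.0, 0.0]], velocities=[[1.0, 2.0, 3.0]],
            shape_constant=1.0, learning_rate=0.1,
        )
        before = m.velocities.copy()
        fb.update_velocities(m, [0.3, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert np.array_equal(m.velocities, before)

    def test_single_basis_lms_step(self):
        m = fb.BasisSystem(
            positions=[[0.0, 0.0, 0.0]], velocities=[[0.0, 0.0, 0.0]],
            shape_constant=1.0, learning_rate=0.1,
        )
        fb.update_velocities(m, [0.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        assert m.velocities[0] == pytest.approx([0.1, 0.0, 0.0], rel=1e-15)

    def test_positions_untouched(self):
        m = _random_model(np.random.default_rng(6))
        pos = m.positions.copy()
        fb.update_velocities(m, [0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        assert np.array_equal(m.positions, pos)

    def test_residual_contracts_by_closed_form_factor(self):
        m = _random_model(np.random.default_rng(7), eta=0.1)
        x = np.array([0.2, -0.1, 0.4])
        y = np.array([1.0, 2.0, -1.0])
        norms = []
        for _ in range(5):
            w = fb.similarities(m, x)
            res = y - w.normalized @ m.velocities
            norms.append(np.linalg.norm(res))
            fb.update_velocities(m, x, y)
        factor = 1.0 - 0.1 * (w.normalized @ w.normalized)
        for a, b in zip(norms, norms[1:]):
            assert b == pytest.approx(factor * a, rel=1e-10)
            assert b < a


class TestPredict:
    def test_single_basis_constant(self):
        m = fb.BasisSystem(
            positions=[[1.0, 1.0, 1.0]], velocities=[[3.0, -1.0, 0.5]],
            shape_constant=2.0, learning_rate=0.1,
        )
        for q in ([0, 0, 0], [9, 9, 9], [1, 1, 1]):
            assert fb.predict_velocity(m, q) == pytest.approx([3.0, -1.0, 0.5])

    def test_equidistant_bases_average(self):
        m = fb.BasisSystem(
            positions=[[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]],
            velocities=[[2.0, 0.0, 0.0], [0.0, 4.0, 0.0]],
            shape_constant=1.0, learning_rate=0.1,
        )
        assert fb.predict_velocity(m, [0.0, 0.5, 0.0]) == pytest.approx([1.0, 2.0, 0.0])

    def test_matches_naive_direct_summation(self):
        rng = np.random.default_rng(9)
        m = _random_model(rng, n=8, k=0.7)
        for _ in range(20):
            q = rng.normal(size=3)
            got = fb.predict_velocity(m, q)
            want = naive_predict(m.positions, m.velocities, 0.7, q)
            assert got == pytest.approx(want, abs=1e-12)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(10)
        m = _random_model(rng, n=12)
        qs = rng.normal(size=(30, 3))
        batch = fb.predict_velocities(m, qs)
        for i, q in enumerate(qs):
            assert batch[i] == pytest.approx(fb.predict_velocity(m, q), abs=1e-9)

    def test_prediction_inside_convex_hull_of_velocities(self):
        rng = np.random.default_rng(11)
        m = _random_model(rng, n=16)
        lo = m.velocities.min(axis=0) - 1e-12
        hi = m.velocities.max(axis=0) + 1e-12
        for _ in range(50):
            v = fb.predict_velocity(m, rng.normal(size=3) * 3)
            assert (v >= lo).all() and (v <= hi).all()


class TestTrain:
    def test_constant_velocity_field_converges(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, size=(1000, 3))
        y = np.tile([0.5, -0.25, 0.0], (1000, 1))
        m = fb.train((x, y), 32, 1.0, 0.1, 100_000, seed=1)
        for q in x[:50]:
            assert fb.predict_velocity(m, q) == pytest.approx([0.5, -0.25, 0.0], abs=1e-3)

    def test_zero_iterations_equals_init(self):
        rng = np.random.default_rng(13)
        pairs = (rng.normal(size=(40, 3)), rng.normal(size=(40, 3)))
        trained = fb.train(pairs, 8, 1.0, 0.1, 0, seed=4)
        init = fb.init_bases(pairs, 8, seed=4)
        assert np.array_equal(trained.positions, init.positions)
        assert np.array_equal(trained.velocities, init.velocities)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(14)
        pairs = (rng.uniform(size=(200, 3)), rng.normal(size=(200, 3)))
        a = fb.train(pairs, 16, 1.0, 0.1, 5_000, seed=9)
        b = fb.train(pairs, 16, 1.0, 0.1, 5_000, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_training_log_recorded(self):
        rng = np.random.default_rng(15)
        pairs = (rng.uniform(size=(100, 3)), rng.normal(size=(100, 3)))
        m = fb.train(pairs, 8, 2.0, 0.2, 500, seed=3, source="toy")
        log = m.training_log
        assert log.iterations == 500
        assert log.epochs == pytest.approx(5.0)
        assert log.seed == 3
        assert log.source == "toy"

    def test_two_phase_schedule_runs(self):
        rng = np.random.default_rng(16)
        pairs = (rng.uniform(size=(100, 3)), rng.normal(size=(100, 3)))
        m = fb.train(pairs, 8, 1.0, 0.1, 2_000, seed=3, schedule="two_phase")
        assert m.training_log.schedule == "two_phase"

    def test_heldout_mre_improves_with_more_bases(
        self, slit_train_ds, slit_heldout_ds, slit_models
    ):
        """Parameter recovery: finer basis systems track the slit flow better."""
        pairs = fb.assemble_training_vectors(slit_train_ds)
        medians = []
        for n in (64, 256):
            vals = [
                fb.local_error_summary(
                    fb.train(pairs, n, 10.0, 0.1, 200_000, seed=s), slit_heldout_ds
                ).mre_full
                for s in TRAIN_SEEDS
            ]
            medians.append(float(np.median(vals)))
        vals_1024 = [
            fb.local_error_summary(m, slit_heldout_ds).mre_full
            for m in slit_models.values()
        ]
        medians.append(float(np.median(vals_1024)))
        assert medians[0] >= medians[1] >= medians[2]


class TestPersistence:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(17)
        pairs = (rng.uniform(size=(60, 3)), rng.normal(size=(60, 3)))
        m = fb.train(pairs, 8, 1.5, 0.1, 300, seed=2, source="fix")
        path = tmp_path / "m.txt"
        fb.save_model(m, path)
        back = fb.load_model(path)
        assert np.array_equal(back.positions, m.positions)
        assert np.array_equal(back.velocities, m.velocities)
        assert back.shape_constant == m.shape_constant
        assert back.learning_rate == m.learning_rate
        assert back.training_log == m.training_log

    def test_save_load_save_byte_identical(self, tmp_path):
        rng = np.random.default_rng(18)
        m = _random_model(rng)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        fb.save_model(m, p1)
        fb.save_model(fb.load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truncated_file_errors(self, tmp_path):
        rng = np.random.default_rng(19)
        m = _random_model(rng)
        path = tmp_path / "t.txt"
        fb.save_model(m, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(ModelFormatError, match="truncated"):
            fb.load_model(path)

    def test_version_mismatch_errors(self, tmp_path):
        path = tmp_path / "v.txt"
        path.write_text("# flowbasis basis-system v99\n# n_bases: 0\n")
        with pytest.raises(ModelFormatError, match="version"):
            fb.load_model(path)
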