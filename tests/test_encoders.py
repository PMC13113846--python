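"""Recurrence plot, GASF and MTF encoders against brute-force oracles."""

import numpy as np
import pytest

from mcgscreen.embedding import PhaseTrajectory, delay_embed, select_epsilon
from mcgscreen.encoders import (
    GasfMatrix,
    RecurrenceMatrix,
    gasf,
    mtf,
    recurrence_plot,
    to_image,
)
from mcgscreen.errors import InvalidInputError, InvalidParameterError


def _traj(points):
    points = np.asarray(points, dtype=float)
    return PhaseTrajectory(points=points, m=points.shape[1], tau=1)


class TestRecurrencePlot:
    def test_identical_points_all_ones(self):
        rp = recurrence_plot(_traj([[0.0, 0.0], [0.0, 0.0]]), 0.1)
        np.testing.assert_array_equal(rp.R, [[1, 1], [1, 1]])

    def test_distant_points_identity(self):
        rp = recurrence_plot(_traj([[0.0, 0.0], [1.0, 0.0]]), 0.5)
        np.testing.assert_array_equal(rp.R, np.eye(2))

    def test_boundary_distance_counts_as_recurrence(self):
        rp = recurrence_plot(_traj([[0.0], [1.0]]), 1.0)  # Theta(0) = 1
        np.testing.assert_array_equal(rp.R, [[1, 1], [1, 1]])

    @pytest.mark.parametrize("m_points", [5, 17, 42, 60])
    def test_matches_brute_force_distance_oracle(self, m_points, rng):
        pts = rng.random((m_points, 3))
        eps = 0.4
        rp = recurrence_plot(_traj(pts), eps)
        for i in range(m_points):
            for j in range(m_points):
                expected = 1 if np.linalg.norm(pts[i] - pts[j]) <= eps else 0
                assert rp.R[i, j] == expected

    def test_symmetry_and_reflexive_diagonal(self, rng):
        traj = delay_embed(rng.random(80), 3, 4)
        rp = recurrence_plot(traj, select_epsilon(traj, 0.2))
        np.testing.assert_array_equal(rp.R, rp.R.T)
        assert np.all(np.diag(rp.R) == 1)

    def test_time_reversal_anti_transpose(self, rng):
        x = rng.random(60)
        eps = 0.3
        fwd = recurrence_plot(delay_embed(x, 3, 4), eps).R
        rev = recurrence_plot(delay_embed(x[::-1], 3, 4), eps).R
        np.testing.assert_array_equal(rev, fwd[::-1, ::-1])

    def test_empty_and_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            recurrence_plot(_traj([[0.0]]), -1.0)


class TestGasf:
    def test_closed_form_example(self):
        out = gasf(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(out.xbar, [-1, 0, 1], atol=1e-15)
        np.testing.assert_allclose(out.phi, [np.pi, np.pi / 2, 0], atol=1e-12)
        np.testing.assert_allclose(
            out.G, [[1, 0, -1], [0, -1, 0], [-1, 0, 1]], atol=1e-12
        )

    def test_all_ones_input(self):
        out = gasf(np.ones(8))
        np.testing.assert_allclose(out.G, 1.0, atol=1e-15)

    def test_trig_and_algebraic_forms_agree(self, rng):
        for _ in range(20):
            x = rng.random(224)
            out = gasf(x)
            xb = out.xbar
            algebraic = np.outer(xb, xb) - np.outer(
                np.sqrt(1 - xb**2), np.sqrt(1 - xb**2)
            )
            assert np.abs(out.G - algebraic).max() <= 1e-12

    def test_diagonal_identity_and_symmetry(self, rng):
        out = gasf(rng.random(100))
        np.testing.assert_allclose(np.diag(out.G), 2 * out.xbar**2 - 1, atol=1e-12)
        np.testing.assert_array_equal(out.G, out.G.T)
        assert np.abs(out.G).max() <= 1.0 + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            gasf(np.array([0.0, 1.2]))
        # within the 1e-9 tolerance values are clamped, not rejected
        out = gasf(np.array([0.0, 1.0 + 1e-10]))
        assert out.xbar.max() <= 1.0


class TestMtf:
    def test_worked_q2_example(self):
        out = mtf(np.array([0.0, 0.1, 0.6, 0.9]), Q=2)
        np.testing.assert_array_equal(out.states, [0, 0, 1, 1])
        np.testing.assert_allclose(out.transition, [[0.5, 0.5], [0.0, 1.0]])
        expected_field = [
            [0.5, 0.5, 0.5, 0.5],
            [0.5, 0.5, 0.5, 0.5],
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
        np.testing.assert_allclose(out.field, expected_field)

    def test_constant_input_degenerate_all_ones(self):
        out = mtf(np.full(20, 0.4), Q=4)
        assert out.degenerate
        np.testing.assert_allclose(out.field, 1.0)

    def test_rows_stochastic_and_field_from_transition(self, rng):
        x = rng.random(224)
        out = mtf(x, Q=8)
        occupied = out.transition.sum(axis=1) > 0
        np.testing.assert_allclose(out.transition[occupied].sum(axis=1), 1.0, atol=1e-12)
        assert out.field.min() >= 0 and out.field.max() <= 1
        entries = set(np.round(out.transition.ravel(), 12))
        assert set(np.round(out.field.ravel(), 12)) <= entries

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            mtf(np.array([0.1, 0.2]), Q=8)


class TestToImage:
    def test_gasf_all_ones_maps_to_ones(self):
        img = to_image(GasfMatrix(G=np.ones((224, 224)), xbar=np.ones(224), phi=np.zeros(224)), "GASF")
        np.testing.assert_allclose(img.pixels, 1.0)
        assert img.pixels.shape == (224, 224, 3)

    def test_rp_identity_matrix(self):
        img = to_image(RecurrenceMatrix(R=np.eye(224, dtype=np.uint8), epsilon=0.1), "RP")
        np.testing.assert_array_equal(img.pixels[:, :, 0], np.eye(224))

    def test_gasf_round_trip(self, rng):
        g = gasf(rng.random(224))
        img = to_image(g, "GASF")
        recovered = img.pixels[:, :, 0] * 2 - 1
        assert np.abs(recovered - g.G).max() <= 1e-9

    def test_rp_resize_preserves_binary_texture(self, rng):
        traj = delay_embed(rng.random(224), 3, 4)  # side 216
        rp = recurrence_plot(traj, select_epsilon(traj, 0.1))
        img = to_image(rp, "RP")
        assert img.pixels.shape == (224, 224, 3)
        assert set(np.unique(img.pixels)) <= {0.0, 1.0}

    def test_non_square_rejected(self):
        with pytest.raises(InvalidInputError):
            to_image(np.zeros((10, 12)), "MTF")
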