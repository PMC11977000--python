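"""Simplex machinery: closure, zero replacement, pivot ilr and rotations.

scikit-bio's compositional functions serve as an independent oracle for
closure, multiplicative replacement and the isometry of the ilr map
(its basis differs from the pivot basis, so only basis-free quantities
are compared).
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from skbio.stats.composition import closure as skbio_closure
from skbio.stats.composition import clr as skbio_clr
from skbio.stats.composition import ilr as skbio_ilr
from skbio.stats.composition import multi_replace as skbio_multi_replace

from coda_activity import coda

positive_parts = arrays(
    float,
    3,
    elements=st.floats(min_value=1e-3, max_value=1e3),
)


def random_compositions(n, rng, d=3):
    return np.exp(rng.normal(0.0, 1.0, size=(n, d)))


class TestClosure:
    def test_printed_minutes_close_to_printed_shares(self):
        # group geometric means in min/day close to the printed % shares
        pct = coda.closure(np.array([438.4, 457.2, 64.5]), kappa=100.0)
        assert np.round(pct, 1).tolist() == [45.7, 47.6, 6.7]

    @pytest.mark.parametrize(
        "x, kappa, expected",
        [
            ([1.0, 1.0, 1.0], 3.0, [1.0, 1.0, 1.0]),
            ([2.0, 3.0, 5.0], 100.0, [20.0, 30.0, 50.0]),
        ],
    )
    def test_simple_cases(self, x, kappa, expected):
        assert np.allclose(coda.closure(np.array(x), kappa), expected)

    @given(positive_parts, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance_and_idempotence(self, x, c):
        closed = coda.closure(x, 100.0)
        assert np.allclose(coda.closure(c * x, 100.0), closed, rtol=1e-9)
        assert np.allclose(coda.closure(closed, 100.0), closed, rtol=1e-9)
        assert np.isclose(closed.sum(), 100.0, rtol=1e-9)

    def test_matches_reference_implementation(self, rng):
        x = random_compositions(20, rng)
        assert np.allclose(coda.closure(x, 1.0), skbio_closure(x))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            coda.closure(np.array([1.0, 0.0, 2.0]))


class TestZeroReplace:
    def test_multiplicative_replacement_preserves_total(self):
        out = coda.zero_replace(np.array([350.0, 250.0, 0.0]), delta=1.0)
        # non-zero parts shrink by (600-1)/600
        assert np.allclose(out, [350 * 599 / 600, 250 * 599 / 600, 1.0])
        assert np.isclose(out.sum(), 600.0)

    def test_two_zeros(self):
        out = coda.zero_replace(np.array([0.0, 0.0, 600.0]), delta=1.0)
        assert np.allclose(out, [1.0, 1.0, 598.0])

    def test_noop_without_zeros(self):
        x = np.array([10.0, 20.0, 30.0])
        assert np.array_equal(coda.zero_replace(x), x)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="positive part"):
            coda.zero_replace(np.zeros(3))

    def test_matches_reference_on_closed_data(self):
        # on unit-closed rows with absolute delta, the multiplicative scheme
        # coincides with scikit-bio's
        x = np.array([[0.0, 0.3, 0.7], [0.2, 0.0, 0.8], [0.1, 0.4, 0.5]])
        delta = 0.01
        assert np.allclose(coda.zero_replace(x, delta), skbio_multi_replace(x, delta))


class TestGeometricMean:
    def test_single_row_is_its_closure(self):
        row = np.array([[40.0, 40.0, 20.0]])
        assert np.allclose(
            coda.geometric_mean_composition(row, 100.0), coda.closure(row[0], 100.0)
        )

    def test_hand_computed_two_rows(self):
        rows = np.array([[40.0, 40.0, 20.0], [10.0, 80.0, 10.0]])
        gm = np.array([np.sqrt(400.0), np.sqrt(3200.0), np.sqrt(200.0)])
        expected = 100.0 * gm / gm.sum()
        out = coda.geometric_mean_composition(rows, 100.0)
        assert np.allclose(out, expected, atol=1e-12)
        assert np.allclose(out, [22.05, 62.37, 15.59], atol=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            coda.geometric_mean_composition(np.array([[1.0, 0.0, 2.0]]))


class TestIlrPivot:
    def test_neutral_element_maps_to_origin(self):
        assert np.allclose(coda.ilr_pivot(np.array([1 / 3, 1 / 3, 1 / 3])), 0.0)

    def test_direct_formula_evaluation(self):
        z = coda.ilr_pivot(coda.closure(np.array([4.0, 1.0, 1.0]), 1.0))
        assert np.allclose(z, [np.sqrt(2 / 3) * np.log(4.0), 0.0], atol=1e-12)

    def test_closed_form_d3(self, rng):
        # matrix implementation vs the two explicit D=3 coordinates
        x = random_compositions(50, rng)
        z = coda.ilr_pivot(x)
        z1 = np.sqrt(2 / 3) * np.log(x[:, 0] / np.sqrt(x[:, 1] * x[:, 2]))
        z2 = np.sqrt(1 / 2) * np.log(x[:, 1] / x[:, 2])
        assert np.allclose(z, np.column_stack([z1, z2]), atol=1e-12)

    @given(positive_parts, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance(self, x, c):
        assert np.allclose(coda.ilr_pivot(c * x), coda.ilr_pivot(x), atol=1e-9)

    def test_isometry_against_reference_basis(self, rng):
        # any orthonormal ilr basis preserves Aitchison geometry: compare
        # norms and pairwise distances with scikit-bio's (different) basis
        x = random_compositions(30, rng)
        z_mine = coda.ilr_pivot(x)
        z_ref = skbio_ilr(skbio_closure(x))
        assert np.allclose(
            np.linalg.norm(z_mine, axis=1), np.linalg.norm(z_ref, axis=1), atol=1e-9
        )
        d_mine = np.linalg.norm(z_mine[:10] - z_mine[10:20], axis=1)
        d_ait = [coda.aitchison_distance(a, b) for a, b in zip(x[:10], x[10:20])]
        assert np.allclose(d_mine, d_ait, atol=1e-9)

    def test_clr_matches_reference(self, rng):
        x = random_compositions(10, rng)
        assert np.allclose(coda.clr(x), skbio_clr(skbio_closure(x)), atol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            coda.ilr_pivot(np.array([1.0, 0.0, 1.0]))


class TestIlrInverse:
    def test_origin_maps_to_equal_parts(self):
        assert np.allclose(coda.ilr_inverse(np.zeros(2), kappa=960.0), 960.0 / 3)

    def test_round_trip(self, rng):
        z = rng.normal(0.0, 2.0, size=(1000, 2))
        back = coda.ilr_pivot(coda.ilr_inverse(z, kappa=960.0))
        assert np.abs(back - z).max() < 1e-9

    def test_round_trip_under_rotation(self, rng):
        perm = (2, 0, 1)
        z = rng.normal(size=(100, 2))
        x = coda.ilr_inverse(z, kappa=1.0, perm=perm)
        assert np.abs(coda.ilr_pivot(x, perm) - z).max() < 1e-9

    def test_printed_geometric_mean_round_trip(self):
        gm = np.array([438.4, 457.2, 64.5])
        pct = coda.ilr_inverse(coda.ilr_pivot(gm), kappa=100.0)
        assert np.round(pct, 1).tolist() == [45.7, 47.6, 6.7]


class TestRotations:
    def test_rotation_order_matches_reporting_rows(self):
        rots = coda.pivot_rotations(("st", "lpa", "mvpa"))
        assert rots == [
            ("st", "lpa", "mvpa"),
            ("lpa", "mvpa", "st"),
            ("mvpa", "st", "lpa"),
        ]

    def test_two_part_composition(self):
        assert len(coda.pivot_rotations(("a", "b"))) == 2

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            coda.pivot_rotations(("a", "a", "b"))

    def test_first_coordinates_sum_to_zero_across_rotations(self, rng):
        x = random_compositions(200, rng)
        z1s = np.column_stack(
            [coda.ilr_pivot(x, perm)[:, 0] for perm in coda.rotation_perms(3)]
        )
        assert np.abs(z1s.sum(axis=1)).max() < 1e-12

    def test_first_coordinate_invariant_to_tail_order(self, rng):
        # z1 contrasts the first part against the geometric mean of the rest,
        # so swapping the remaining parts cannot change it
        x = random_compositions(50, rng)
        z_a = coda.ilr_pivot(x, (2, 0, 1))
        z_b = coda.ilr_pivot(x, (2, 1, 0))
        assert np.allclose(z_a[:, 0], z_b[:, 0], atol=1e-12)


class TestBetaRotation:
    def test_first_pivot_betas_round_trip(self, rng):
        beta = rng.normal(size=2)
        vals = coda.first_pivot_betas(beta)
        assert abs(sum(vals.values())) < 1e-12
        back = coda.canonical_betas_from_first_pivots(vals)
        assert np.allclose(back, beta, atol=1e-10)

    def test_published_triple_is_consistent(self):
        beta = coda.canonical_betas_from_first_pivots(
            {"st": 0.136, "lpa": -0.010, "mvpa": -0.126}
        )
        vals = coda.first_pivot_betas(beta)
        assert np.allclose(
            [vals["st"], vals["lpa"], vals["mvpa"]], [0.136, -0.010, -0.126], atol=1e-12
        )

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            coda.canonical_betas_from_first_pivots(
                {"st": 1.0, "lpa": 1.0, "mvpa": 1.0}
            )
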