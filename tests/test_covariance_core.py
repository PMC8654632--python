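import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_covariance, fractional_anisotropy
from spacems.covariance_core import (
    cai,
    centre_of_mass,
    covariance_tensor,
    cpi,
    csi,
    mci,
    shape_metrics,
)
from spacems.errors import DomainError, EmptyInputError
from spacems.phantom import random_rotation

CUBE = np.array(
    [[i, j, k] for i in range(3) for j in range(3) for k in range(3)], dtype=float
)


def random_cloud(rng, n=None):
    """Random anisotropic Gaussian point cloud."""
    n = n or int(rng.integers(2, 200))
    scales = rng.uniform(0.01, 20.0, size=3)
    return rng.standard_normal((n, 3)) * scales @ random_rotation(rng).T


class TestCentreOfMass:
    def test_midpoint(self):
        np.testing.assert_array_equal(
            centre_of_mass([(0, 0, 0), (2, 0, 0)]), [1.0, 0.0, 0.0]
        )

    def test_single_point_identity(self):
        np.testing.assert_array_equal(centre_of_mass([(3.5, -1, 2)]), [3.5, -1.0, 2.0])

    def test_cube_centre(self):
        np.testing.assert_allclose(centre_of_mass(CUBE), [1.0, 1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            centre_of_mass(np.empty((0, 3)))


class TestCovarianceTensor:
    def test_single_point_zero_tensor(self):
        summary = covariance_tensor([(1.0, 2.0, 3.0)])
        np.testing.assert_array_equal(summary.tensor, np.zeros((3, 3)))
        assert summary.eigenvalues == (0.0, 0.0, 0.0)

    def test_collinear_points(self):
        summary = covariance_tensor([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        np.testing.assert_allclose(summary.eigenvalues, (2 / 3, 0.0, 0.0), atol=1e-12)

    def test_cube_is_isotropic(self):
        summary = covariance_tensor(CUBE)
        np.testing.assert_allclose(summary.tensor, np.eye(3) * (2 / 3), atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            cloud = random_cloud(rng, n=int(rng.integers(2, 40)))
            summary = covariance_tensor(cloud)
            np.testing.assert_allclose(
                summary.tensor, brute_force_covariance(cloud), atol=1e-9
            )

    def test_sample_normalisation_option(self):
        pts = [(0, 0, 0), (2, 0, 0)]
        pop = covariance_tensor(pts, ddof=0)
        samp = covariance_tensor(pts, ddof=1)
        assert pop.tensor[0, 0] == pytest.approx(1.0)
        assert samp.tensor[0, 0] == pytest.approx(2.0)

    def test_uncentred_moment_option(self):
        pts = [(1.0, 0, 0), (1.0, 0, 0)]
        raw = covariance_tensor(pts, centred=False)
        assert raw.tensor[0, 0] == pytest.approx(1.0)  # E[x^2], not var

    def test_trace_equals_eigenvalue_sum(self, rng):
        cloud = random_cloud(rng)
        summary = covariance_tensor(cloud)
        assert np.trace(summary.tensor) == pytest.approx(
            sum(summary.eigenvalues), rel=1e-9
        )


eigen_triples = st.tuples(
    st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6)
).map(lambda t: tuple(sorted(t, reverse=True)))


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "func,triple,expected",
        [
            (mci, (0, 0, 0), 0.0),
            (mci, (3, 2, 1), 2.0),
            (mci, (2 / 3, 2 / 3, 2 / 3), 2 / 3),
            (cai, (5.0, 5.0, 5.0), 0.0),
            (cai, (7.0, 0.0, 0.0), 1.0),
            (cai, (2.0, 1.0, 1.0), math.sqrt(1 / 6)),
            (cpi, (4.0, 4.0, 0.0), 1.0),
            (cpi, (2.0, 2.0, 2.0), 0.0),
            (cpi, (3.0, 2.0, 1.0), 1 / 3),
            (csi, (9.0, 9.0, 9.0), 1.0),
            (csi, (5.0, 3.0, 0.0), 0.0),
            (csi, (3.0, 2.0, 1.0), 0.5),
        ],
    )
    def test_known_values(self, func, triple, expected):
        assert func(*triple) == pytest.approx(expected, abs=1e-12)

    def test_negative_eigenvalue_rejected(self):
        for func in (mci, cai, cpi, csi):
            with pytest.raises(DomainError):
                func(1.0, 0.5, -0.1)

    def test_unsorted_eigenvalues_rejected(self):
        with pytest.raises(DomainError):
            cpi(1.0, 2.0, 0.5)

    def test_zero_trace_shape_indices_undefined(self):
        assert math.isnan(cai(0, 0, 0))
        assert math.isnan(cpi(0, 0, 0))
        assert math.isnan(csi(0, 0, 0))
        assert mci(0, 0, 0) == 0.0

    @settings(max_examples=300, deadline=None)
    @given(eigen_triples)
    def test_ranges_over_arbitrary_triples(self, triple):
        u1, u2, u3 = triple
        assert mci(u1, u2, u3) >= 0
        for func in (cai, cpi, csi):
            value = func(u1, u2, u3)
            assert math.isnan(value) or -1e-12 <= value <= 1 + 1e-12

    @settings(max_examples=200, deadline=None)
    @given(eigen_triples)
    def test_cai_matches_fa_oracle(self, triple):
        expected = fractional_anisotropy(*triple)
        got = cai(*triple)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(min(expected, 1.0), abs=1e-12)


class TestShapeMetricsBundle:
    def test_single_voxel_degenerate(self):
        m = shape_metrics(covariance_tensor([(0.0, 0.0, 0.0)]))
        assert m.degenerate_flag
        assert m.mci == 0.0
        assert math.isnan(m.cai) and math.isnan(m.cpi) and math.isnan(m.csi)

    def test_cube_archetype(self):
        m = shape_metrics(covariance_tensor(CUBE))
        assert m.mci == pytest.approx(2 / 3)
        assert m.cai == pytest.approx(0.0, abs=1e-9)
        assert m.cpi == pytest.approx(0.0, abs=1e-9)
        assert m.csi == pytest.approx(1.0, abs=1e-9)

    def test_collinear_archetype(self):
        m = shape_metrics(covariance_tensor([(0, 0, 0), (1, 0, 0), (2, 0, 0)]))
        assert m.cai == pytest.approx(1.0)
        assert m.cpi == pytest.approx(0.0, abs=1e-12)
        assert m.csi == pytest.approx(0.0, abs=1e-12)


class TestInvariances:
    def _metrics(self, points):
        return shape_metrics(covariance_tensor(points))

    def test_rotation_invariance(self, rng):
        for _ in range(25):
            cloud = random_cloud(rng)
            base = self._metrics(cloud)
            rotated = self._metrics(cloud @ random_rotation(rng).T)
            for name in ("mci", "cai", "cpi", "csi"):
                assert getattr(rotated, name) == pytest.approx(
                    getattr(base, name), abs=1e-9
                )

    def test_translation_invariance(self, rng):
        cloud = random_cloud(rng)
        base = self._metrics(cloud)
        shifted = self._metrics(cloud + rng.uniform(-100, 100, 3))
        for name in ("mci", "cai", "cpi", "csi"):
            assert getattr(shifted, name) == pytest.approx(getattr(base, name), abs=1e-9)

    def test_scaling_scales_mci_quadratically(self, rng):
        cloud = random_cloud(rng)
        base = self._metrics(cloud)
        for s in (0.5, 2.0, 7.3):
            scaled = self._metrics(cloud * s)
            assert scaled.mci == pytest.approx(base.mci * s**2, rel=1e-9)
            for name in ("cai", "cpi", "csi"):
                assert getattr(scaled, name) == pytest.approx(
                    getattr(base, name), abs=1e-9
                )

    def test_mci_equals_third_of_trace(self, rng):
        """MCI can be computed without any eigen-decomposition."""
        for _ in range(20):
            cloud = random_cloud(rng)
            summary = covariance_tensor(cloud)
            assert mci(*summary.eigenvalues) == pytest.approx(
                np.trace(summary.tensor) / 3, rel=1e-9
            )

    def test_ranges_over_random_clouds(self, rng):
        for _ in range(1000):
            m = self._metrics(random_cloud(rng, n=int(rng.integers(2, 60))))
            assert m.mci >= 0
            for v in (m.cai, m.cpi, m.csi):
                assert math.isnan(v) or 0 <= v <= 1
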