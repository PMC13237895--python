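"""Transmission, friction, wheel drive, and the coupled spillover solve."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lhsdrive.drivetrain import (CouplingMatrix, TransmissionParams,
                                 WheelAllocation, coupled_velocities,
                                 friction_R, spectral_radius, transmission_T,
                                 wheel_drive)
from lhsdrive.errors import StabilityError, ValidationError

from conftest import neumann_oracle, random_stable_coupling

P = TransmissionParams(a=10.0, m0=0.5, r_max=0.6, eta=2.0, c=0.5)

# the four spillovers printed in the narrative (rows receive):
# gov->clin 0.18, gov->edu 0.10, gov->res 0.10, clin->res 0.12
K_TEXT = np.array([[0, 0, 0, 0.18],
                   [0, 0, 0, 0.10],
                   [0.12, 0, 0, 0.10],
                   [0, 0, 0, 0]])

params_strategy = st.builds(
    TransmissionParams,
    a=st.floats(0.5, 30), m0=st.floats(0.0, 1.0),
    r_max=st.floats(0.0, 0.95), eta=st.floats(0.2, 5.0),
    c=st.floats(0.05, 1.0),
)


class TestTransmission:
    def test_midpoint_identity(self):
        assert transmission_T(P.m0, P) == pytest.approx(0.5)

    def test_logistic_tails(self):
        assert transmission_T(1.0, P) == pytest.approx(1 / (1 + np.exp(-5)), rel=1e-5)
        assert transmission_T(0.0, P) == pytest.approx(1 / (1 + np.exp(5)), rel=1e-5)
        assert transmission_T(1.0, P) == pytest.approx(0.99331, abs=1e-5)
        assert transmission_T(0.0, P) == pytest.approx(0.00669, abs=1e-5)

    @given(params_strategy)
    def test_strictly_increasing_and_half_at_midpoint(self, p):
        grid = np.linspace(0, 1, 101)
        t = transmission_T(grid, p)
        assert np.all(np.diff(t) > 0)
        assert transmission_T(p.m0, p) == pytest.approx(0.5, abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            TransmissionParams(a=-1, m0=0.5, r_max=0.6, eta=2, c=0.5)
        with pytest.raises(ValidationError):
            TransmissionParams(a=10, m0=0.5, r_max=1.0, eta=2, c=0.5)


class TestFriction:
    def test_zero_and_half_saturation(self):
        assert friction_R(0.0, P) == 0.0
        assert friction_R(P.c, P) == pytest.approx(P.r_max / 2)

    def test_value_at_full_maturity(self):
        # r_max * 1 / (1 + 0.25)
        assert friction_R(1.0, P) == pytest.approx(0.48)

    @given(st.builds(
        TransmissionParams,
        a=st.floats(0.5, 30), m0=st.floats(0.0, 1.0),
        r_max=st.floats(0.01, 0.95),  # r_max = 0 degenerates to R == 0
        eta=st.floats(0.2, 5.0), c=st.floats(0.05, 1.0)))
    def test_increasing_bounded_halfway_identity(self, p):
        grid = np.linspace(0, 1, 101)
        r = friction_R(grid, p)
        assert np.all(np.diff(r) > 0)
        assert r[0] == 0.0
        assert np.all(r < p.r_max + 1e-12)
        if p.c <= 1.0:
            assert friction_R(p.c, p) == pytest.approx(p.r_max / 2, abs=1e-12)


class TestWheelDrive:
    def test_symmetric_point_gives_half_vmax(self):
        # choose E, F so that E*T == F*(1-R) at M = m0
        T = transmission_T(0.5, P)   # 0.5
        R = friction_R(0.5, P)       # 0.3
        E = np.full(4, 1.0)
        F = E * T / (1 - R)
        alloc = WheelAllocation(tuple(E), tuple(F), (1.0, 1.0, 1.0, 1.0))
        f = wheel_drive(0.5, alloc, P)
        assert f == pytest.approx(np.full(4, 0.5))

    def test_direct_evaluation(self):
        # at M = m0 = c: T = 1/2 and R = r_max/2 = 0.4, so with
        # v_max=1, E=2, F=1: f = 1*(2*0.5)/(2*0.5 + 1*0.6) = 0.625
        p = TransmissionParams(a=10, m0=0.5, r_max=0.8, eta=2.0, c=0.5)
        alloc = WheelAllocation((2.0,) * 4, (1.0,) * 4, (1.0,) * 4)
        f = wheel_drive(0.5, alloc, p)
        assert f == pytest.approx(np.full(4, 0.625))

    def test_saturates_to_vmax_at_large_engine_power(self):
        alloc = WheelAllocation((1e9,) * 4, (1.0,) * 4, (1.0, 2.0, 3.0, 4.0))
        f = wheel_drive(0.5, alloc, P)
        assert f == pytest.approx([1.0, 2.0, 3.0, 4.0], rel=1e-8)

    def test_monotone_in_engine_friction_and_maturity(self, rng):
        for _ in range(50):
            E = tuple(rng.uniform(0.2, 3, 4))
            F = tuple(rng.uniform(0.2, 3, 4))
            vmax = tuple(rng.uniform(0.5, 2, 4))
            alloc = WheelAllocation(E, F, vmax)
            m1, m2 = sorted(rng.uniform(0.01, 0.99, 2))
            f1, f2 = wheel_drive(m1, alloc, P), wheel_drive(m2, alloc, P)
            if m2 > m1:
                assert np.all(f2 >= f1)
            boostedE = WheelAllocation(tuple(np.array(E) * 2), F, vmax)
            assert np.all(wheel_drive(m1, boostedE, P) > f1)
            boostedF = WheelAllocation(E, tuple(np.array(F) * 2), vmax)
            assert np.all(wheel_drive(m1, boostedF, P) < f1)
            assert np.all(f1 > 0) and np.all(f1 < np.array(vmax))


class TestCoupling:
    def test_spectral_radius_zero_matrix(self):
        assert spectral_radius(np.zeros((4, 4))) == 0.0

    def test_acyclic_text_matrix_is_nilpotent(self):
        assert spectral_radius(K_TEXT) == pytest.approx(0.0, abs=1e-12)

    def test_scaled_permutation(self):
        Kp = 0.5 * np.array([[0, 1, 0, 0], [0, 0, 1, 0],
                             [0, 0, 0, 1], [1, 0, 0, 0]])
        assert spectral_radius(Kp) == pytest.approx(0.5)

    def test_validation(self):
        with pytest.raises(ValidationError):
            CouplingMatrix(-K_TEXT)
        with pytest.raises(ValidationError):
            CouplingMatrix(np.eye(4) * 0.5)
        with pytest.raises(StabilityError):
            CouplingMatrix(np.ones((4, 4)) - np.eye(4))


class TestCoupledVelocities:
    def test_identity_coupling(self):
        f = np.array([0.1, 0.2, 0.3, 0.4])
        assert coupled_velocities(f, np.zeros((4, 4))) == pytest.approx(f)

    def test_text_spillovers_forward_substitution(self):
        v = coupled_velocities(np.full(4, 0.5), K_TEXT)
        assert v == pytest.approx([0.59, 0.55, 0.6208, 0.5])

    def test_unstable_matrix_refused(self):
        with pytest.raises(StabilityError):
            coupled_velocities(np.full(4, 0.5), np.ones((4, 4)) - np.eye(4))

    def test_matches_neumann_series_oracle(self, rng):
        """Linear solve equals the truncated Neumann series to 1e-10
        for 1,000 random stable coupling matrices."""
        for _ in range(1000):
            K = random_stable_coupling(rng, max_rho=0.9)
            f = rng.uniform(0, 2, size=4)
            v = coupled_velocities(f, K)
            expected = neumann_oracle(K, f, terms=300)
            np.testing.assert_allclose(v, expected, atol=1e-10)

    def test_amplification_v_geq_f(self, rng):
        for _ in range(200):
            K = random_stable_coupling(rng)
            f = rng.uniform(0, 1, size=4)
            v = coupled_velocities(f, K)
            assert np.all(v >= f - 1e-12)

    def test_strict_amplification_on_positive_path(self):
        v = coupled_velocities(np.full(4, 0.5), K_TEXT)
        assert v[0] > 0.5 and v[2] > 0.5  # receive from governance/clinical
        assert v[3] == pytest.approx(0.5)  # governance receives nothing

    def test_batched_rows_match_single_solves(self, rng):
        K = random_stable_coupling(rng)
        F = rng.uniform(0, 1, size=(7, 4))
        V = coupled_velocities(F, K)
        for i in range(7):
            np.testing.assert_allclose(V[i], coupled_velocities(F[i], K))
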