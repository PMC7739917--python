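"""The D3Q19 stencil, equilibrium, collision, streaming and moments."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasclbm import lattice as lb
from vasclbm.errors import DivergenceError, InvalidStateError, StabilityError

from conftest import closed_box


class TestDescriptor:
    def test_weights_sum_to_one_exactly(self, lat):
        assert sum(lat.weights_exact) == Fraction(1)

    def test_weight_values_by_vector_class(self, lat):
        norms = (lat.velocities**2).sum(axis=1)
        assert np.count_nonzero(norms == 0) == 1
        assert np.count_nonzero(norms == 1) == 6
        assert np.count_nonzero(norms == 2) == 12
        for w, n in zip(lat.weights_exact, norms):
            assert w == {0: Fraction(1, 3), 1: Fraction(1, 18), 2: Fraction(1, 36)}[n]

    def test_first_and_second_moments_isotropy_exact(self, lat):
        # sum w e = 0 and sum w e_a e_b = (1/3) delta_ab in exact arithmetic
        for a in range(3):
            assert sum(
                w * int(e[a]) for w, e in zip(lat.weights_exact, lat.velocities)
            ) == Fraction(0)
            for b in range(3):
                expect = Fraction(1, 3) if a == b else Fraction(0)
                assert sum(
                    w * int(e[a]) * int(e[b])
                    for w, e in zip(lat.weights_exact, lat.velocities)
                ) == expect

    def test_opposite_is_involution_and_antisymmetric(self, lat):
        for i in range(19):
            j = lat.opposite[i]
            assert lat.opposite[j] == i
            assert (lat.velocities[j] == -lat.velocities[i]).all()


class TestEquilibrium:
    def test_rest_state_gives_weights(self, lat):
        feq = lb.equilibrium(1.0, np.zeros(3), lat)
        assert np.allclose(feq, lat.weights, atol=1e-15)

    def test_moment_identities_random_states(self, lat, rng):
        for _ in range(20):
            rho = float(rng.uniform(0.5, 2.0))
            u = rng.uniform(-0.08, 0.08, 3)
            feq = lb.equilibrium(rho, u, lat)
            assert np.isclose(feq.sum(), rho, rtol=1e-13)
            mom = lat.velocities.T.astype(float) @ feq
            assert np.allclose(mom, rho * u, atol=1e-14)

    def test_rest_population_at_u01(self, lat):
        # w0 * (1 - u^2 / (2 c_s^2)) = (1/3)(1 - 0.015) evaluated term by term
        feq = lb.equilibrium(1.0, np.array([0.1, 0.0, 0.0]), lat)
        assert feq[0] == pytest.approx(0.3283333333333333, abs=1e-15)

    def test_nonpositive_density_rejected(self, lat):
        with pytest.raises(InvalidStateError):
            lb.equilibrium(0.0, np.zeros(3), lat)

    @settings(max_examples=30, deadline=None)
    @given(
        ux=st.floats(-0.1, 0.1),
        uy=st.floats(-0.1, 0.1),
        uz=st.floats(-0.1, 0.1),
        rho=st.floats(0.5, 2.0),
    )
    def test_galilean_moment_roundtrip(self, ux, uy, uz, rho):
        """macroscopic(equilibrium(rho, u)) recovers (rho, u) to round-off."""
        u = np.array([ux, uy, uz])
        feq = lb.equilibrium(rho, u)[:, None, None, None]
        mac = lb.macroscopic(feq)
        assert mac.rho[0, 0, 0] == pytest.approx(rho, rel=1e-13)
        assert np.allclose(mac.u[:, 0, 0, 0], u, atol=1e-14)


class TestCollide:
    def test_equilibrium_is_fixed_point(self, lat):
        feq = lb.equilibrium(1.2, np.array([0.02, -0.01, 0.03]), lat)
        f = feq[:, None, None, None].copy()
        out = lb.collide(f, tau=0.7, lat=lat)
        assert np.allclose(out, f, atol=1e-15)

    def test_full_relaxation_at_tau_one(self, lat, rng):
        f = lb.equilibrium(1.0, np.zeros(3), lat)[:, None, None, None] * (
            1 + 0.01 * rng.standard_normal((19, 1, 1, 1))
        )
        out = lb.collide(f, tau=1.0, lat=lat)
        rho = f.sum(axis=0)
        u = np.tensordot(lat.velocities.astype(float), f, axes=([0], [0])) / rho
        assert np.allclose(out, lb.equilibrium(rho, u, lat), atol=1e-15)

    def test_subcritical_tau_rejected(self, lat):
        f = lb.equilibrium(1.0, np.zeros(3), lat)[:, None, None, None]
        with pytest.raises(StabilityError):
            lb.collide(f, tau=0.5, lat=lat)

    def test_uniform_force_momentum_budget(self, lat):
        """On a periodic box a uniform force adds g*N momentum per step."""
        shape = (4, 4, 4)
        mask = np.ones(shape, dtype=bool)
        f = lb.equilibrium(1.0, np.zeros(3), lat)[:, None, None, None] * mask
        g = 1e-4
        F = np.zeros((3,) + shape)
        F[0] = g
        n = 50
        for _ in range(n):
            f = lb.collide(f, tau=0.8, F=F, lat=lat)
            f = lb.stream(f, mask, lat)
        # bare momentum of the populations after n steps is n*g*N minus the
        # half-step correction that lives in the velocity definition
        mom_x = float((lat.velocities[:, 0][:, None, None, None] * f).sum())
        expected = n * g * mask.sum()
        assert mom_x == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestStream:
    def test_uniform_periodic_state_invariant(self, lat):
        mask = np.ones((5, 5, 5), dtype=bool)
        f = lb.equilibrium(1.0, np.array([0.05, 0.0, 0.0]), lat)[
            :, None, None, None
        ] * mask
        out = lb.stream(f, mask, lat)
        assert np.array_equal(out, f)

    def test_single_population_advects(self, lat):
        mask = np.ones((5, 5, 5), dtype=bool)
        f = np.zeros((19, 5, 5, 5))
        i = 7  # some moving direction
        e = lat.velocities[i]
        f[i, 2, 2, 2] = 1.0
        out = lb.stream(f, mask, lat)
        assert out[i, 2 + e[0], 2 + e[1], 2 + e[2]] == 1.0
        assert out.sum() == 1.0

    def test_bounce_back_reverses_at_wall(self, lat):
        # site next to a solid wall: population aimed at the wall returns
        mask = np.ones((5, 5, 5), dtype=bool)
        mask[3, :, :] = False  # wall plane
        f = np.zeros((19, 5, 5, 5))
        (i,) = [
            k
            for k, e in enumerate(lat.velocities)
            if (e == (1, 0, 0)).all()
        ]
        f[i, 2, 2, 2] = 1.0
        out = lb.stream(f, mask, lat)
        assert out[lat.opposite[i], 2, 2, 2] == 1.0

    def test_closed_box_conserves_mass(self, lat, rng):
        dom = closed_box(6)
        mask = dom.fluid_mask
        rho = 1.0 + 0.1 * rng.random(mask.shape)
        f = lb.equilibrium(rho, np.zeros((3,) + mask.shape), lat) * mask
        total = f.sum()
        for _ in range(20):
            f = lb.stream(f, mask, lat)
        assert f.sum() == pytest.approx(total, rel=1e-14)


class TestMacroscopic:
    def test_rest_weights_give_reference_state(self, lat):
        f = np.asarray(lat.weights)[:, None, None, None]
        mac = lb.macroscopic(f, lat=lat)
        assert mac.rho[0, 0, 0] == pytest.approx(1.0, rel=1e-15)
        assert np.allclose(mac.u, 0.0, atol=1e-16)
        assert mac.P[0, 0, 0] == pytest.approx(1.0 / 3.0, rel=1e-15)

    def test_half_force_velocity_correction(self, lat):
        f = lb.equilibrium(1.0, np.zeros(3), lat)[:, None, None, None]
        F = np.zeros((3, 1, 1, 1))
        F[0] = 0.01
        mac = lb.macroscopic(f, F, lat)
        assert mac.u[0, 0, 0, 0] == pytest.approx(0.005, rel=1e-13)

    def test_divergence_error_names_site_and_step(self, lat):
        f = np.zeros((19, 2, 2, 2))
        f[:, 0, 0, 0] = np.asarray(lat.weights)
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(DivergenceError, match=r"\(0, 0, 1\).*step 7"):
            lb.macroscopic(f, lat=lat, fluid_mask=mask, step=7)


def test_closed_domain_mass_conserved_over_1000_steps(lat, rng):
    """Collide+stream in a sealed cavity keeps total mass to 1e-10 relative."""
    dom = closed_box(8)
    mask = dom.fluid_mask
    rho = 1.0 + 0.05 * rng.random(mask.shape)
    u = 0.02 * rng.standard_normal((3,) + mask.shape)
    f = lb.equilibrium(rho, u, lat) * mask
    total0 = f.sum()
    for _ in range(1000):
        f = lb.collide(f, tau=0.9, lat=lat, fluid_mask=mask)
        f = lb.stream(f, mask, lat)
    assert abs(f.sum() - total0) < 1e-10 * total0


def test_equilibrium_fixed_point_full_cycle(lat):
    """One collide+stream on a uniform periodic equilibrium moves nothing."""
    mask = np.ones((6, 6, 6), dtype=bool)
    f = lb.equilibrium(1.0, np.array([0.03, -0.02, 0.01]), lat)[
        :, None, None, None
    ] * mask
    out = lb.stream(lb.collide(f, tau=0.8, lat=lat), mask, lat)
    assert np.abs(out - f).max() < 1e-14
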