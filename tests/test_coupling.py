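"""Coupling map construction, scale factors, and the exchange protocol."""

import numpy as np
import pytest

from vasclbm import coupling as cp
from vasclbm import geometry as geo
from vasclbm.errors import ExchangeError, MappingError


def _patch(pid, kind, x, area=1.0):
    """Planar stand-in patch at position (x, 0, 0)."""
    return geo.BoundaryPatch(
        id=pid,
        kind=kind,
        sites=np.zeros((1, 3), dtype=int),
        centroid=np.array([float(x), 0.0, 0.0]),
        normal=np.array([0.0, 0.0, 1.0]),
        area=area,
    )


def _literal_factor_expression(group):
    """The velocity scale factors written exactly as the ratio-of-ratios
    expression: (A0/Ai) * [dPi L1 Ai / (dP1 Li A1)] / sum_j [dPj L1 Aj /
    (dP1 Lj A1)].  Independent oracle for the simplified w_i form."""
    l1 = group.links[0]
    A0 = group.outlet.area
    terms = [
        (lk.dP_frac * l1.L * lk.inlet.area) / (l1.dP_frac * lk.L * l1.inlet.area)
        for lk in group.links
    ]
    return [
        (A0 / lk.inlet.area) * t / sum(terms)
        for lk, t in zip(group.links, terms)
    ]


class TestBuildMap:
    def test_single_outlet_collects_all_inlets(self):
        out = [_patch(0, "outlet", 0.0)]
        ins = [_patch(i + 1, "inlet", x) for i, x in enumerate((1.0, 2.0, 3.0))]
        cmap = cp.build_coupling_map(out, ins)
        assert len(cmap.groups) == 1
        assert len(cmap.groups[0].links) == 3

    def test_two_pass_assignment_hand_enumerated(self):
        # outlets at x = 0 and 10; inlets at 1, 2, 8, 11.5.
        # pass 1: O0 takes inlet@1, O1 takes inlet@11.5 (its nearest
        # unassigned); pass 2: inlet@2 -> O0, inlet@8 -> O1.
        outs = [_patch(0, "outlet", 0.0), _patch(1, "outlet", 10.0)]
        ins = [
            _patch(10, "inlet", 1.0),
            _patch(11, "inlet", 2.0),
            _patch(12, "inlet", 8.0),
            _patch(13, "inlet", 11.5),
        ]
        cmap = cp.build_coupling_map(outs, ins)
        got = {
            g.outlet.id: sorted(lk.inlet.id for lk in g.links)
            for g in cmap.groups
        }
        assert got == {0: [10, 11], 1: [12, 13]}
        # distances are recorded per link
        g0 = cmap.group_for_outlet(0)
        assert sorted(round(lk.L, 6) for lk in g0.links) == [1.0, 2.0]

    def test_tie_breaks_to_lowest_id(self):
        outs = [_patch(0, "outlet", 0.0)]
        ins = [_patch(5, "inlet", 1.0), _patch(3, "inlet", -1.0)]
        cmap = cp.build_coupling_map(outs, ins)
        first = cmap.groups[0].links[0]
        assert first.inlet.id == 3  # equidistant; lowest id wins pass 1

    def test_production_scale_totality(self):
        outs, ins = geo.make_random_boundary_fixture(38, 494, seed=7)
        cmap = cp.build_coupling_map(outs, ins)
        assigned = [lk.inlet.id for lk in cmap.links]
        assert len(assigned) == 494
        assert len(set(assigned)) == 494
        assert all(len(g.links) >= 1 for g in cmap.groups)
        assert len(cmap.groups) == 38

    def test_totality_over_many_random_fixtures(self):
        """Map totality holds for any feasible random patch cloud."""
        master = np.random.default_rng(2024)
        for _ in range(200):
            n_out = int(master.integers(1, 12))
            n_in = int(master.integers(n_out, n_out * 8 + 1))
            outs, ins = geo.make_random_boundary_fixture(
                n_out, n_in, seed=int(master.integers(0, 2**31))
            )
            cmap = cp.build_coupling_map(outs, ins)
            assert sorted(lk.inlet.id for lk in cmap.links) == sorted(
                p.id for p in ins
            )
            assert {g.outlet.id for g in cmap.groups} == {p.id for p in outs}
            assert min(len(g.links) for g in cmap.groups) >= 1

    def test_infeasible_rejected(self):
        with pytest.raises(MappingError):
            cp.build_coupling_map(
                [_patch(0, "outlet", 0), _patch(1, "outlet", 1)],
                [_patch(2, "inlet", 0.5)],
            )


class TestPressureFactors:
    def test_range_and_determinism(self):
        outs, ins = geo.make_random_boundary_fixture(10, 100, seed=3)
        cmap = cp.build_coupling_map(outs, ins)
        cp.sample_pressure_factors(cmap, rng_seed=11)
        d1 = [lk.dP_frac for lk in cmap.links]
        assert min(d1) >= 0.3 and max(d1) <= 0.7
        cp.sample_pressure_factors(cmap, rng_seed=11)
        assert [lk.dP_frac for lk in cmap.links] == d1

    def test_large_sample_statistics(self):
        outs, ins = geo.make_random_boundary_fixture(1, 10_000, seed=5)
        cmap = cp.build_coupling_map(outs, ins)
        cp.sample_pressure_factors(cmap, rng_seed=99)
        d = np.array([lk.dP_frac for lk in cmap.links])
        assert d.min() >= 0.3 and d.max() <= 0.7
        # U(0.3, 0.7) has mean 0.5
        assert abs(d.mean() - 0.5) < 0.01


class TestVelocityFactors:
    def test_single_link_is_area_ratio(self):
        out = _patch(0, "outlet", 0.0, area=2.0)
        inl = _patch(1, "inlet", 1.0, area=0.5)
        g = cp.CouplingGroup(
            outlet=out, links=[cp.CouplingLink(outlet=out, inlet=inl, L=1.0, dP_frac=0.5)]
        )
        cp.velocity_factors(g)
        assert g.links[0].v_factor == pytest.approx(4.0)

    def test_symmetric_case_reduces_to_pressure_shares(self):
        # equal areas and lengths: factors collapse to dP_i / sum dP_j
        out = _patch(0, "outlet", 0.0)
        dps = (0.30, 0.52, 0.69)
        g = cp.CouplingGroup(
            outlet=out,
            links=[
                cp.CouplingLink(
                    outlet=out, inlet=_patch(i + 1, "inlet", 1.0), L=2.0, dP_frac=dp
                )
                for i, dp in enumerate(dps)
            ],
        )
        cp.velocity_factors(g)
        got = [lk.v_factor for lk in g.links]
        assert got == pytest.approx([0.1987, 0.3444, 0.4570], abs=5e-5)
        # equal areas: the factors sum to A0/A1 = 1 (printed tables round
        # this to values summing near 1, e.g. 1.01)
        assert sum(got) == pytest.approx(1.0, abs=1e-12)

    def test_matches_literal_ratio_expression(self, rng):
        """The w_i = dP A/L form equals the full ratio-of-ratios expression."""
        for _ in range(50):
            n = int(rng.integers(1, 9))
            out = _patch(0, "outlet", 0.0, area=float(rng.uniform(0.5, 3)))
            g = cp.CouplingGroup(
                outlet=out,
                links=[
                    cp.CouplingLink(
                        outlet=out,
                        inlet=_patch(i + 1, "inlet", i, area=float(rng.uniform(0.2, 2))),
                        L=float(rng.uniform(0.5, 10)),
                        dP_frac=float(rng.uniform(0.3, 0.7)),
                    )
                    for i in range(n)
                ],
            )
            cp.velocity_factors(g)
            lit = _literal_factor_expression(g)
            assert [lk.v_factor for lk in g.links] == pytest.approx(lit, rel=1e-12)

    def test_mass_conservation_identity_random_groups(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 21))
            out = _patch(0, "outlet", 0.0, area=float(rng.uniform(0.5, 3)))
            g = cp.CouplingGroup(
                outlet=out,
                links=[
                    cp.CouplingLink(
                        outlet=out,
                        inlet=_patch(i + 1, "inlet", i, area=float(rng.uniform(0.2, 2))),
                        L=float(rng.uniform(0.5, 10)),
                        dP_frac=float(rng.uniform(0.3, 0.7)),
                    )
                    for i in range(n)
                ],
            )
            cp.velocity_factors(g)
            assert abs(g.mass_identity() - 1.0) < 1e-12

    def test_degenerate_link_rejected(self):
        out = _patch(0, "outlet", 0.0)
        g = cp.CouplingGroup(
            outlet=out,
            links=[cp.CouplingLink(outlet=out, inlet=_patch(1, "inlet", 1.0), L=0.0, dP_frac=0.5)],
        )
        with pytest.raises(MappingError):
            cp.velocity_factors(g)


class _FakeInstance:
    """Minimal stand-in exposing the windowed patch means the exchange uses."""

    def __init__(self, means):
        self.means = means

    def windowed_mean_v(self, pid, window):
        return self.means[pid]


def _simple_map(factors=(0.1987, 0.3444, 0.4570), P0=1.0):
    out = _patch(0, "outlet", 0.0)
    links = []
    for i, vf in enumerate(factors):
        lk = cp.CouplingLink(
            outlet=out, inlet=_patch(i + 1, "inlet", i + 1.0), L=1.0, dP_frac=0.5
        )
        lk.v_factor = vf
        links.append(lk)
    return cp.CouplingMap(
        groups=[cp.CouplingGroup(outlet=out, links=links)], P0_ref=P0
    )


class TestExchange:
    def test_forward_scales_outlet_mean(self):
        cmap = _simple_map()
        art = _FakeInstance({0: 0.01})
        targets = cp.forward_exchange(art, cmap)
        assert targets[1][0] == pytest.approx(0.001987)
        assert targets[2][0] == pytest.approx(0.003444)
        assert targets[3][0] == pytest.approx(0.004570)
        # pressure bookkeeping: (1 - dP_frac) P0
        assert targets[1][1] == pytest.approx(0.5)
        assert cmap.direction_state == "reverse"

    def test_forward_zero_outlet_gives_zero_targets(self):
        cmap = _simple_map()
        targets = cp.forward_exchange(_FakeInstance({0: 0.0}), cmap)
        assert all(v == 0.0 for v, _ in targets.values())

    def test_reverse_round_trip_recovers_v0(self):
        cmap = _simple_map()
        cmap.direction_state = "reverse"
        v0 = 0.0123
        ven = _FakeInstance({i + 1: f * v0 for i, f in enumerate((0.1987, 0.3444, 0.4570))})
        targets = cp.reverse_exchange(ven, cmap)
        assert targets[0] == pytest.approx(v0, rel=1e-12)
        assert cmap.direction_state == "forward"

    def test_reverse_arithmetic_oracle(self):
        cmap = _simple_map()
        cmap.direction_state = "reverse"
        ven = _FakeInstance({1: 0.002, 2: 0.003, 3: 0.005})
        targets = cp.reverse_exchange(ven, cmap)
        # mean of (0.002/0.1987, 0.003/0.3444, 0.005/0.4570)
        assert targets[0] == pytest.approx(0.009906, abs=5e-6)

    def test_single_link_reverse_is_inverse_area_ratio(self):
        out = _patch(0, "outlet", 0.0, area=2.0)
        inl = _patch(1, "inlet", 1.0, area=0.5)
        g = cp.CouplingGroup(
            outlet=out, links=[cp.CouplingLink(outlet=out, inlet=inl, L=1.0, dP_frac=0.5)]
        )
        cp.velocity_factors(g)  # v_factor = A0/A1 = 4
        cmap = cp.CouplingMap(groups=[g], direction_state="reverse")
        targets = cp.reverse_exchange(_FakeInstance({1: 0.02}), cmap)
        assert targets[0] == pytest.approx(0.02 * 0.5 / 2.0)

    def test_wrong_phase_and_unset_factors_raise(self):
        cmap = _simple_map()
        with pytest.raises(ExchangeError):
            cp.reverse_exchange(_FakeInstance({}), cmap)
        cmap.links[0].v_factor = np.nan
        with pytest.raises(ExchangeError):
            cp.forward_exchange(_FakeInstance({0: 0.01}), cmap)


class TestRunCoupled:
    def test_decoupled_limit_has_empty_log(self):
        from vasclbm.experiments import coupled_one_to_n_experiment

        res = coupled_one_to_n_experiment(
            n=1, n_steps=30, exchange_period=31, measure_window=10
        )
        assert len(res.log) == 0

    def test_exchange_log_alternates_directions(self):
        from vasclbm.experiments import coupled_one_to_n_experiment

        res = coupled_one_to_n_experiment(
            n=2, n_steps=60, exchange_period=10, measure_window=10
        )
        by_step = res.log.groupby("step")["direction"].first()
        assert list(by_step) == ["forward", "reverse"] * 3

    def test_exchange_period_insensitivity(self):
        """Halving/stretching the swap cadence leaves steady ratios alone."""
        from vasclbm.experiments import coupled_one_to_n_experiment

        r1 = coupled_one_to_n_experiment(
            n=1, dp_fracs=(0.5,), n_steps=1200, exchange_period=1
        )
        r10 = coupled_one_to_n_experiment(
            n=1, dp_fracs=(0.5,), n_steps=1200, exchange_period=10
        )
        assert r1.achieved_ratios[0] == pytest.approx(
            r10.achieved_ratios[0], rel=0.01
        )
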