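"""Tracing-model unit and property tests.

The load-bearing checks: exact N and 15N conservation, agreement of the
one-flux system with its closed-form solution, and the quadrature
behaviour of the time-averaged rates.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nitracer as nt
from nitracer.tracing_model import (
    DEFAULT_KINETIC_KINDS,
    NATURAL_ABUNDANCE,
    TRANSFORM_NAMES,
    average_gross_rates,
    default_grid,
    derived_rate_sums,
    round_half_up,
)


def make_state(**kw):
    base = dict(nh4=50.0, no3=20.0, nlab=30.0, nrec=200.0, nh4ads=5.0)
    base.update(kw)
    return nt.PoolState(**base)


class TestKineticRate:
    @pytest.mark.parametrize("law,substrate,expected", [
        (nt.KineticLaw("first_order", 0.1), 50.0, 5.0),
        (nt.KineticLaw("zero_order", 0.12), 0.0, 0.0),
        (nt.KineticLaw("zero_order", 0.12), 50.0, 0.12),
        (nt.KineticLaw("michaelis_menten", 10.0, km=50.0), 50.0, 5.0),
        (nt.KineticLaw("first_order", 0.0), 100.0, 0.0),
    ])
    def test_law_values(self, law, substrate, expected):
        assert nt.kinetic_rate(law, substrate) == pytest.approx(expected)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            nt.kinetic_rate(nt.KineticLaw("first_order", 0.1), -1.0)

    def test_zero_order_ramps_near_empty_pool(self):
        law = nt.KineticLaw("zero_order", 1.0)
        assert nt.kinetic_rate(law, 0.005) == pytest.approx(0.5)
        assert nt.kinetic_rate(law, 0.02) == pytest.approx(1.0)

    def test_km_only_for_michaelis_menten(self):
        with pytest.raises(ValueError):
            nt.KineticLaw("first_order", 0.1, km=5.0)
        with pytest.raises(ValueError):
            nt.KineticLaw("michaelis_menten", 0.1)


class TestPoolState:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_state(nh4=-1.0)
        with pytest.raises(ValueError):
            make_state(f_nh4=0.001)   # below natural-abundance guard
        with pytest.raises(ValueError):
            nt.PoolState(nh4=1, no3=1, nlab=1, nrec=1, nh4ads=1, time=-0.5)

    def test_vector_round_trip(self):
        s = make_state(f_nh4=0.1, f_no3=0.05)
        back = nt.PoolState.from_vector(s.to_vector(), s.time)
        for pool in ("nh4", "no3", "nlab", "nrec", "nh4ads"):
            assert getattr(back, pool) == pytest.approx(getattr(s, pool))
            assert getattr(back, "f_" + pool) == pytest.approx(
                getattr(s, "f_" + pool))


class TestSimulate:
    def test_all_rates_zero_is_identity(self):
        ts = nt.TransformationSet.from_constants({}, km={"O_NH4": 10.0})
        init = make_state(f_nh4=0.1)
        traj = nt.simulate(ts, init, default_grid())
        for s in traj.states:
            assert s.nh4 == pytest.approx(init.nh4, abs=1e-9)
            assert s.f_nh4 == pytest.approx(init.f_nh4, abs=1e-9)
        assert np.allclose(traj.rates.values, 0.0)

    def test_single_flux_matches_closed_form(self):
        """With only first-order NH4+ oxidation the system is linear:
        NH4+ decays exponentially and the NO3- enrichment is the exact
        two-pool mixing curve."""
        k = 0.8
        n0, m0 = 40.0, 10.0
        f0, f1 = 0.10, NATURAL_ABUNDANCE
        ts = nt.TransformationSet.from_constants(
            {"O_NH4": k}, kinds={"O_NH4": "first_order"})
        init = make_state(nh4=n0, no3=m0, f_nh4=f0, f_no3=f1)
        grid = default_grid()
        traj = nt.simulate(ts, init, grid)
        for t, s in zip(grid, traj.states):
            nh4_exact = n0 * np.exp(-k * t)
            no3_exact = m0 + n0 * (1 - np.exp(-k * t))
            # 15N: influx carries f0, so 15NO3 = m0 f1 + (n0 - nh4) f0
            f_no3_exact = (m0 * f1 + (n0 - nh4_exact) * f0) / no3_exact
            assert s.nh4 == pytest.approx(nh4_exact, abs=1e-6)
            assert s.no3 == pytest.approx(no3_exact, abs=1e-6)
            assert s.f_no3 == pytest.approx(f_no3_exact, abs=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mass_and_isotope_conservation(self, seed):
        """Total N and total 15N over the five pools are conserved for
        random admissible parameter draws (the model has no gaseous sink)."""
        r = np.random.default_rng(seed)
        k = {n: float(r.uniform(0, 2.0)) for n in TRANSFORM_NAMES}
        ts = nt.TransformationSet.from_constants(k, km={"O_NH4": 10.0})
        init = make_state(f_nh4=float(r.uniform(0.004, 0.6)))
        traj = nt.simulate(ts, init, default_grid())
        tot0, iso0 = init.total_n, init.total_n15
        for s in traj.states:
            assert abs(s.total_n - tot0) < 1e-6 * tot0
            assert abs(s.total_n15 - iso0) < 1e-6 * iso0
            for pool in ("nh4", "no3", "nlab", "nrec", "nh4ads"):
                assert getattr(s, pool) >= 0

    def test_grid_must_start_at_init_time(self):
        ts = nt.TransformationSet.from_constants({}, km={"O_NH4": 10.0})
        with pytest.raises(ValueError):
            nt.simulate(ts, make_state(), [1.0, 2.0])


class TestAverageRates:
    def _traj(self, ts, init=None):
        return nt.simulate(ts, init or make_state(), default_grid())

    def test_zero_order_average_is_k(self):
        ts = nt.TransformationSet.from_constants({"M_Nrec": 0.12})
        table = average_gross_rates(ts, self._traj(ts), (0.0, 2.0))
        assert table.rates["M_Nrec"] == pytest.approx(0.12, abs=1e-12)

    def test_first_order_average_matches_quadrature(self):
        """For exponential decay the time-average k*mean(pool) has the
        closed form k * N0 (1 - e^-kT) / (kT); trapezoid on the stored
        grid must agree within 0.1%."""
        k, n0, T = 1.3, 40.0, 2.0
        ts = nt.TransformationSet.from_constants(
            {"O_NH4": k}, kinds={"O_NH4": "first_order"})
        traj = self._traj(ts, make_state(nh4=n0))
        table = average_gross_rates(ts, traj, (0.0, T))
        exact = k * n0 * (1 - np.exp(-k * T)) / (k * T)
        assert table.rates["O_NH4"] == pytest.approx(exact, rel=1e-3)

    def test_invalid_interval_rejected(self):
        ts = nt.TransformationSet.from_constants({})
        traj = self._traj(ts)
        with pytest.raises(ValueError):
            average_gross_rates(ts, traj, (1.0, 1.0))
        with pytest.raises(ValueError):
            average_gross_rates(ts, traj, (0.0, 5.0))

    def test_all_zero_rates_give_undefined_contributions(self):
        ts = nt.TransformationSet.from_constants({})
        table = average_gross_rates(ts, self._traj(ts), (0.0, 2.0))
        assert all(v == 0.0 for v in table.rates.values())
        assert table.contrib_o_nh4_pct is None
        assert table.contrib_m_nlab_pct is None


class TestDerivedSums:
    def test_published_nitrification_composition(self):
        """O_NH4 5.44 + O_Nrec 0.38 give Nit_tot 5.82 with autotrophic
        nitrification contributing 93% (and heterotrophic 7%)."""
        rates = {n: 0.0 for n in TRANSFORM_NAMES}
        rates.update({"O_NH4": 5.44, "O_Nrec": 0.38,
                      "M_Nrec": 2.59, "M_Nlab": 5.80})
        table = derived_rate_sums(nt.RateTable(rates=rates))
        assert table.nit_tot == pytest.approx(5.82)
        assert round_half_up(table.contrib_o_nh4_pct) == 93
        assert round_half_up(100 - table.contrib_o_nh4_pct) == 7
        assert table.m_tot == pytest.approx(8.39)

    def test_sums_are_exact_additions(self):
        rates = {n: 0.1 * (i + 1) for i, n in enumerate(TRANSFORM_NAMES)}
        table = derived_rate_sums(nt.RateTable(rates=rates))
        assert abs(table.m_tot - (rates["M_Nrec"] + rates["M_Nlab"])) < 1e-9
        assert abs(table.i_nh4tot
                   - (rates["I_NH4_Nrec"] + rates["I_NH4_Nlab"])) < 1e-9
        assert 0 <= table.contrib_o_nh4_pct <= 100


def test_transformation_set_requires_all_ten():
    with pytest.raises(ValueError):
        nt.TransformationSet({"O_NH4": nt.KineticLaw("zero_order", 1.0)})


def test_transformation_topology():
    ts = nt.TransformationSet.from_constants({})
    assert ts.source_pool("O_NH4") == "nh4" and ts.sink_pool("O_NH4") == "no3"
    assert ts.source_pool("D_NO3") == "no3" and ts.sink_pool("D_NO3") == "nh4"
    assert ts.source_pool("A_NH4") == "nh4" and ts.sink_pool("A_NH4") == "nh4ads"
    assert ts.source_pool("R_NH4a") == "nh4ads" and ts.sink_pool("R_NH4a") == "nh4"
    assert ts.source_pool("I_NO3") == "no3" and ts.sink_pool("I_NO3") == "nrec"
    assert ts.source_pool("M_Nlab") == "nlab" and ts.sink_pool("M_Nlab") == "nh4"


@pytest.mark.parametrize("x,expected", [
    (0.5, 1), (1.5, 2), (-0.5, -1), (92.5, 93), (-62.5, -63), (2.4, 2)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
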