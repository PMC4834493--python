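import math

import numpy as np
import pandas as pd
import pytest

from flipbind.constants import eyring_prefactor, kt
from flipbind.kinetics import (
    InterfaceSet,
    ShootingEnsemble,
    default_interfaces,
    fit_dissociation,
    rate_from_barrier,
    run_shooting,
    transmission_coefficient,
)
from flipbind.landscape import symmetric_double_well
from flipbind.synth import gen_sensorgram


class TestInterfaces:
    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            InterfaceSet(values=np.array([1.0, 0.5, 2.0]), saddle_s=1.0)

    def test_saddle_outside_span_rejected(self):
        with pytest.raises(ValueError, match="saddle"):
            InterfaceSet(values=np.array([1.0, 2.0]), saddle_s=5.0)

    def test_default_placement(self):
        ifs = default_interfaces(12.0, half_width=1.0, n=5)
        assert np.allclose(ifs.values, [11.0, 11.5, 12.0, 12.5, 13.0])
        assert ifs.saddle_index == 2


class TestShooting:
    def test_interface_in_deep_basin_commits_there(self, profile):
        ifs = InterfaceSet(values=np.array([3.0]), saddle_s=3.0)
        ens = run_shooting(
            profile, ifs, n_traj=100, max_steps=50_000, seed=1, boundaries=(3.0, 15.5)
        )
        assert (ens.records["outcome"] == "bound").all()

    def test_ballistic_saddle_recovers_kappa_one(self):
        land = symmetric_double_well(barrier=4.0)
        ifs = InterfaceSet(values=np.array([0.0]), saddle_s=0.0)
        ens = run_shooting(
            land, ifs, n_traj=400, max_steps=200_000, seed=2, friction=1e-3
        )
        kap = transmission_coefficient(ens)
        assert kap.converged
        assert kap.value == pytest.approx(1.0, abs=0.05)

    def test_high_friction_suppresses_transmission(self):
        land = symmetric_double_well(barrier=4.0)
        ifs = InterfaceSet(values=np.array([0.0]), saddle_s=0.0)
        ens = run_shooting(land, ifs, n_traj=400, max_steps=400_000, seed=3, friction=50.0)
        kap = transmission_coefficient(ens)
        assert kap.value < 0.5

    def test_too_few_trajectories_rejected(self, profile):
        with pytest.raises(ValueError, match="100"):
            run_shooting(profile, default_interfaces(12.0), n_traj=10)

    def test_timeout_warning(self):
        land = symmetric_double_well(barrier=4.0)
        ifs = InterfaceSet(values=np.array([0.0]), saddle_s=0.0)
        with pytest.warns(UserWarning, match="timed out"):
            run_shooting(land, ifs, n_traj=100, max_steps=20, seed=4)

    def test_unconverged_flag_when_nothing_commits_forward(self):
        records = pd.DataFrame(
            {
                "interface": 0.0,
                "start_s": 0.0,
                "v0": np.linspace(-1, 1, 200),
                "outcome": "bound",
                "fpt_ps": 1.0,
            }
        )
        ens = ShootingEnsemble(
            records=records,
            interfaces=InterfaceSet(values=np.array([0.0]), saddle_s=0.0),
            boundaries=(-1.0, 1.0),
            temperature=300.0,
            mass=1.0,
        )
        kap = transmission_coefficient(ens)
        assert not kap.converged
        assert kap.value <= 1.0 / 100


class TestRateFromBarrier:
    def test_zero_barrier_gives_eyring_prefactor(self):
        rate = rate_from_barrier(0.0, 1.0, 300.0)
        assert rate.k == pytest.approx(6.25e12, rel=1e-3)

    def test_rate_identity_holds_exactly(self):
        rate = rate_from_barrier(10.0, 0.037, 300.0)
        assert rate.k == rate.prefactor * rate.kappa * math.exp(-10.0 / kt(300.0))

    def test_doubling_barrier_scales_by_boltzmann_factor(self):
        k1 = rate_from_barrier(5.0, 1.0).k
        k2 = rate_from_barrier(10.0, 1.0).k
        assert k2 / k1 == pytest.approx(math.exp(-5.0 / kt(300.0)), rel=1e-12)

    def test_full_barrier_ballistic_rate_bounds_reported_off_rate(self):
        # kappa=1 at the 16.5 kcal/mol barrier gives ~6 s^-1, an upper
        # bound far above a diffusive ~0.01 s^-1 off-rate
        rate = rate_from_barrier(16.5, 1.0, 300.0)
        assert 4.0 < rate.k < 9.0
        assert rate.k >= 0.0114

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            rate_from_barrier(5.0, 0.0)
        with pytest.raises(ValueError):
            rate_from_barrier(5.0, 1.5)

    def test_implied_kappa_from_reported_rate_is_far_below_one(self):
        # inverting k = (kT/h) kappa exp(-beta dG) for k = 0.0114 s^-1 at
        # dG = 16.5 kcal/mol implies kappa ~ 2e-3: a strongly diffusive
        # barrier crossing
        k_off, dg = 0.0114, 16.5
        kappa_implied = k_off / eyring_prefactor(300.0) * math.exp(dg / kt(300.0))
        assert kappa_implied == pytest.approx(1.9e-3, rel=0.05)
        assert kappa_implied < 0.01


class TestDissociationFit:
    def test_noiseless_curve_recovered_to_six_decimals(self):
        data = gen_sensorgram(0.05, noise=0.0, seed=0)
        fit = fit_dissociation(data)
        assert fit.k_d == pytest.approx(0.05, abs=1e-6)

    def test_half_life_of_generated_curve(self):
        data = gen_sensorgram(0.1, r0=100.0, baseline=0.0, noise=0.0, seed=0)
        r = np.interp([0.0, 6.93, 13.86], data["time_s"], data["response_RU"])
        assert r[1] / r[0] == pytest.approx(0.5, abs=1e-3)
        assert r[2] / r[1] == pytest.approx(0.5, abs=1e-3)

    def test_zero_amplitude_rejected(self):
        data = gen_sensorgram(0.05, r0=0.0, baseline=50.0, noise=0.0, seed=0)
        with pytest.raises(ValueError, match="no dissociation"):
            fit_dissociation(data)

    def test_rising_signal_rejected(self):
        t = np.linspace(0, 100, 200)
        data = pd.DataFrame({"time_s": t, "response_RU": 10.0 + 0.5 * t})
        with pytest.raises(ValueError, match="no dissociation"):
            fit_dissociation(data)

    def test_too_few_points_rejected(self):
        data = pd.DataFrame({"time_s": np.arange(5.0), "response_RU": np.exp(-np.arange(5.0))})
        with pytest.raises(ValueError, match="10 points"):
            fit_dissociation(data)

    def test_rescaling_invariance(self):
        data = gen_sensorgram(0.08, noise=0.5, seed=5)
        k1 = fit_dissociation(data).k_d
        scaled = data.copy()
        scaled["response_RU"] *= 37.5
        k2 = fit_dissociation(scaled).k_d
        assert abs(k1 - k2) < 1e-10
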