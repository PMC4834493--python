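import numpy as np
import pytest

from flipbind.constants import kt
from flipbind.fes import FreeEnergyProfile
from flipbind.thermo import (
    barrier_height,
    basin_free_energy,
    binding_free_energy,
    boltzmann_population,
    combine_cycle,
    cycle_closure,
    find_critical_points,
    population_from_profile,
    standard_state_correction,
    watershed_basins,
)

@pytest.fixture(scope="module")
def profile_fes(profile):
    return FreeEnergyProfile.from_landscape(profile, spacing=0.01)


class TestCriticalPoints:
    def test_default_preset_landmarks(self, profile_fes):
        cp = find_critical_points(profile_fes)
        labels = [m.label for m in cp.minima]
        assert labels[:3] == ["A", "B", "C"]
        # the main unbinding barrier sits at s ~ 12 (highest saddle)
        main = max(cp.saddles, key=lambda p: p.F)
        assert abs(main.s - 12.0) < 0.5
        # the metastable external pose lies at s in [15, 16]
        c = cp["C"]
        assert 15.0 <= c.s <= 16.0

    def test_single_parabola_one_minimum_no_saddle(self):
        g = np.linspace(-3, 3, 301)
        fes = FreeEnergyProfile(grid=g, F=g**2)
        cp = find_critical_points(fes)
        assert len(cp.minima) == 1 and len(cp.saddles) == 0

    def test_two_equal_minima_one_saddle_at_analytic_positions(self):
        # quartic double well F = (s^2 - 1)^2: minima at +-1, saddle at 0
        g = np.linspace(-2, 2, 2001)
        fes = FreeEnergyProfile(grid=g, F=(g**2 - 1.0) ** 2)
        cp = find_critical_points(fes)
        assert len(cp.minima) == 2 and len(cp.saddles) == 1
        assert cp["A"].s == pytest.approx(-1.0, abs=0.01)
        assert cp["B"].s == pytest.approx(1.0, abs=0.01)
        assert cp["TS1"].s == pytest.approx(0.0, abs=0.01)

    def test_flat_profile_warns_and_returns_empty(self):
        fes = FreeEnergyProfile(grid=np.linspace(0, 1, 50), F=np.zeros(50))
        with pytest.warns(UserWarning, match="flat"):
            cp = find_critical_points(fes)
        assert cp.minima == () and cp.saddles == ()

    def test_watershed_basins_partition_grid(self, profile_fes):
        basins = watershed_basins(profile_fes)
        assert set(basins) >= {"A", "B", "C"}
        ivs = sorted(b.interval for b in basins.values())
        for (lo1, hi1), (lo2, _) in zip(ivs, ivs[1:]):
            assert hi1 == pytest.approx(lo2)


class TestBasinFreeEnergy:
    def test_identical_basins_give_zero(self, profile_fes):
        dg, unc = basin_free_energy(profile_fes, (2.0, 4.0), (2.0, 4.0))
        assert dg == 0.0 and unc == 0.0

    def test_two_harmonic_basins_offset_recovered(self):
        # equal-curvature harmonic basins offset by 2.5 kcal/mol
        k = 5.0
        g = np.linspace(-3.0, 9.0, 12001)
        f = np.minimum(0.5 * k * (g - 1.0) ** 2, 2.5 + 0.5 * k * (g - 5.0) ** 2)
        fes = FreeEnergyProfile(grid=g, F=f)
        dg, _ = basin_free_energy(fes, (3.0, 9.0), (-3.0, 3.0))
        assert dg == pytest.approx(2.5, abs=1e-3)

    def test_antisymmetry_exact(self, profile_fes):
        a = basin_free_energy(profile_fes, (0.0, 12.0), (12.0, 19.0))[0]
        b = basin_free_energy(profile_fes, (12.0, 19.0), (0.0, 12.0))[0]
        assert a == -b

    def test_external_pose_4_kcal_above_bound(self, profile, profile_fes):
        # external-pose basin (between the two exit barriers) vs bound basin
        ts1, ts2 = profile.point("TS1").s, profile.point("TS2").s
        dg, _ = basin_free_energy(profile_fes, (ts1, ts2), (0.0, ts1))
        assert dg == pytest.approx(4.0, abs=0.3)

    def test_unsampled_basin_rejected(self):
        g = np.linspace(0, 10, 101)
        f = np.where(g < 5, 0.0, 8.0)
        fes = FreeEnergyProfile(grid=g, F=f.astype(float))
        with pytest.raises(ValueError, match="unsampled"):
            basin_free_energy(fes, (6.0, 9.0), (0.0, 4.0))

    def test_gauge_invariance(self, profile):
        g = np.linspace(0, 30, 3001)
        f = profile.potential(g)
        a = basin_free_energy(FreeEnergyProfile(g, f), (0.0, 12.0), (22.0, 29.0))[0]
        b = basin_free_energy(FreeEnergyProfile(g, f + 123.456), (0.0, 12.0), (22.0, 29.0))[0]
        assert abs(a - b) < 1e-10


class TestStandardState:
    def test_standard_volume_gives_zero(self):
        assert standard_state_correction(1660.0) == 0.0

    def test_tenfold_volume(self):
        assert standard_state_correction(16600.0, 300.0) == pytest.approx(1.372, abs=2e-3)

    def test_sign_symmetric(self):
        assert standard_state_correction(166.0, 300.0) == pytest.approx(
            -standard_state_correction(16600.0, 300.0), abs=1e-12
        )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            standard_state_correction(0.0)

    def test_binding_free_energy_identity(self, profile_fes):
        bfe = binding_free_energy(profile_fes, (0.0, 12.0), (22.0, 29.0), v_unbound=16600.0)
        assert bfe.dg_std == bfe.dg_raw + bfe.correction

    def test_overlapping_basins_rejected(self, profile_fes):
        with pytest.raises(ValueError, match="disjoint"):
            binding_free_energy(profile_fes, (0.0, 12.0), (10.0, 29.0))


class TestCycle:
    def test_flip_bind_route_totals(self):
        cyc = combine_cycle([("path association", -14.0), ("DFG-flip penalty", 6.0)], "flip-bind")
        assert cyc.total == pytest.approx(-8.0)

    def test_bind_flip_route_and_closure(self):
        a = combine_cycle([("path association", -14.0), ("DFG-flip penalty", 6.0)], "flip-bind", uncertainty=1.0)
        b = combine_cycle([("path association", -8.0), ("DFG-flip penalty", 0.0)], "bind-flip", uncertainty=1.0)
        chk = cycle_closure(a, b)
        assert chk["closes"]

    def test_zero_components(self):
        assert combine_cycle([("x", 0.0), ("y", 0.0)], "bind-flip").total == 0.0

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError, match="route"):
            combine_cycle([("x", 1.0)], "sideways")

    def test_nonfinite_component_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            combine_cycle([("x", np.inf)], "flip-bind")


class TestPopulations:
    def test_equal_states_split_evenly(self):
        p = boltzmann_population([3.0, 3.0])
        assert np.allclose(p, [0.5, 0.5])

    def test_point_state_minor_population_at_4_kcal(self):
        p = boltzmann_population([0.0, 4.0], 300.0)
        expected = np.exp(-4.0 / kt(300.0)) / (1.0 + np.exp(-4.0 / kt(300.0)))
        assert p[1] == pytest.approx(expected, rel=1e-12)
        assert p[1] == pytest.approx(0.0012, abs=2e-4)  # about 0.12%

    def test_populations_sum_to_one_at_machine_precision(self):
        p = boltzmann_population([0.0, 1.0, 2.5, 7.0])
        assert abs(p.sum() - 1.0) < 1e-14

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_population([1.0])

    def test_basin_integrated_external_pose_population(self, profile_fes):
        # broad minor basin: integrated population exceeds the point value
        basins = watershed_basins(profile_fes)
        pops = population_from_profile(
            profile_fes, {"bound": basins["A"], "external": basins["C"]}
        )
        assert 0.001 <= pops["external"] <= 0.05
        assert pops["bound"] + pops["external"] == pytest.approx(1.0)


class TestBarriers:
    def test_full_scale_barrier_recovered_exactly(self, full_scale_profile):
        fes = FreeEnergyProfile.from_landscape(full_scale_profile, spacing=0.005)
        dg, _ = barrier_height(fes, (0.0, 12.0), 12.0)
        assert dg == pytest.approx(16.5, abs=1e-3)

    def test_desk_scale_barrier(self, profile_fes):
        dg, _ = barrier_height(profile_fes, (0.0, 12.0), 12.0)
        assert dg == pytest.approx(7.0, abs=1e-3)

    def test_flat_profile_zero_barrier(self):
        fes = FreeEnergyProfile(grid=np.linspace(0, 1, 11), F=np.zeros(11))
        dg, err = barrier_height(fes, (0.0, 0.5), 0.9)
        assert dg == 0.0

    def test_saddle_below_minimum_rejected(self, profile_fes):
        with pytest.raises(ValueError, match="below"):
            barrier_height(profile_fes, (10.0, 14.0), 3.0)

    def test_uncertainty_combines_in_quadrature(self):
        g = np.linspace(0, 10, 101)
        f = (g - 2.0) ** 2 * 0.5
        err = np.full_like(g, 0.3)
        fes = FreeEnergyProfile(grid=g, F=f, err=err)
        _, e = barrier_height(fes, (0.0, 4.0), 8.0)
        assert e == pytest.approx(np.hypot(0.3, 0.3), rel=1e-6)
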