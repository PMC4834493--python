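import math

import numpy as np
import pytest

from flipbind.constants import kt
from flipbind.landscape import asymmetric_double_well, harmonic_well, symmetric_double_well
from flipbind.metad import (
    HillsLog,
    MetadParams,
    default_grid,
    fes_uncertainty,
    read_hills,
    reconstruct_fes,
    replica_exchange_step,
    run_metad,
    write_hills,
)


def make_hills(centers, heights, sigma=0.2, biasf=math.inf):
    n = len(centers)
    return HillsLog(
        time=np.arange(1, n + 1, dtype=float),
        center=np.asarray(centers, dtype=float),
        sigma=np.full(n, sigma),
        height=np.asarray(heights, dtype=float),
        biasf=np.full(n, biasf),
        walker=np.zeros(n, dtype=int),
    )


class TestReconstruction:
    def test_empty_hills_gives_flat_profile_with_warning(self):
        empty = make_hills([], [])
        with pytest.warns(UserWarning, match="empty"):
            fes = reconstruct_fes(empty, grid=np.linspace(0, 1, 11))
        assert np.allclose(fes.F, 0.0)

    def test_single_standard_hill_closed_form(self):
        hills = make_hills([2.0], [1.0], sigma=0.2)
        grid = np.linspace(0.0, 4.0, 401)
        fes = reconstruct_fes(hills, grid)
        # minimum at the hill centre, 1 kcal/mol deep relative to far field
        i0 = np.argmin(fes.F)
        assert grid[i0] == pytest.approx(2.0, abs=0.01)
        assert fes.value_at(0.0) - fes.value_at(2.0) == pytest.approx(1.0, abs=1e-6)

    def test_well_tempered_rescaling_factor(self):
        hills_wt = make_hills([2.0], [1.0], sigma=0.2, biasf=8.0)
        grid = np.linspace(0.0, 4.0, 401)
        fes = reconstruct_fes(hills_wt, grid)
        assert fes.value_at(0.0) - fes.value_at(2.0) == pytest.approx(8.0 / 7.0, abs=1e-6)

    def test_deposition_order_invariance(self):
        rng = np.random.default_rng(0)
        centers = rng.uniform(0, 5, 50)
        heights = rng.uniform(0.05, 0.2, 50)
        grid = np.linspace(-1, 6, 200)
        f1 = reconstruct_fes(make_hills(centers, heights), grid).F
        perm = rng.permutation(50)
        f2 = reconstruct_fes(make_hills(centers[perm], heights[perm]), grid).F
        assert np.max(np.abs(f1 - f2)) < 1e-10

    def test_grid_must_cover_hills(self):
        hills = make_hills([5.0], [1.0])
        with pytest.raises(ValueError, match="cover"):
            reconstruct_fes(hills, grid=np.linspace(0, 4, 41))


class TestRunMetad:
    def test_gamma_must_exceed_one_in_well_tempered_mode(self, harmonic):
        with pytest.raises(ValueError, match="gamma"):
            run_metad(harmonic, MetadParams(gamma=1.0), nsteps=1000)

    def test_pace_minimum(self, harmonic):
        with pytest.raises(ValueError, match="pace"):
            run_metad(harmonic, MetadParams(pace=5), nsteps=1000)

    def test_standard_mode_constant_heights(self, harmonic):
        hills, _ = run_metad(
            harmonic, MetadParams(well_tempered=False, w0=0.1), nsteps=50_000, seed=1
        )
        assert np.allclose(hills.height, 0.1)
        assert np.all(np.isinf(hills.biasf))

    def test_well_tempered_height_at_fixed_point_nonincreasing(self, harmonic):
        # the tempered height w0*exp(-V_bias(s0)/(kB dT)) can only decay at
        # any fixed s0 because the accumulated bias only grows there
        from flipbind.constants import KB

        params = MetadParams(w0=0.1, gamma=6.0)
        hills, _ = run_metad(harmonic, params, nsteps=400_000, seed=2)
        dkt = KB * (params.gamma - 1.0) * 300.0
        s0 = np.array([0.0])
        v = np.array([hills.bias_potential(s0, upto=k)[0] for k in range(len(hills) + 1)])
        h = params.w0 * np.exp(-v / dkt)
        assert np.all(np.diff(h) <= 1e-15)
        assert h[-1] < 0.5 * params.w0  # substantial tempering happened

    def test_bias_flattens_symmetric_double_well(self):
        land = symmetric_double_well(barrier=2.5)
        hills, trajs = run_metad(land, MetadParams(), nsteps=10**6, seed=3)
        s = trajs[0].s
        # after filling, time is split between the wells
        frac_left = (s < 0).mean()
        assert 0.3 < frac_left < 0.7

    def test_multiwalker_matches_single_walker_dg(self):
        land = asymmetric_double_well()
        estimates = []
        for nwalkers, nsteps, seed in ((1, 1_200_000, 5), (4, 300_000, 6)):
            hills, _ = run_metad(land, MetadParams(), nsteps=nsteps, nwalkers=nwalkers, seed=seed)
            grid = default_grid(hills)
            fes = reconstruct_fes(hills, grid)
            beta = 1.0 / kt(300.0)
            w = np.exp(-beta * fes.F)
            m = grid < 3.5
            estimates.append(-np.log(np.trapezoid(w[~m], grid[~m]) / np.trapezoid(w[m], grid[m])) / beta)
        err = fes_uncertainty(hills, grid).mean()
        assert abs(estimates[0] - estimates[1]) < max(4.0 * err, 0.35)

    def test_hills_times_nondecreasing_per_walker(self):
        land = asymmetric_double_well()
        hills, _ = run_metad(land, MetadParams(), nsteps=100_000, nwalkers=3, seed=7)
        for w in range(3):
            t = hills.time[hills.walker == w]
            assert np.all(np.diff(t) >= 0)


class TestUncertainty:
    def test_identical_snapshots_give_zero_uncertainty(self):
        # final-window hills of negligible height leave the profile unchanged
        centers = np.concatenate([np.linspace(1, 3, 40), np.full(10, 2.0)])
        heights = np.concatenate([np.full(40, 0.1), np.full(10, 1e-15)])
        hills = make_hills(centers, heights)
        err = fes_uncertainty(hills, window=10 / 50)
        assert np.max(err) < 1e-12

    def test_constant_offset_removed_by_mean_alignment(self):
        from flipbind.metad import align_profiles

        base = np.sin(np.linspace(0, 3, 60))
        snapshots = np.stack([base, base + 2.5, base - 1.0])
        aligned = align_profiles(snapshots)
        assert np.max(np.std(aligned, axis=0)) < 1e-12
        # alignment over a sub-region behaves the same for pure offsets
        mask = np.zeros(60, dtype=bool)
        mask[10:30] = True
        aligned2 = align_profiles(snapshots, mask)
        assert np.max(np.std(aligned2, axis=0)) < 1e-12

    def test_window_validation(self):
        hills = make_hills(np.linspace(0, 1, 30), np.full(30, 0.1))
        with pytest.raises(ValueError, match="window"):
            fes_uncertainty(hills, window=1.5)
        with pytest.raises(ValueError, match="snapshots"):
            fes_uncertainty(hills, nsnapshots=3)

    def test_error_bar_covers_quadrature_oracle(self):
        from conftest import quadrature_dg

        land = asymmetric_double_well()
        oracle = quadrature_dg(land, 3.5)
        beta = 1.0 / kt(300.0)
        covered = 0
        n_rep = 10
        for seed in range(n_rep):
            hills, _ = run_metad(land, MetadParams(), nsteps=1_200_000, seed=100 + seed)
            grid = default_grid(hills)
            fes = reconstruct_fes(hills, grid)
            err = fes_uncertainty(hills, grid)
            w = np.exp(-beta * fes.F)
            m = grid < 3.5
            dg = -np.log(np.trapezoid(w[~m], grid[~m]) / np.trapezoid(w[m], grid[m])) / beta
            # basin-mean error in quadrature
            e = float(np.hypot(err[m].mean(), err[~m].mean()))
            if abs(dg - oracle) <= 2.0 * max(e, 0.05):
                covered += 1
        assert covered >= 8


class TestReplicaExchange:
    def test_equal_temperatures_always_accepted(self):
        land = harmonic_well(k=2.0)
        x, rec = replica_exchange_step([0.0, 1.5], [300.0, 300.0], land, seed=0)
        assert rec[0][2] and np.allclose(sorted(x), [0.0, 1.5])

    def test_equal_energies_always_accepted(self):
        land = harmonic_well(k=2.0)
        x, rec = replica_exchange_step([1.0, -1.0], [300.0, 450.0], land, seed=0)
        assert rec[0][2]

    def test_mismatched_landscapes_rejected(self):
        a, b = harmonic_well(k=2.0), harmonic_well(k=3.0)
        with pytest.raises(ValueError, match="landscape"):
            replica_exchange_step([0.0, 0.0], [300.0, 400.0], [a, b], seed=0)

    def test_mean_acceptance_matches_monte_carlo_estimate(self):
        # two harmonic replicas: empirical swap acceptance vs a direct
        # Monte-Carlo average of min(1, exp(dbeta dU)) over Boltzmann draws
        k = 2.0
        t1, t2 = 300.0, 450.0
        land = harmonic_well(k=k)
        rng = np.random.default_rng(42)
        n = 40_000
        x1 = rng.normal(0.0, np.sqrt(kt(t1) / k), n)
        x2 = rng.normal(0.0, np.sqrt(kt(t2) / k), n)
        db = 1.0 / kt(t1) - 1.0 / kt(t2)
        du = 0.5 * k * x1**2 - 0.5 * k * x2**2
        oracle = np.minimum(1.0, np.exp(db * du)).mean()
        accepted = 0
        gen = np.random.default_rng(7)
        for i in range(0, n, 10):
            _, rec = replica_exchange_step([x1[i], x2[i]], [t1, t2], land, seed=gen)
            accepted += rec[0][2]
        assert abs(accepted / (n / 10) - oracle) < 0.02


class TestHillsIO:
    def test_round_trip(self, tmp_path):
        hills = make_hills([1.0, 2.0, 3.0], [0.1, 0.09, 0.08], biasf=8.0)
        path = tmp_path / "HILLS"
        write_hills(hills, path)
        back = read_hills(path)
        assert np.allclose(back.center, hills.center)
        assert np.allclose(back.height, hills.height)
        assert back.biasf[0] == 8.0

    def test_header_present(self, tmp_path):
        write_hills(make_hills([1.0], [0.1]), tmp_path / "HILLS")
        first = (tmp_path / "HILLS").read_text().splitlines()[0]
        assert first.startswith("#! FIELDS time s sigma_s height biasf")

    def test_malformed_height_rejected(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time s sigma_s height biasf walker\n1.0 2.0 0.2 -0.5 8.0 0\n")
        with pytest.raises(ValueError, match="height"):
            read_hills(p)

    def test_malformed_width_rejected(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time s sigma_s height biasf walker\n1.0 2.0 0.0 0.5 8.0 0\n")
        with pytest.raises(ValueError, match="width"):
            read_hills(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("1.0 2.0 0.2 0.5 8.0 0\n")
        with pytest.raises(ValueError, match="FIELDS"):
            read_hills(p)
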