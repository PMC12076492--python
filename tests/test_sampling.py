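import numpy as np
import pytest
from scipy import stats

from metacv import (
    KB, DoubleWell, GaussianMixture, Harmonic, Hill, LangevinParams, MetaDBias,
    MetaDSchedule, RatchetBias, SamplingError, WalkerPool, WallRestraint,
    bias_energy, fes_from_hills, integrate, metad_height, ratchet_energy_and_update,
    run_multiple_walkers, wall_energy, read_colvar, read_hills, write_colvar, write_hills,
)


class TestPotentials:
    @pytest.mark.parametrize("pot", [
        DoubleWell(barrier=12.0, separation=5.0, tilt=3.0),
        GaussianMixture(centers=[[0.0, 0.0], [3.0, 1.0]], widths=[1.0, 0.7],
                        depths=[5.0, 8.0]),
        Harmonic(k=2.5, center=[1.0, -1.0]),
    ])
    def test_gradient_matches_finite_differences(self, pot):
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(20):
            s = rng.uniform(-4, 4, size=pot.dimension)
            g = pot.gradient(s)
            for j in range(pot.dimension):
                e = np.zeros(pot.dimension)
                e[j] = h
                fd = (pot.energy(s + e) - pot.energy(s - e)) / (2 * h)
                assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_double_well_barrier_height(self):
        pot = DoubleWell(barrier=15.0, separation=6.0)
        left, right = pot.well_positions()
        assert pot.energy(0.0) - pot.energy(left) == pytest.approx(15.0)
        assert pot.energy(left) == pytest.approx(pot.energy(right))


class TestRatchet:
    def test_lagging_costs_half_k_delta_squared(self):
        bias = RatchetBias(k=5.0, direction=-1, s_best=20.0)
        energy, updated = ratchet_energy_and_update(23.0, bias)
        assert energy == pytest.approx(22.5)
        assert updated.s_best == 20.0

    def test_progress_resets_best_at_zero_cost(self):
        bias = RatchetBias(k=5.0, direction=-1, s_best=20.0)
        energy, updated = ratchet_energy_and_update(19.0, bias)
        assert energy == 0.0 and updated.s_best == 19.0

    def test_boundary_is_free(self):
        bias = RatchetBias(k=5.0, direction=-1, s_best=20.0)
        energy, _ = ratchet_energy_and_update(20.0, bias)
        assert energy == 0.0

    def test_s_best_monotone_over_trajectory(self):
        pot = DoubleWell(barrier=8.0, separation=10.0)
        bias = RatchetBias(k=5.0, direction=1)
        bests = []
        res = integrate(pot, [bias], LangevinParams(seed=1), 5000, record_stride=1,
                        s0=pot.well_positions()[0])
        # replay the recorded CV through the pure ratchet rule
        replay = RatchetBias(k=5.0, direction=1)
        for s in res.cv[:, 0]:
            _, replay = ratchet_energy_and_update(float(s), replay)
            bests.append(replay.s_best)
        assert all(b2 >= b1 for b1, b2 in zip(bests, bests[1:]))

    def test_new_extreme_has_zero_bias_energy(self):
        replay = RatchetBias(k=3.0, direction=1)
        for s in [0.0, 1.0, 0.5, 2.0, 1.5, 3.0]:
            e, replay = ratchet_energy_and_update(s, replay)
            if s == replay.s_best:  # a new extreme was just set
                assert e == 0.0


class TestMetaDHeight:
    SCHED = MetaDSchedule()  # w0=1.2, pace=500, gamma=20, T=300

    def test_zero_bias_gives_initial_height(self):
        assert metad_height(0.0, self.SCHED) == pytest.approx(1.2)

    def test_one_decay_constant(self):
        v = KB * 19 * 300.0
        assert metad_height(v, self.SCHED) == pytest.approx(1.2 / np.e, rel=1e-12)

    def test_infinite_bias_factor_limit(self):
        sched = MetaDSchedule(bias_factor=1e12)
        assert metad_height(50.0, sched) == pytest.approx(1.2, rel=1e-9)

    def test_repeated_deposits_at_same_point_decay(self):
        sched = MetaDSchedule(widths=(0.1,))
        mb = MetaDBias(sched)
        s = np.array([0.0])
        heights = [mb.deposit(s, step).height for step in range(1, 8)]
        assert all(h2 < h1 for h1, h2 in zip(heights, heights[1:]))


class TestBiasEnergy:
    def test_empty_hills(self):
        assert bias_energy(0.0, []) == 0.0

    def test_peak_value_at_center(self):
        h = Hill((1.0,), (0.5,), 2.0, 1)
        assert bias_energy(1.0, [h]) == pytest.approx(2.0)

    def test_one_sigma_value(self):
        h = Hill((0.0,), (0.5,), 2.0, 1)
        assert bias_energy(0.5, [h]) == pytest.approx(2.0 * np.exp(-0.5))

    def test_grid_cache_matches_exact(self):
        sched = MetaDSchedule(widths=(0.1,))
        exact = MetaDBias(sched)
        cached = MetaDBias(sched, grid_range=(-3.0, 3.0))
        rng = np.random.default_rng(2)
        for step, c in enumerate(rng.uniform(-2, 2, 50), start=1):
            exact.deposit(np.array([c]), step)
            cached.deposit(np.array([c]), step)
        for s in rng.uniform(-2.5, 2.5, 20):
            ve, _ = exact.exact_energy_and_gradient(np.array([s]))
            vc, _ = cached.energy_and_gradient(np.array([s]))
            # sigma/5 linear interpolation: sub-percent accuracy on a ~7 kJ/mol bias
            assert vc == pytest.approx(ve, abs=0.03)


class TestWalls:
    WALL = WallRestraint(lower=[0.0], upper=[10.0], kappa=10.0)

    def test_inside_is_free(self):
        assert wall_energy(5.0, self.WALL) == 0.0

    def test_above_upper(self):
        assert wall_energy(11.0, self.WALL) == pytest.approx(10.0)

    def test_below_lower(self):
        assert wall_energy(-2.0, self.WALL) == pytest.approx(40.0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            WallRestraint(lower=[5.0], upper=[1.0])


class TestIntegrator:
    def test_cold_overdamped_descent_is_monotone(self):
        pot = Harmonic(k=2.0, center=[0.0])
        params = LangevinParams(dt=0.002, friction=50.0, temperature=1e-14, mass=10.0, seed=0)
        res = integrate(pot, [], params, 20_000, record_stride=100, s0=4.0)
        dist = np.abs(res.cv[:, 0])
        assert dist[-1] < 1e-3
        assert np.all(np.diff(dist) <= 1e-8)

    def test_same_seed_bitwise_identical(self):
        pot = DoubleWell(barrier=5.0, separation=4.0)
        r1 = integrate(pot, [], LangevinParams(seed=9), 3000, s0=-2.0)
        r2 = integrate(pot, [], LangevinParams(seed=9), 3000, s0=-2.0)
        assert np.array_equal(r1.cv, r2.cv)

    def test_equipartition_in_harmonic_well(self):
        k_well = 2.0
        pot = Harmonic(k=k_well)
        res = integrate(pot, [], LangevinParams(seed=12), 1_000_000, record_stride=10)
        var = res.cv[:, 0].var()
        assert var == pytest.approx(KB * 300.0 / k_well, rel=0.05)

    def test_divergence_reports_step(self):
        pot = Harmonic(k=1e12)
        with np.errstate(over="ignore"), pytest.raises(SamplingError, match="step"):
            integrate(pot, [], LangevinParams(dt=10.0, seed=0), 10_000, s0=1e3)

    def test_boltzmann_histogram_in_harmonic_well(self):
        # detailed-balance sanity: CV samples follow N(0, kBT/k)
        k_well = 2.0
        pot = Harmonic(k=k_well)
        res = integrate(pot, [], LangevinParams(seed=4), 1_000_000, record_stride=10)
        sigma = np.sqrt(KB * 300.0 / k_well)
        ks = stats.kstest(res.cv[:, 0], "norm", args=(0.0, sigma)).statistic
        assert ks < 0.02


class TestWellTempered:
    def test_heights_nonincreasing_in_revisited_regions(self):
        pot = Harmonic(k=0.5)  # confined: CV keeps revisiting the well
        sched = MetaDSchedule(pace=100, widths=(0.5,))
        mb = MetaDBias(sched)
        integrate(pot, [mb], LangevinParams(seed=5), 50_000, record_stride=100)
        hills = mb.hills
        # for hills deposited within half a sigma of one another, later is lower
        for i, hi in enumerate(hills):
            for hj in hills[i + 1:]:
                if abs(hi.center[0] - hj.center[0]) < 0.25 * 0.5:
                    assert hj.height <= hi.height * (1 + 1e-9)

    def test_fes_single_hill_closed_form(self):
        gamma = 20.0
        h = Hill((0.0,), (0.2,), 1.5, 1)
        grid = fes_from_hills([h], [(-5.0, 5.0, 501)], gamma)
        center_idx = 250
        assert grid.values[center_idx] == pytest.approx(0.0, abs=1e-12)
        assert grid.values[0] == pytest.approx(gamma / (gamma - 1.0) * 1.5, rel=1e-6)

    def test_fes_invariant_to_constant_bias_offset(self):
        rng = np.random.default_rng(6)
        hills = [Hill((float(c),), (0.3,), float(h), i)
                 for i, (c, h) in enumerate(zip(rng.uniform(-2, 2, 30),
                                                rng.uniform(0.2, 1.0, 30)))]
        flat = Hill((0.0,), (1e8,), 7.0, 99)  # effectively constant over the grid
        g1 = fes_from_hills(hills, [(-3.0, 3.0, 101)], 20.0)
        g2 = fes_from_hills(hills + [flat], [(-3.0, 3.0, 101)], 20.0)
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-5)


class TestMultipleWalkers:
    POT = DoubleWell(barrier=6.0, separation=3.0)
    SCHED = MetaDSchedule(pace=100, widths=(0.1,))

    def test_single_walker_pool_matches_integrate(self):
        pool = WalkerPool(1, seeds=[3], starts=[-1.5], sync_stride=200)
        combined, results = run_multiple_walkers(pool, self.POT, self.SCHED,
                                                 LangevinParams(seed=3), 2000)
        single = integrate(self.POT, [MetaDBias(self.SCHED)], LangevinParams(seed=3),
                           2000, s0=-1.5)
        assert np.array_equal(results[0].cv, single.cv)
        assert [h.center for h in combined] == [h.center for h in single.hills]

    def test_combined_hills_time_ordered(self):
        pool = WalkerPool(2, seeds=[1, 2], starts=[-1.5, 1.5], sync_stride=250)
        combined, _ = run_multiple_walkers(pool, self.POT, self.SCHED,
                                           LangevinParams(seed=0), 1000)
        keys = [(h.deposit_step, h.walker) for h in combined]
        assert keys == sorted(keys)
        assert {h.walker for h in combined} == {0, 1}

    def test_all_walkers_share_final_bias(self):
        pool = WalkerPool(4, seeds=[1, 2, 3, 4], starts=[-1.5, -1.0, 1.0, 1.5],
                          sync_stride=200)
        combined, results = run_multiple_walkers(pool, self.POT, self.SCHED,
                                                 LangevinParams(seed=0), 2000)
        probe = np.array([0.3])
        v_combined = bias_energy(probe, combined)
        for res in results:
            assert bias_energy(probe, res.hills) == pytest.approx(v_combined, abs=1e-12)


class TestPlumedIO:
    def test_hills_roundtrip(self, tmp_path):
        sched = MetaDSchedule(pace=50, widths=(0.1,))
        mb = MetaDBias(sched)
        res = integrate(DoubleWell(barrier=4.0, separation=3.0), [mb],
                        LangevinParams(seed=1), 500, s0=-1.5)
        path = tmp_path / "HILLS"
        write_hills(path, res.hills, sched.bias_factor, dt=0.01)
        hills, biasf = read_hills(path, dt=0.01)
        assert biasf == pytest.approx(20.0)
        assert [h.deposit_step for h in hills] == [h.deposit_step for h in res.hills]
        np.testing.assert_allclose([h.height for h in hills],
                                   [h.height for h in res.hills], rtol=1e-8)

    def test_colvar_roundtrip(self, tmp_path):
        res = integrate(Harmonic(k=1.0), [], LangevinParams(seed=2), 300, record_stride=10)
        path = tmp_path / "COLVAR"
        write_colvar(path, res.times, res.cv)
        t, cv = read_colvar(path)
        np.testing.assert_allclose(t, res.times)
        np.testing.assert_allclose(cv, res.cv, atol=1e-9)

    def test_missing_header_is_error(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("1.0 2.0 3.0\n")
        with pytest.raises(ValueError, match="FIELDS"):
            read_hills(p)
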