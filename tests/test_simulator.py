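"""Stochastic ensembles: bleaching, exact kinematics, limit equivalences."""

import numpy as np
import pytest

from filafrap import (
    BleachGeometry,
    SimulationConfig,
    bleach,
    initialize_ensemble,
    make_distribution,
    measure_profile,
    moving_fraction,
    simulate_profile,
)
from filafrap.fitting import default_plateau_window
from filafrap.simulator import FilamentEnsemble
from filafrap.theory import evaluate_profile_grid


def _config(sim_type=1, n=2000, geom=None, vlaw=None, llaw=None, **kw):
    geom = geom or BleachGeometry(F=470.0, y0=200.0, y1=210.0)
    return SimulationConfig(
        sim_type,
        n,
        vlaw or make_distribution("gamma", mean=1.0, sd=0.25, cap=40.0),
        llaw or make_distribution("dirac", mean=10.0),
        geom,
        **kw,
    )


def _single_filament(x0, length, v=0.0):
    return FilamentEnsemble(
        1,
        np.array([x0]),
        np.array([length]),
        np.array([[v]]),
        np.array([[np.inf]]),
        np.array([[0.0]]),
        np.array([0.0]),
        np.inf,
    )


class TestBleachRule:
    def setup_method(self):
        self.geom = BleachGeometry(F=100.0, y0=4.0, y1=14.0)

    def test_straddling_filament_keeps_unbleached_tail(self):
        ens = bleach(_single_filament(5.0, 10.0), self.geom)
        assert ens.x0[0] == 4.0
        assert ens.length[0] == pytest.approx(9.0)

    def test_filament_left_of_bleach_unchanged(self):
        ens = bleach(_single_filament(3.0, 10.0), self.geom)
        assert ens.x0[0] == 3.0 and ens.length[0] == 10.0

    def test_fully_invisible_filament_removed(self):
        ens = bleach(_single_filament(20.0, 2.0), self.geom)
        assert ens.n == 0

    def test_double_bleach_rejected(self):
        ens = bleach(_single_filament(3.0, 10.0), self.geom)
        with pytest.raises(ValueError):
            bleach(ens, self.geom)


class TestKinematics:
    def test_right_endpoints_uniform_on_placement_interval(self):
        ens = initialize_ensemble(_config(n=100_000), seed=1)
        se = (470.0 / np.sqrt(12.0)) / np.sqrt(ens.n)
        assert abs(ens.x0.mean() - 235.0) < 3 * se

    def test_type1_displacement_is_velocity_times_time(self):
        cfg = _config(vlaw=make_distribution("dirac", mean=1.0))
        ens = initialize_ensemble(cfg, seed=2)
        np.testing.assert_allclose(ens.positions(5.0) - ens.x0, 5.0)

    def test_type1_has_one_infinite_segment(self):
        ens = initialize_ensemble(_config(), seed=3)
        assert ens.on.shape == (2000, 1) and np.all(np.isinf(ens.on))

    def test_positions_nondecreasing_in_time(self):
        cfg = _config(
            sim_type=3,
            on_law=make_distribution("uniform", mean=1.0),
            off_law=make_distribution("uniform", mean=0.5),
        )
        ens = initialize_ensemble(cfg, seed=4)
        prev = ens.positions(0.0)
        for t in (0.5, 1.0, 3.0, 5.0):
            cur = ens.positions(t)
            assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_query_beyond_schedule_horizon_rejected(self):
        cfg = _config(
            sim_type=2, on_law=make_distribution("uniform", mean=1.0), output_times=(5.0,)
        )
        ens = initialize_ensemble(cfg, seed=5)
        with pytest.raises(ValueError, match="horizon"):
            ens.positions(50.0)


class TestLimitEquivalences:
    def test_zero_pause_law_makes_type3_identical_to_type2(self):
        on = make_distribution("uniform", mean=1.0)
        cfg2 = _config(sim_type=2, on_law=on, seed=7)
        cfg3 = _config(
            sim_type=3, on_law=on, off_law=make_distribution("dirac", mean=0.0), seed=7
        )
        p2 = simulate_profile(cfg2)
        p3 = simulate_profile(cfg3)
        assert np.array_equal(p2.intensity, p3.intensity)

    def test_long_on_durations_make_type2_identical_to_type1(self):
        cfg1 = _config(sim_type=1, seed=7)
        cfg2 = _config(
            sim_type=2, on_law=make_distribution("uniform", bounds=(1e6, 2e6)), seed=7
        )
        assert np.array_equal(
            simulate_profile(cfg1).intensity, simulate_profile(cfg2).intensity
        )

    def test_same_seed_gives_bit_identical_profiles(self):
        cfg = _config(
            sim_type=3,
            on_law=make_distribution("uniform", mean=1.0),
            off_law=make_distribution("uniform", mean=0.5),
            seed=11,
        )
        assert np.array_equal(
            simulate_profile(cfg).intensity, simulate_profile(cfg).intensity
        )


class TestMovingFraction:
    def _ensemble(self, tau_on, tau_off, seed=13, n=20_000):
        cfg = _config(
            sim_type=3,
            n=n,
            on_law=make_distribution("uniform", mean=tau_on),
            off_law=make_distribution("uniform", mean=tau_off),
            output_times=(30.0,),
        )
        return initialize_ensemble(cfg, seed=seed)

    def test_long_run_fraction_is_on_over_cycle(self):
        ens = self._ensemble(1.0, 0.5)
        fr = np.mean([moving_fraction(ens, t) for t in np.linspace(5.0, 30.0, 11)])
        assert fr == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_no_pausing_means_everything_moves(self):
        ens = self._ensemble(1.0, 1e-9)
        assert moving_fraction(ens, 10.0) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_on_off_gives_half(self):
        ens = self._ensemble(1.0, 1.0)
        fr = np.mean([moving_fraction(ens, t) for t in np.linspace(5.0, 30.0, 11)])
        assert fr == pytest.approx(0.5, abs=0.01)

    def test_undefined_for_constant_velocity_types(self):
        ens = initialize_ensemble(_config(), seed=14)
        with pytest.raises(ValueError):
            moving_fraction(ens, 1.0)


class TestProfiles:
    def test_single_filament_covers_exactly_one_bin(self):
        geom = BleachGeometry(F=10.0, y0=9.0, y1=10.0)
        ens = _single_filament(5.0, 1.0)
        curve = measure_profile(ens, geom, [0.0], bin_width=1.0, window=(0.0, 10.0))
        expected = np.zeros(10)
        expected[4] = 1.0  # filament spans (4, 5], the bin [4, 5)
        np.testing.assert_allclose(curve.intensity[0], expected)

    def test_fluorescent_material_is_conserved(self):
        cfg = _config(
            sim_type=3,
            n=5000,
            llaw=make_distribution("uniform", bounds=(0.05, 10.0)),
            on_law=make_distribution("uniform", mean=1.0),
            off_law=make_distribution("uniform", mean=0.5),
            output_times=(0.5, 1.0, 3.0, 5.0),
            bin_width=0.5,
            window=(-20.0, 700.0),
        )
        ens = bleach(initialize_ensemble(cfg, seed=15), cfg.geom)
        curve = measure_profile(ens, cfg.geom, cfg.output_times, 0.5, (-20.0, 700.0))
        totals = curve.intensity.sum(axis=1) * 0.5
        np.testing.assert_allclose(totals, ens.total_fluorescent_length(), rtol=1e-9)

    def test_empty_fluorescent_set_warns_and_returns_zeros(self):
        geom = BleachGeometry(F=100.0, y0=4.0, y1=14.0)
        ens = bleach(_single_filament(20.0, 2.0), geom)
        with pytest.warns(UserWarning, match="empty"):
            curve = measure_profile(ens, geom, [1.0], 1.0, (0.0, 20.0))
        assert not curve.intensity.any()

    def test_type1_profile_converges_to_fixed_length_closed_form(
        self, geom_plateau, gamma_velocity, dirac_length_10
    ):
        # mean-absolute agreement at the Monte-Carlo noise floor (plateau
        # count ~ n*l/F = 425 filaments => ~5% pointwise noise at n=20,000)
        cfg = _config(
            n=20_000,
            vlaw=gamma_velocity,
            llaw=dirac_length_10,
            bin_width=0.5,
            window=(190.0, 235.0),
            seed=17,
        )
        sim = simulate_profile(cfg)
        theo = evaluate_profile_grid(
            geom_plateau,
            sim.times,
            sim.positions,
            velocity_law=gamma_velocity,
            length_law=dirac_length_10,
        )
        plateau = default_plateau_window(geom_plateau)
        s = sim.normalized("plateau_mean", plateau_window=plateau)
        t = theo.normalized("plateau_mean", plateau_window=plateau)
        assert np.mean(np.abs(s.intensity - t.intensity)) < 0.04
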