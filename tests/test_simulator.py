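"""Simulator physics: diffusion step, replenishment, state kinetics,
photon emission and the full multi-particle run."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from trbva.photon_model import ACCEPTOR, DONOR_EX
from trbva.simulator import (DetectionConfig, DiffusionConfig, KineticConfig,
                             emit_photons, entry_radius_table,
                             replenishment_mean, run_simulation,
                             sample_entry_radius, simulate_state_trajectory,
                             step_radial_position)

D, R, W0 = 5e-5, 3.0, 0.4


class TestRadialStep:
    def test_no_diffusion_is_exact(self, rng):
        assert step_radial_position(1.0, 0.0, 1.0, rng) == 1.0

    def test_drift_arithmetic(self, rng):
        # D=5e-5, dt=1, r=1 -> deterministic drift 1e-4 um
        steps = np.array([step_radial_position(1.0, D, 1.0, rng)
                          for _ in range(20000)])
        assert np.isclose(np.mean(steps) - 1.0, 2 * D * 1.0 / 1.0,
                          atol=4 * math.sqrt(2 * D / 20000))
        assert np.isclose(np.var(steps), 2 * D, rtol=0.05)

    def test_reflection_keeps_positive(self, rng):
        r = 1e-4
        for _ in range(200):
            r = step_radial_position(r, D, 1.0, rng)
            assert r > 0


class TestReplenishment:
    def test_long_period_recovers_n0(self):
        n0 = 3.4
        assert replenishment_mean(n0, D, R, 1e12) == pytest.approx(n0,
                                                                   rel=1e-9)

    def test_short_period_vanishes(self):
        # small-T_new asymptotic: n_new/n0 ~ (6/pi^2) sqrt(pi x) with
        # x = D pi^2 T_new / R^2, so the influx vanishes like sqrt(T_new)
        vals = [replenishment_mean(3.4, D, R, t) for t in (1e-3, 1.0, 1e3)]
        assert vals[0] < vals[1] < vals[2]
        x = D * math.pi ** 2 * 1e-3 / R ** 2
        expected = 3.4 * 6 / math.pi ** 2 * math.sqrt(math.pi * x)
        assert vals[0] == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("t_new", [200.0, 1000.0, 5000.0, 50000.0])
    def test_series_matches_volume_quadrature(self, t_new):
        """Independent oracle: integrate 4 pi r^2 c_new(r) numerically."""
        n0 = 3.4

        def c_rel(r):
            x = D * math.pi ** 2 * t_new / R ** 2
            n = np.arange(1, 4000)
            s = np.sum((-1.0) ** n / n * np.sin(n * math.pi * r / R)
                       * np.exp(-x * n ** 2))
            return 1.0 + 2 * R / (math.pi * r) * s

        val, _ = integrate.quad(lambda r: 4 * math.pi * r ** 2 * c_rel(r),
                                1e-9, R, limit=400)
        frac = val / (4.0 / 3.0 * math.pi * R ** 3)
        expected = replenishment_mean(n0, D, R, t_new)
        assert expected == pytest.approx(n0 * frac, rel=1e-6, abs=1e-9)


class TestEntryRadius:
    def test_density_normalises(self):
        _, _, cdf = entry_radius_table(D, R, 1000.0)
        assert cdf[-1] == pytest.approx(1.0)
        assert np.all(np.diff(cdf) >= 0)

    def test_small_period_concentrates_near_boundary(self, rng):
        r = sample_entry_radius(D, R, 50.0, 20000, rng)
        assert np.mean(r) > 0.9 * R

    def test_samples_match_tabulated_cdf(self, rng):
        grid, _, cdf = entry_radius_table(D, R, 1000.0)
        samples = sample_entry_radius(D, R, 1000.0, 100000, rng)
        ks = stats.ks_1samp(samples, lambda x: np.interp(x, grid, cdf))
        assert ks.pvalue > 1e-3


class TestStateTrajectory:
    def test_frozen_when_all_rates_zero(self, rng):
        kin = KineticConfig.two_state(0.0, 0.0, ka=0.0, kd=0.0)
        r_traj = np.full(5000, 2.0)
        s = simulate_state_trajectory(r_traj, 0, kin, rng, s_init=1)
        assert np.all(s == 1)

    def test_dwell_times_and_occupancy_far_from_focus(self, rng):
        """Far from the focus (I ~ 0) the chain is the bare two-state CTMC:
        exponential dwells with mean 1/k, occupancies 1/2 each."""
        k = 2e-3  # 1/us
        kin = KineticConfig.two_state(k, k, ka=0.0, kd=0.0)
        r_traj = np.full(400000, 2.5)
        s = simulate_state_trajectory(r_traj, 0, kin, rng, s_init=1)
        occ = np.mean(s == 1)
        assert abs(occ - 0.5) < 0.05
        # dwell lengths between switches (in steps of 1 us)
        switch = np.flatnonzero(np.diff(s) != 0)
        dwells = np.diff(switch).astype(float)
        assert dwells.mean() == pytest.approx(1.0 / k, rel=0.1)
        # geometric/exponential agreement via KS on the dwell distribution
        ks = stats.ks_1samp(dwells, stats.geom(1 - math.exp(-k)).cdf)
        assert ks.pvalue > 1e-4

    def test_unequal_rates_reach_k0_equilibrium(self, rng):
        kin = KineticConfig.two_state(2e-3, 1e-3, ka=0.0, kd=0.0)
        r_traj = np.full(500000, 2.5)
        s = simulate_state_trajectory(r_traj, 0, kin, rng, s_init=1)
        # p_eq = (1/3, 2/3) over the two FRET states
        obs = np.array([np.sum(s == 1), np.sum(s == 2)])
        # correlated samples widen a chi-square test; require gross agreement
        assert abs(obs[1] / s.size - 2 / 3) < 0.05

    @pytest.mark.parametrize("e1,expected_frac_to_donor", [(0.1, 0.1),
                                                           (0.8, 0.8)])
    def test_bleach_flux_sharing(self, rng, e1, expected_frac_to_donor):
        """At the focus the acceptor bleaches at ka*E and the donor at
        kd*(1-E): with ka = kd the probability that the first bleach is an
        acceptor bleach equals E."""
        kin = KineticConfig(k0=np.zeros((1, 1)), state_e=np.array([e1]),
                            ka=2e-3, kd=2e-3)
        r_traj = np.zeros(6000)  # clamped at the spot centre, I = 1
        first = []
        for _ in range(1500):
            s = simulate_state_trajectory(r_traj, 0, kin, rng, s_init=1)
            left = np.flatnonzero(s != 1)
            if left.size:
                first.append(s[left[0]])
        first = np.asarray(first)
        frac_to_donor_only = np.mean(first == 0)
        se = math.sqrt(expected_frac_to_donor
                       * (1 - expected_frac_to_donor) / first.size)
        assert abs(frac_to_donor_only - expected_frac_to_donor) < 4 * se


class TestEmission:
    def test_zero_rates_give_empty_stream(self, rng):
        det = DetectionConfig(lambda_tot=0.0, lambda_d=0.0, lambda_a=0.0)
        kin = KineticConfig()
        s = emit_photons(np.zeros(10000), np.ones(10000, np.int8), det, kin,
                         rng)
        assert s.n_photons == 0

    def test_acceptor_fraction_is_fret_efficiency_when_ideal(self, rng):
        """Clamped at r=0, E=0.9, gamma=1, beta=alpha=0: the acceptor
        fraction of donor-excitation photons is E within binomial error."""
        det = DetectionConfig(gamma=1.0, leakage=0.0, direct_excitation=0.0,
                              lambda_d=0.0, lambda_a=0.0)
        kin = KineticConfig.two_state(0.0, 0.0, e1=0.1, e2=0.9,
                                      ka=0.0, kd=0.0)
        s = emit_photons(np.zeros(300000), np.full(300000, 2, np.int8),
                         det, kin, rng)
        dex = s.excitation == DONOR_EX
        frac = np.mean(s.channel[dex] == ACCEPTOR)
        n = int(dex.sum())
        assert abs(frac - 0.9) < 4 * math.sqrt(0.9 * 0.1 / n)

    def test_raw_proximity_ratio_with_printed_corrections(self, rng):
        """With gamma=1.16, beta=0.054, alpha=0.048 a state at corrected
        E=0.1 shows an uncorrected proximity ratio of ~0.2."""
        det = DetectionConfig()
        kin = KineticConfig.two_state(0.0, 0.0, ka=0.0, kd=0.0)
        s = emit_photons(np.zeros(400000), np.ones(400000, np.int8),
                         det, kin, rng)
        dex = s.excitation == DONOR_EX
        eps = np.mean(s.channel[dex] == ACCEPTOR)
        # analytic expectation of the emission model
        lam = det.lambda_tot
        r_dd = lam * 0.9
        r_da = lam * (det.gamma * 0.1 + det.leakage * 0.9) \
            + det.direct_excitation * lam / det.gamma_pie
        expected = r_da / (r_da + r_dd)
        assert eps == pytest.approx(expected, abs=0.01)
        assert abs(eps - 0.2) < 0.05

    def test_rate_follows_illumination_profile(self, rng):
        """Photon rate vs radial position follows exp(-2 r^2 / w0^2)."""
        det = DetectionConfig(lambda_d=0.0, lambda_a=0.0)
        kin = KineticConfig.two_state(0.0, 0.0, ka=0.0, kd=0.0)
        radii = np.array([0.0, 0.2, 0.4, 0.6])
        counts = []
        for r in radii:
            s = emit_photons(np.full(150000, r), np.ones(150000, np.int8),
                             det, kin, rng)
            counts.append(s.n_photons)
        counts = np.asarray(counts, float)
        expected = np.exp(-2 * radii ** 2 / W0 ** 2)
        ratio = counts / counts[0]
        slope = np.polyfit(np.log(expected), np.log(ratio), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestFullSimulation:
    def test_expected_initial_particle_count(self):
        # n0 = (4/3) pi R^3 c0 with 50 pM in a 3-um sphere
        assert DiffusionConfig().n0 == pytest.approx(3.405, abs=0.005)

    def test_background_only_when_no_particles(self):
        det = DetectionConfig()
        stream = run_simulation(DiffusionConfig(c0_pm=0.0, t_total_s=5.0),
                                KineticConfig(), det, seed=3)
        t_us = 5e6
        n_d = int(np.sum(stream.channel == 0))
        n_a = int(np.sum(stream.channel == ACCEPTOR))
        assert abs(n_d - det.lambda_d * t_us) < 5 * math.sqrt(
            det.lambda_d * t_us)
        assert abs(n_a - det.lambda_a * t_us) < 5 * math.sqrt(
            det.lambda_a * t_us)

    def test_seeded_runs_are_bit_reproducible(self):
        cfg = DiffusionConfig(t_total_s=3.0)
        a = run_simulation(cfg, KineticConfig(), DetectionConfig(), seed=42)
        b = run_simulation(cfg, KineticConfig(), DetectionConfig(), seed=42)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.channel, b.channel)
        np.testing.assert_array_equal(a.excitation, b.excitation)

    def test_particle_count_stationary(self):
        """After burn-in the sphere occupancy fluctuates around n0 with no
        trend: replenishment balances boundary losses."""
        diff = DiffusionConfig(t_total_s=40.0)
        stream = run_simulation(diff, KineticConfig(), DetectionConfig(),
                                seed=11, store_truth=True)
        truth = stream.metadata["truth"]
        entry = np.asarray(truth["entry_step"], dtype=float)
        exit_ = np.asarray(truth["exit_step"], dtype=float)
        probes = np.linspace(5e6, 39e6, 35)  # us probes after burn-in
        occ = [(np.sum((entry <= p) & (exit_ > p))) for p in probes]
        occ = np.asarray(occ, float)
        assert abs(occ.mean() - diff.n0) < 1.0
        slope = np.polyfit(probes, occ, 1)[0] * 1e6  # particles per second
        assert abs(slope * 34) < 2.5  # no material drift over the window
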