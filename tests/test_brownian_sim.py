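"""Langevin-integrator validation at reduced barriers (<= ~8 k_B*T).

The physiological 17-22 k_B*T regime is covered by the quadrature layer;
single passages there would need >1e9 steps.
"""

import math

import numpy as np
import pytest

from nbratchet import (
    AxialLandscape,
    RadialPotential,
    RatchetEnergies,
    SimConfig,
    StepSizeError,
    build_axial,
    dissociation_time,
    integrate,
    moving_time,
    occupancy_ratio,
    potential_2d,
    sample_first_passage,
    simulate_1d,
    suggest_timestep,
)
from nbratchet.first_passage import _sawtooth_potential
from scipy.integrate import simpson


def flat(x):
    return np.zeros_like(np.asarray(x, dtype=float))


class TestFreeDiffusion:
    def test_msd_matches_2dt(self, env):
        """<x^2> = 2 D t for the force-free integrator, 500 replicates."""
        t_total = 1e-6
        cfg0 = SimConfig(timestep_s=1e-9, max_time_s=t_total, record_stride=1000)
        finals = []
        for i in range(500):
            st = simulate_1d(flat, cfg0.model_copy(update={"seed": i}), env, 0.0,
                             (-150.0, 150.0))
            finals.append(st.x_nm[-1])
        finals = np.asarray(finals)
        msd = np.mean(finals**2)
        expected = 2 * env.diffusion_coefficient_nm2_per_s * t_total
        # var of x^2 for a Gaussian is 2*(2Dt)^2
        sem = expected * math.sqrt(2.0 / finals.size)
        assert abs(msd - expected) < 3 * sem

    def test_msd_2d_both_axes(self, env):
        """The 2-D kernel free-diffuses independently in x and r."""
        ax = AxialLandscape(
            site_positions_nm=np.array([-200.0, 200.0]),
            well_depths_kt=np.array([0.0, 0.0]),
            force_pN=0.0,
            env=env,
        )
        u = potential_2d(ax, r_d_nm=0.5)
        t_total = 5e-7
        dx, dr = [], []
        for i in range(300):
            cfg = SimConfig(timestep_s=1e-9, max_time_s=t_total, record_stride=500,
                            seed=1000 + i)
            st = integrate(u, cfg, env, (0.0, 60.0))
            dx.append(st.x_nm[-1])
            dr.append(st.r_nm[-1] - 60.0)
        expected = 2 * env.diffusion_coefficient_nm2_per_s * t_total
        sem = expected * math.sqrt(2.0 / 300)
        assert abs(np.mean(np.array(dx) ** 2) - expected) < 3 * sem
        assert abs(np.mean(np.array(dr) ** 2) - expected) < 3 * sem


class TestEquipartition:
    def test_harmonic_stationary_variance(self, env):
        """var(x) = k_B*T / curvature in a confining harmonic well."""
        k = 50.0  # kT/nm^2

        def harm(x):
            return 0.5 * k * np.asarray(x, dtype=float) ** 2

        cfg = SimConfig(timestep_s=2e-11, max_time_s=4e-6, seed=5, record_stride=10)
        st = simulate_1d(harm, cfg, env, 0.0, (-0.8, 0.8), l_char_nm=0.8)
        burn = st.x_nm.size // 10
        var = float(np.var(st.x_nm[burn:]))
        assert var == pytest.approx(1.0 / k, rel=0.10)


class TestFirstPassageSampling:
    def test_sawtooth_agrees_with_quadrature(self, env, geom):
        pot = _sawtooth_potential(6.0, 4.0, geom.half_spacing_nm)
        dt = suggest_timestep(pot, 0.0, geom.site_spacing_nm, env, geom.half_spacing_nm)
        cfg = SimConfig(timestep_s=dt, max_time_s=1e-5, seed=1, stop="absorb_at_x")
        res = sample_first_passage(pot, cfg, 0.0, geom.site_spacing_nm, 500, env,
                                   l_char_nm=geom.half_spacing_nm)
        q = moving_time(6.0, 4.0, geom, env).mean_time_s
        assert abs(res.mean_time_s - q) < 3 * res.sem_s

    def test_morse_escape_agrees_with_quadrature(self, env):
        rp = RadialPotential(depth_kt=6.0, range_nm=0.5, escape_distance_nm=4.0)
        dt = suggest_timestep(rp, 0.0, 4.0, env, 0.5)
        cfg = SimConfig(timestep_s=dt, max_time_s=2e-4, seed=2, stop="absorb_at_x")
        res = sample_first_passage(rp, cfg, 0.0, 4.0, 400, env, l_char_nm=0.5)
        q = dissociation_time(rp, env).mean_time_s
        assert abs(res.mean_time_s - q) < 3 * res.sem_s

    def test_step_size_convergence(self, env, geom):
        """Halving the timestep moves the estimate by less than one SEM."""
        pot = _sawtooth_potential(5.0, 3.0, geom.half_spacing_nm)
        dt = suggest_timestep(pot, 0.0, geom.site_spacing_nm, env, geom.half_spacing_nm)
        out = []
        for step in (dt, dt / 2):
            cfg = SimConfig(timestep_s=step, max_time_s=1e-5, seed=9, stop="absorb_at_x")
            out.append(
                sample_first_passage(pot, cfg, 0.0, geom.site_spacing_nm, 300, env,
                                     l_char_nm=geom.half_spacing_nm)
            )
        # the two estimates use independent noise, so the difference has
        # standard error sqrt(sem_a^2 + sem_b^2)
        se_diff = math.hypot(out[0].sem_s, out[1].sem_s)
        assert abs(out[0].mean_time_s - out[1].mean_time_s) < 3 * se_diff

    def test_seed_reproducibility(self, env, geom):
        pot = _sawtooth_potential(4.0, 2.0, geom.half_spacing_nm)
        cfg = SimConfig(timestep_s=2e-12, max_time_s=1e-6, seed=42, stop="absorb_at_x")
        a = sample_first_passage(pot, cfg, 0.0, geom.site_spacing_nm, 50, env,
                                 l_char_nm=geom.half_spacing_nm)
        b = sample_first_passage(pot, cfg, 0.0, geom.site_spacing_nm, 50, env,
                                 l_char_nm=geom.half_spacing_nm)
        np.testing.assert_array_equal(a.samples_s, b.samples_s)

    def test_single_sample_flags_undefined_sem(self, env, geom):
        pot = _sawtooth_potential(2.0, 1.0, geom.half_spacing_nm)
        cfg = SimConfig(timestep_s=2e-12, max_time_s=1e-6, seed=4, stop="absorb_at_x")
        with pytest.warns(RuntimeWarning, match="single sample"):
            res = sample_first_passage(pot, cfg, 0.0, geom.site_spacing_nm, 1, env,
                                       l_char_nm=geom.half_spacing_nm)
        assert res.sem_s is None

    def test_aborts_when_passages_time_out(self, env, geom):
        pot = _sawtooth_potential(8.0, 6.0, geom.half_spacing_nm)
        cfg = SimConfig(timestep_s=2e-12, max_time_s=1e-9, seed=6, stop="absorb_at_x")
        with pytest.raises(RuntimeError, match="increase max_time"):
            sample_first_passage(pot, cfg, 0.0, geom.site_spacing_nm, 20, env,
                                 l_char_nm=geom.half_spacing_nm)

    def test_timestep_guard(self, env, geom):
        pot = _sawtooth_potential(8.0, 6.0, geom.half_spacing_nm)
        with pytest.raises(StepSizeError, match="use timestep"):
            cfg = SimConfig(timestep_s=1e-9, max_time_s=1e-5, seed=0, stop="absorb_at_x")
            sample_first_passage(pot, cfg, 0.0, geom.site_spacing_nm, 10, env,
                                 l_char_nm=geom.half_spacing_nm)


class TestOccupancy:
    @staticmethod
    def boltzmann_ratio(ax):
        """Independent oracle: ratio of basin Boltzmann weights."""
        lo, hi = ax.x_min_nm, ax.x_max_nm
        mid = 0.5 * (lo + hi)
        x = np.linspace(lo, hi, 40001)
        w = np.exp(-ax(x))
        return simpson(w[x <= mid], x=x[x <= mid]) / simpson(w[x >= mid], x=x[x >= mid])

    def test_symmetric_wells_unbiased(self, env):
        e = RatchetEnergies(e2_kt=3.0, e2p_kt=2.99, e0_kt=0.0)
        ax = build_axial(e, env, "dbh_like")  # equal wells of depth 3
        cfg = SimConfig(timestep_s=2e-12, max_time_s=1.6e-5, seed=21)
        res = occupancy_ratio(ax, cfg, env)
        assert abs(res.ratio - 1.0) < 3 * res.sem

    def test_biased_wells_match_boltzmann_weights(self, env):
        e = RatchetEnergies(e2_kt=4.0, e2p_kt=2.0, e0_kt=0.0)
        ax = build_axial(e, env, "dpo4_like")  # depths 4 and 2
        cfg = SimConfig(timestep_s=1e-12, max_time_s=2.4e-5, seed=22)
        res = occupancy_ratio(ax, cfg, env)
        expected = self.boltzmann_ratio(ax)
        # 3 SEM plus a 3% allowance for the O(sqrt(dt)) wall bias
        assert abs(res.ratio - expected) < 3 * res.sem + 0.03 * expected

    def test_backward_load_deepens_pre_translocation_bias(self, env):
        e = RatchetEnergies(e2_kt=4.0, e2p_kt=2.0, e0_kt=0.0)
        ax0 = build_axial(e, env, "dpo4_like")
        axf = build_axial(e, env, "dpo4_like", force_pN=12.18)  # F*p = 1 kT
        cfg = SimConfig(timestep_s=1e-12, max_time_s=2.4e-5, seed=23)
        r0 = occupancy_ratio(ax0, cfg, env)
        rf = occupancy_ratio(axf, cfg, env)
        expected = self.boltzmann_ratio(axf)
        assert rf.ratio > r0.ratio
        assert abs(rf.ratio - expected) < 3 * rf.sem + 0.03 * expected

    def test_warns_when_crossings_scarce(self, env):
        e = RatchetEnergies(e2_kt=5.0, e2p_kt=3.0, e0_kt=0.0)
        ax = build_axial(e, env, "dpo4_like")
        cfg = SimConfig(timestep_s=2e-12, max_time_s=8e-7, seed=24)
        with pytest.warns(RuntimeWarning, match="crossings"):
            occupancy_ratio(ax, cfg, env, min_crossings=100_000, max_widenings=1)


class TestIntegrate2D:
    def test_radial_escape_with_flat_axial_channel(self, env):
        """With a nearly flat axial landscape the 2-D escape reduces to the
        1-D Morse problem; the coupled integrator must reproduce the
        quadrature (the regime where the model's factorization is exact)."""
        ax = AxialLandscape(
            site_positions_nm=np.array([0.0, 0.34]),
            well_depths_kt=np.array([6.0, 6.0]),
            force_pN=0.0,
            env=env,
            barrier_kt=-5.9,
        )
        u = potential_2d(ax, r_d_nm=0.5)
        rp = RadialPotential(depth_kt=6.0, range_nm=0.5, escape_distance_nm=4.0)
        q = dissociation_time(rp, env).mean_time_s
        fps = []
        for i in range(150):
            cfg = SimConfig(timestep_s=3e-11, max_time_s=2e-4, seed=100 + i,
                            stop="absorb_at_r", absorb_r_nm=4.0)
            st = integrate(u, cfg, env, (0.0, 0.0))
            assert st.dissociation_count == 1
            fps.append(st.first_passage_s)
        fps = np.asarray(fps, dtype=float)
        sem = fps.std(ddof=1) / math.sqrt(fps.size)
        assert abs(fps.mean() - q) < 3 * sem

    def test_occupancy_fractions_sum_to_one(self, env):
        e = RatchetEnergies(e2_kt=4.0, e2p_kt=3.0, e0_kt=1.0)
        ax = build_axial(e, env, "dpo4_like")
        u = potential_2d(ax, r_d_nm=0.5)
        cfg = SimConfig(timestep_s=2e-12, max_time_s=2e-7, seed=8, record_stride=10)
        st = integrate(u, cfg, env, (0.0, 0.0))
        assert sum(st.occupancy.values()) == pytest.approx(1.0)
        assert st.n_steps == int(cfg.max_time_s / cfg.timestep_s)

    def test_deterministic_given_seed(self, env):
        e = RatchetEnergies(e2_kt=4.0, e2p_kt=3.0, e0_kt=1.0)
        u = potential_2d(build_axial(e, env, "dpo4_like"), r_d_nm=0.5)
        cfg = SimConfig(timestep_s=2e-12, max_time_s=1e-7, seed=77, record_stride=10)
        a = integrate(u, cfg, env, (0.0, 0.0))
        b = integrate(u, cfg, env, (0.0, 0.0))
        np.testing.assert_array_equal(a.x_nm, b.x_nm)
        np.testing.assert_array_equal(a.r_nm, b.r_nm)
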