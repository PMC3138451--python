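"""Cycle-level observables: processivity, force response, synthesis rate.

One incorporation cycle of the nucleotide-binding-rectification ratchet:
after chemistry and pyrophosphate release the polymerase sits at the
pre-translocation site n and hops thermally between sites n and n+1; a
dNTP can bind only at n+1, and once bound it sterically blocks the
backward hop (the rectification).  Activation of the ternary complex then
locks the enzyme until the nucleotide is incorporated.

The polymerase can fall off the DNA only in the two vulnerable windows:
the hopping window of duration T_p1 and the bound-but-unactivated window
of duration T_p2.  With P_d(E_r) = 1/T_d(E_r) the escape rate from a
Morse well of depth E_r = E_site + E0, the per-cycle dissociation
probabilities are P_d1 ~ C * P_d(E_m + E0) * T_p1 (m the deeper well,
C ~ 1-2) and P_d2 = P_d(E_{n+1} + E0) * T_p2, and the processivity is
N_p = 1/(P_d1 + P_d2) nucleotides per binding event.  For Dpo4-like
enzymes (E_n > E_{n+1}, T_p1 < T_p2 at saturating dNTP) the P_d1 term is
negligible and N_p = 1/P_d2 = T_d/T_p2.

A backward load F repartitions the hop window (dwell ratio
rho(F) = exp[(dE + F p)/k_B T]), reducing the fraction of time the dNTP
site is accessible; the binding rate scales as
R(F) = k_b(F)/k_b(0) = (1 + rho(0))/(1 + rho(F)) and the synthesis rate
follows Michaelis-Menten kinetics with K_m rescaled by 1/R(F):
k(F, S) = k_c S / (S + K_m0/R(F)).  k is therefore bounded by k_c,
independent of viscosity, while N_p and T_d scale linearly with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .core_units import Geometry, ThermalEnvironment, force_times_length_kt
from .first_passage import dissociation_time, dwell_ratio, moving_time
from .landscape import RadialPotential, RatchetEnergies, site_affinities

__all__ = [
    "KineticParams",
    "ProcessivityResult",
    "dissociation_rate",
    "processivity",
    "processivity_from_depth",
    "binding_rate_factor",
    "synthesis_rate",
    "cycle_monte_carlo",
]


class KineticParams(BaseModel):
    """Cycle timing and catalysis constants.

    ``t_p1_s``/``t_p2_s`` are the two vulnerable windows (before dNTP
    binding / after binding but before activation); ``t_p1_s = None``
    applies the default T_p1 = T_p2/2 (shorter than T_p2 at saturating
    dNTP).  ``c_factor`` is the order-unity prefactor of the P_d1 term.
    ``k_c_per_s`` and ``k_m0_M`` are the saturating incorporation rate and
    the zero-force Michaelis concentration.
    """

    model_config = ConfigDict(frozen=True)

    t_p1_s: Optional[float] = Field(None, gt=0)
    t_p2_s: float = Field(0.065, gt=0)
    c_factor: float = Field(1.5, ge=1.0, le=2.0)
    k_c_per_s: float = Field(..., gt=0)
    k_m0_M: float = Field(..., gt=0)
    dntp_conc_M: float = Field(1e-3, gt=0)

    @property
    def t_p1_resolved_s(self) -> float:
        return self.t_p1_s if self.t_p1_s is not None else 0.5 * self.t_p2_s


@dataclass(frozen=True)
class ProcessivityResult:
    """Processivity and the per-cycle dissociation probabilities behind it.

    ``n_p`` is the mean number of nucleotides incorporated per binding
    event (may be ``inf`` when dissociation is switched off in the
    stochastic simulator); ``n_p = 1/(p_d1 + p_d2)`` within rounding.
    """

    n_p: float
    p_d1: float
    p_d2: float
    t_d_s: dict[str, float]
    method: Literal["analytic", "monte_carlo"] = "analytic"
    n_p_sem: Optional[float] = None
    velocity_nt_per_s: Optional[float] = None
    velocity_sem: Optional[float] = None
    n_traj: Optional[int] = None


def dissociation_rate(
    e_r_kt: float, geom: Geometry, env: ThermalEnvironment
) -> float:
    """Dissociation rate P_d = 1/T_d (s^-1) from a well of depth E_r.

    Falls off essentially as exp(-E_r) and is inversely proportional to
    the viscosity.  For E_r = 0 it reduces to the free-diffusion escape
    rate 2D/L^2.
    """
    if e_r_kt < 0:
        raise ValueError("E_r must be non-negative")
    rp = RadialPotential(
        depth_kt=e_r_kt,
        range_nm=geom.radial_range_nm,
        escape_distance_nm=geom.escape_distance_nm,
    )
    return 1.0 / dissociation_time(rp, env).mean_time_s


def processivity_from_depth(
    e_r_kt: float, kp: KineticParams, geom: Geometry, env: ThermalEnvironment
) -> float:
    """Dpo4-like processivity N_p = T_d(E_r)/T_p2 for a given well depth."""
    return 1.0 / (dissociation_rate(e_r_kt, geom, env) * kp.t_p2_s)


def processivity(
    energies: RatchetEnergies,
    kp: KineticParams,
    geom: Geometry,
    env: ThermalEnvironment,
    mode: Literal["dpo4_like", "dbh_like"],
    scenario: Optional[str] = None,
) -> ProcessivityResult:
    """Mean number of nucleotides incorporated per DNA-binding event.

    ``mode`` selects which dissociation windows matter: ``dpo4_like``
    (E_n > E_{n+1}; only the post-binding window counts, N_p = 1/P_d2)
    or ``dbh_like`` (both windows, N_p = 1/(P_d1 + P_d2)).  ``scenario``
    defaults to ``mode`` and may be set to ``lesion_at_n`` to evaluate the
    lesion-site processivity with the same window bookkeeping.
    """
    scen = scenario or mode
    e_n, e_n1 = site_affinities(energies, scen)  # type: ignore[arg-type]
    e0 = energies.e0_for(e_n1)
    rate_n1 = dissociation_rate(e_n1 + e0, geom, env)
    p_d2 = rate_n1 * kp.t_p2_s
    e_m = max(e_n, e_n1)  # the deeper well dominates the hop window
    rate_m = dissociation_rate(e_m + e0, geom, env)
    p_d1 = kp.c_factor * rate_m * kp.t_p1_resolved_s
    if mode == "dpo4_like":
        if e_n <= e_n1:
            raise ValueError("dpo4_like mode requires E_n > E_{n+1}")
        n_p = 1.0 / p_d2
    elif mode == "dbh_like":
        n_p = 1.0 / (p_d1 + p_d2)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return ProcessivityResult(
        n_p=n_p,
        p_d1=p_d1,
        p_d2=p_d2,
        t_d_s={"site_n1": 1.0 / rate_n1, "deeper_site": 1.0 / rate_m},
    )


def binding_rate_factor(
    delta_e_kt: float, force_pN: float, geom: Geometry, env: ThermalEnvironment
) -> float:
    """Force dependence of the dNTP-binding rate, R(F) = k_b(F)/k_b(0).

    The dNTP can bind only while the active site occupies the
    post-translocation site, i.e. during a fraction 1/(1 + rho(F)) of the
    hop window, where rho is the dwell ratio T_n/T_{n+1}; hence
    R(F) = (1 + rho(0))/(1 + rho(F)), equal to 1 at F = 0 and strictly
    decreasing with backward force.
    """
    rho0 = dwell_ratio(delta_e_kt, 0.0, geom, env)
    rho_f = dwell_ratio(delta_e_kt, force_pN, geom, env)
    return (1.0 + rho0) / (1.0 + rho_f)


def synthesis_rate(
    kp: KineticParams,
    delta_e_kt: float,
    force_pN: float,
    geom: Geometry,
    env: ThermalEnvironment,
    dntp_conc_M: Optional[float] = None,
) -> float:
    """DNA-synthesis rate k(F, S) = k_c S / (S + K_m0 / R(F)), in s^-1.

    The load enters only through the binding-rate factor R(F), so the
    saturating rate k_c is force independent and the whole expression is
    viscosity independent.
    """
    s = kp.dntp_conc_M if dntp_conc_M is None else dntp_conc_M
    r = binding_rate_factor(delta_e_kt, force_pN, geom, env)
    return kp.k_c_per_s * s / (s + kp.k_m0_M / r)


def cycle_monte_carlo(
    energies: RatchetEnergies,
    kp: KineticParams,
    geom: Geometry,
    env: ThermalEnvironment,
    mode: Literal["dpo4_like", "dbh_like"] = "dpo4_like",
    seed: int = 0,
    n_traj: int = 200,
    *,
    dntp_conc_M: Optional[float] = None,
    no_dissociation: bool = False,
    n_cycles_if_no_dissociation: int = 50,
    max_cycles: int = 1_000_000,
) -> ProcessivityResult:
    """Event-driven stochastic simulation of the incorporation cycle.

    Each cycle starts at the pre-translocation site after pyrophosphate
    release.  States and exponential waiting times:

    * at site n: forward hop (rate 1/T_{n->n+1}) or dissociation
      (rate P_d(E_n + E0));
    * at site n+1 unbound: backward hop (1/T_{(n+1)->n}), dNTP binding
      (pseudo-first-order (k_c/K_m0)(1 + rho_0) S), or dissociation
      (P_d(E_{n+1} + E0));
    * bound, unactivated: activation (1/T_p2) or dissociation; the bound
      nucleotide sterically blocks the backward hop (rectification);
    * activated: locked (no dissociation); the residual catalytic time
      max(1/k_c - T_p2, 0) completes the cycle.

    Returns the mean processivity with standard error and the mean
    synthesis velocity.  With ``no_dissociation=True`` every dissociation
    channel is switched off, N_p is reported as ``inf`` and the velocity
    is measured over a fixed number of cycles per trajectory.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    s_conc = kp.dntp_conc_M if dntp_conc_M is None else dntp_conc_M
    e_n, e_n1 = site_affinities(energies, mode)
    e0 = energies.e0_for(e_n1)

    t_fwd = moving_time(e_n, e_n1, geom, env, method="closed_form").mean_time_s
    t_bwd = moving_time(e_n1, e_n, geom, env, method="closed_form").mean_time_s
    k_fwd, k_bwd = 1.0 / t_fwd, 1.0 / t_bwd
    k_dis_n = 0.0 if no_dissociation else dissociation_rate(e_n + e0, geom, env)
    k_dis_n1 = 0.0 if no_dissociation else dissociation_rate(e_n1 + e0, geom, env)
    rho0 = math.exp(e_n - e_n1)
    k_bind = (kp.k_c_per_s / kp.k_m0_M) * (1.0 + rho0) * s_conc
    k_act = 1.0 / kp.t_p2_s
    t_residual = max(1.0 / kp.k_c_per_s - kp.t_p2_s, 0.0)
    for name, rate in [("forward hop", k_fwd), ("backward hop", k_bwd),
                       ("binding", k_bind), ("activation", k_act)]:
        if not (rate > 0 and math.isfinite(rate)):
            raise ValueError(f"invalid {name} rate: {rate}")

    # The hop window is a two-state chain (site n <-> site n+1) absorbed by
    # binding (at n+1 only) or dissociation (either site).  Because binding
    # can be many orders of magnitude slower than hopping, the window is
    # sampled exactly instead of hop by hop: the number of n -> n+1 rounds
    # before absorption is geometric, the accumulated residence times are
    # Gamma sums of the per-visit exponentials, and the absorbing event is
    # drawn from the per-round branch probabilities.  This is an exact
    # sampler of the same exponential-waiting-time process.
    k_out_n = k_fwd + k_dis_n
    k_out_n1 = k_bind + k_bwd + k_dis_n1
    p_dis_at_n = k_dis_n / k_out_n
    p_bind_visit = k_bind / k_out_n1
    p_dis_visit = k_dis_n1 / k_out_n1
    p_round = p_dis_at_n + (1.0 - p_dis_at_n) * (p_bind_visit + p_dis_visit)
    p_bound_act = k_act / (k_act + k_dis_n1)

    counts = np.empty(n_traj)
    times = np.empty(n_traj)
    for i in range(n_traj):
        rng = np.random.default_rng(seed + i)
        n_inc = 0
        t_tot = 0.0
        alive = True
        while alive:
            if no_dissociation and n_inc >= n_cycles_if_no_dissociation:
                break
            if n_inc >= max_cycles:
                break
            # hop window, starting at site n
            n_rounds = int(rng.geometric(p_round))
            u = rng.random() * p_round
            if u < p_dis_at_n:
                bound, visits_n1 = False, n_rounds - 1
            elif u < p_dis_at_n + (1.0 - p_dis_at_n) * p_bind_visit:
                bound, visits_n1 = True, n_rounds
            else:
                bound, visits_n1 = False, n_rounds
            t_tot += rng.gamma(n_rounds, 1.0 / k_out_n)
            if visits_n1 > 0:
                t_tot += rng.gamma(visits_n1, 1.0 / k_out_n1)
            if not bound:
                alive = False
                break
            # bound, unactivated: activation vs dissociation race
            t_tot += rng.exponential(1.0 / (k_act + k_dis_n1))
            if rng.random() >= p_bound_act:
                alive = False
                break
            # activated and locked: residual catalytic time, then incorporate
            if t_residual > 0:
                t_tot += rng.exponential(t_residual)
            n_inc += 1
        counts[i] = n_inc
        times[i] = t_tot

    mean_np = float(np.mean(counts))
    sem_np = float(np.std(counts, ddof=1) / math.sqrt(n_traj)) if n_traj > 1 else float("nan")
    # pooled velocity (total incorporations / total time) avoids the 1/T bias
    # of averaging per-trajectory ratios; the SEM comes from their spread
    mean_v = float(np.sum(counts) / np.sum(times))
    velocities = counts / times
    sem_v = float(np.std(velocities, ddof=1) / math.sqrt(n_traj)) if n_traj > 1 else float("nan")
    p_d2 = k_dis_n1 * kp.t_p2_s
    p_d1 = kp.c_factor * min(k_dis_n, k_dis_n1) * kp.t_p1_resolved_s
    return ProcessivityResult(
        n_p=float("inf") if no_dissociation else mean_np,
        p_d1=p_d1,
        p_d2=p_d2,
        t_d_s={
            "site_n1": float("inf") if no_dissociation else 1.0 / k_dis_n1,
            "deeper_site": float("inf") if no_dissociation else 1.0 / min(k_dis_n, k_dis_n1),
        },
        method="monte_carlo",
        n_p_sem=None if no_dissociation else sem_np,
        velocity_nt_per_s=mean_v,
        velocity_sem=sem_v,
        n_traj=n_traj,
    )
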