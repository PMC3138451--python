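"""Overdamped Langevin dynamics on the ratchet landscapes.

Stochastic cross-check of the deterministic MFPT layer.  The motion is
inertia-free: each coordinate obeys

    Gamma dq/dt = -dU/dq + xi(t),   <xi_i(t) xi_j(t')> = 2 k_B T Gamma delta_ij delta(t-t'),

discretized by the Euler-Maruyama scheme.  Working in nm / k_B*T / s units
the update is

    q_{k+1} = q_k - (dU/dq)(q_k) * D * dt + sqrt(2 D dt) * N(0, 1),

with D in nm^2/s, so drag and temperature enter only through D.  Reflecting
walls are realized by mirroring the overshoot; absorbing boundaries by
first touch.  Each trajectory owns a generator seeded as
``master_seed + trajectory_index``, making results independent of batching.

Validation runs use reduced barriers (<= ~10 k_B*T): at the physiological
17-22 k_B*T depths a single passage would take >> 1e9 steps, which is the
regime the quadrature layer covers analytically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
from numba import njit
from pydantic import BaseModel, ConfigDict, Field

from .core_units import ThermalEnvironment
from .first_passage import FPTResult
from .landscape import Potential2D

__all__ = [
    "SimConfig",
    "TrajectoryStats",
    "OccupancyResult",
    "StepSizeError",
    "suggest_timestep",
    "integrate",
    "simulate_1d",
    "sample_first_passage",
    "occupancy_ratio",
]

#: maximum deterministic displacement per step, as a fraction of the
#: characteristic length (half site spacing or Morse range).
DRIFT_FRACTION = 0.05


class StepSizeError(ValueError):
    """Timestep violates the drift-per-step bound; message suggests one."""


class SimConfig(BaseModel):
    """Integration controls for the Langevin runs."""

    model_config = ConfigDict(frozen=True)

    timestep_s: float = Field(..., gt=0)
    max_time_s: float = Field(..., gt=0)
    seed: int = 0
    record_stride: int = Field(100, ge=1)
    stop: Literal["absorb_at_x", "absorb_at_r", "fixed_time"] = "fixed_time"
    absorb_x_nm: Optional[float] = None
    absorb_r_nm: Optional[float] = None


@dataclass
class TrajectoryStats:
    """Recorded trajectory plus summary statistics."""

    times_s: np.ndarray
    x_nm: np.ndarray
    r_nm: Optional[np.ndarray]
    first_passage_s: Optional[float]
    occupancy: dict[int, float]
    dissociation_count: int
    n_steps: int
    config: SimConfig


# ---------------------------------------------------------------------------
# numba kernels: potentials enter as lookup tables (position grid + slope
# grid, linearly interpolated), which keeps the inner loop allocation-free.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_1d(
    seed, x0, xg, sg, d_nm2, dt, max_steps,
    reflect_lo, reflect_hi, absorb_lo, absorb_hi, stride, rec,
):
    np.random.seed(seed)
    sig = math.sqrt(2.0 * d_nm2 * dt)
    x = x0
    n_rec = 0
    for k in range(max_steps):
        slope = np.interp(x, xg, sg)
        x += -slope * d_nm2 * dt + sig * np.random.normal()
        if x <= absorb_lo or x >= absorb_hi:
            return 1, (k + 1) * dt, k + 1, n_rec
        if x < reflect_lo:
            x = 2.0 * reflect_lo - x
        elif x > reflect_hi:
            x = 2.0 * reflect_hi - x
        if (k + 1) % stride == 0 and n_rec < rec.shape[0]:
            rec[n_rec] = x
            n_rec += 1
    return 0, max_steps * dt, max_steps, n_rec


@njit(cache=True)
def _run_2d(
    seed, x0, r0, xg, vg, sg, rd, d_nm2, dt, max_steps,
    reflect_x_lo, reflect_x_hi, absorb_x_lo, absorb_x_hi, absorb_r,
    stride, rec_x, rec_r,
):
    np.random.seed(seed)
    sig = math.sqrt(2.0 * d_nm2 * dt)
    x = x0
    r = r0
    n_rec = 0
    for k in range(max_steps):
        g = 2.0 * math.exp(-r / rd) - math.exp(-2.0 * r / rd)
        dg = (2.0 / rd) * (math.exp(-2.0 * r / rd) - math.exp(-r / rd))
        v = np.interp(x, xg, vg)
        s = np.interp(x, xg, sg)
        x += -(s * g) * d_nm2 * dt + sig * np.random.normal()
        r += -(v * dg) * d_nm2 * dt + sig * np.random.normal()
        if r < 0.0:
            r = -r  # Morse form defined for r >= 0
        if r >= absorb_r or x <= absorb_x_lo or x >= absorb_x_hi:
            return 1, (k + 1) * dt, k + 1, n_rec
        if x < reflect_x_lo:
            x = 2.0 * reflect_x_lo - x
        elif x > reflect_x_hi:
            x = 2.0 * reflect_x_hi - x
        if (k + 1) % stride == 0 and n_rec < rec_x.shape[0]:
            rec_x[n_rec] = x
            rec_r[n_rec] = r
            n_rec += 1
    return 0, max_steps * dt, max_steps, n_rec


@njit(cache=True)
def _occupancy_1d(seed, x0, xg, sg, d_nm2, dt, max_steps, lo, hi, mid):
    np.random.seed(seed)
    sig = math.sqrt(2.0 * d_nm2 * dt)
    x = x0
    t_left = 0.0
    t_right = 0.0
    crossings = 0
    side = x >= mid
    for _ in range(max_steps):
        slope = np.interp(x, xg, sg)
        x += -slope * d_nm2 * dt + sig * np.random.normal()
        if x < lo:
            x = 2.0 * lo - x
        elif x > hi:
            x = 2.0 * hi - x
        new_side = x >= mid
        if new_side != side:
            crossings += 1
            side = new_side
        if new_side:
            t_right += dt
        else:
            t_left += dt
    return t_left, t_right, crossings


# ---------------------------------------------------------------------------
# grid construction and step-size policing
# ---------------------------------------------------------------------------


def _slope_table(
    potential: Callable[[np.ndarray], np.ndarray],
    lo: float,
    hi: float,
    n: int = 4001,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tabulate V and dV/dx (central differences) on [lo, hi]."""
    xg = np.linspace(lo, hi, n)
    vg = np.asarray(potential(xg), dtype=float)
    if not np.all(np.isfinite(vg)):
        raise ValueError("potential non-finite on the simulation domain")
    sg = np.gradient(vg, xg)
    return xg, vg, sg


def _check_timestep(dt: float, max_slope_kt_per_nm: float, d_nm2: float, l_char_nm: float):
    if max_slope_kt_per_nm <= 0:
        return
    drift = max_slope_kt_per_nm * d_nm2 * dt
    limit = DRIFT_FRACTION * l_char_nm
    if drift > limit:
        suggested = limit / (max_slope_kt_per_nm * d_nm2)
        raise StepSizeError(
            f"timestep {dt:.3g} s gives deterministic displacement "
            f"{drift:.3g} nm > {DRIFT_FRACTION:.0%} of the characteristic "
            f"length {l_char_nm} nm; use timestep <= {suggested:.3g} s"
        )


def suggest_timestep(
    potential: Callable[[np.ndarray], np.ndarray],
    lo_nm: float,
    hi_nm: float,
    env: ThermalEnvironment,
    l_char_nm: float,
) -> float:
    """Largest timestep satisfying the drift-per-step bound on [lo, hi]."""
    _, _, sg = _slope_table(potential, lo_nm, hi_nm)
    max_slope = float(np.max(np.abs(sg)))
    d_nm2 = env.diffusion_coefficient_nm2_per_s
    if max_slope == 0:
        return DRIFT_FRACTION * l_char_nm**2 / d_nm2  # diffusion-limited
    return DRIFT_FRACTION * l_char_nm / (max_slope * d_nm2)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def integrate(
    u: Potential2D,
    cfg: SimConfig,
    env: ThermalEnvironment,
    start: tuple[float, float],
) -> TrajectoryStats:
    """Integrate one 2-D trajectory on U(x, r) and collect statistics.

    ``start`` is the initial (x, r) in nm.  The axial domain is bounded by
    the landscape's terminal wells (reflecting, realizing the structural
    restriction on the primer terminus and the excluded forward jump);
    r = 0 is reflecting.  Stop conditions: ``fixed_time`` runs to
    ``max_time_s``; ``absorb_at_r`` scores dissociation at
    ``absorb_r_nm``; ``absorb_at_x`` absorbs at ``absorb_x_nm``.
    """
    axial = u.axial
    lo, hi = axial.x_min_nm, axial.x_max_nm
    xg, vg_ax, sg = _slope_table(axial, lo, hi)
    vg = vg_ax - u.e0_offset_kt
    d_nm2 = env.diffusion_coefficient_nm2_per_s
    # axial slope is steepest at r=0 (Morse factor 1); the radial slope
    # peaks at r = r_d ln 2 where |dg/dr| = 1/(2 r_d)
    max_slope = max(float(np.max(np.abs(sg))), float(np.max(np.abs(vg))) * 0.5 / u.range_nm)
    l_char = min(0.5 * (axial.site_positions_nm[1] - axial.site_positions_nm[0]), u.range_nm)
    _check_timestep(cfg.timestep_s, max_slope, d_nm2, l_char)

    max_steps = int(round(cfg.max_time_s / cfg.timestep_s))
    n_rec_max = max_steps // cfg.record_stride + 1
    rec_x = np.empty(n_rec_max)
    rec_r = np.empty(n_rec_max)
    absorb_r = cfg.absorb_r_nm if cfg.stop == "absorb_at_r" else np.inf
    if cfg.stop == "absorb_at_r" and cfg.absorb_r_nm is None:
        raise ValueError("absorb_at_r requires absorb_r_nm")
    absorb_x_lo, absorb_x_hi = -np.inf, np.inf
    if cfg.stop == "absorb_at_x":
        if cfg.absorb_x_nm is None:
            raise ValueError("absorb_at_x requires absorb_x_nm")
        if cfg.absorb_x_nm >= start[0]:
            absorb_x_hi = cfg.absorb_x_nm
        else:
            absorb_x_lo = cfg.absorb_x_nm

    status, t_end, n_steps, n_rec = _run_2d(
        cfg.seed, start[0], start[1], xg, vg, sg, u.range_nm, d_nm2,
        cfg.timestep_s, max_steps, lo, hi, absorb_x_lo, absorb_x_hi,
        absorb_r, cfg.record_stride, rec_x, rec_r,
    )
    rec_x, rec_r = rec_x[:n_rec], rec_r[:n_rec]
    times = (np.arange(1, n_rec + 1) * cfg.record_stride) * cfg.timestep_s
    sites = axial.site_positions_nm
    occ: dict[int, float] = {}
    if n_rec:
        nearest = np.argmin(np.abs(rec_x[:, None] - sites[None, :]), axis=1)
        for k in range(sites.size):
            occ[k] = float(np.mean(nearest == k))
    dissociated = int(status == 1 and cfg.stop == "absorb_at_r")
    return TrajectoryStats(
        times_s=times,
        x_nm=rec_x,
        r_nm=rec_r,
        first_passage_s=t_end if status == 1 else None,
        occupancy=occ,
        dissociation_count=dissociated,
        n_steps=n_steps,
        config=cfg,
    )


def simulate_1d(
    potential: Callable[[np.ndarray], np.ndarray],
    cfg: SimConfig,
    env: ThermalEnvironment,
    start_nm: float,
    reflect_nm: tuple[float, float],
    *,
    l_char_nm: Optional[float] = None,
) -> TrajectoryStats:
    """Fixed-time 1-D Langevin run between two reflecting walls.

    Records the strided trajectory; used for equilibrium checks
    (free-diffusion spreading, equipartition in a confining well).
    """
    lo, hi = reflect_nm
    if not (lo <= start_nm <= hi):
        raise ValueError("start must lie within the reflecting walls")
    xg, _, sg = _slope_table(potential, lo, hi)
    d_nm2 = env.diffusion_coefficient_nm2_per_s
    l_char = l_char_nm if l_char_nm is not None else 0.5 * (hi - lo)
    _check_timestep(cfg.timestep_s, float(np.max(np.abs(sg))), d_nm2, l_char)
    max_steps = int(round(cfg.max_time_s / cfg.timestep_s))
    rec = np.empty(max_steps // cfg.record_stride + 1)
    _, t_end, n_steps, n_rec = _run_1d(
        cfg.seed, start_nm, xg, sg, d_nm2, cfg.timestep_s, max_steps,
        lo, hi, -np.inf, np.inf, cfg.record_stride, rec,
    )
    rec = rec[:n_rec]
    times = (np.arange(1, n_rec + 1) * cfg.record_stride) * cfg.timestep_s
    return TrajectoryStats(
        times_s=times,
        x_nm=rec,
        r_nm=None,
        first_passage_s=None,
        occupancy={},
        dissociation_count=0,
        n_steps=n_steps,
        config=cfg,
    )


def sample_first_passage(
    potential: Callable[[np.ndarray], np.ndarray],
    cfg: SimConfig,
    start_nm: float,
    target_nm: float,
    n_samples: int,
    env: ThermalEnvironment,
    *,
    l_char_nm: Optional[float] = None,
) -> FPTResult:
    """Empirical first-passage times on a 1-D potential (reflecting start).

    ``potential`` maps nm to k_B*T (an axial landscape, a radial potential
    or any callable).  Trajectories start at ``start_nm`` against a
    reflecting wall and are absorbed at first touch of ``target_nm``.
    Raises if more than half the replicates fail to arrive within
    ``max_time_s``.  The sample vector is attached to the result.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = min(start_nm, target_nm), max(start_nm, target_nm)
    xg, vg, sg = _slope_table(potential, lo, hi)
    d_nm2 = env.diffusion_coefficient_nm2_per_s
    l_char = l_char_nm if l_char_nm is not None else 0.5 * (hi - lo)
    _check_timestep(cfg.timestep_s, float(np.max(np.abs(sg))), d_nm2, l_char)

    max_steps = int(round(cfg.max_time_s / cfg.timestep_s))
    rec = np.empty(0)
    forward = target_nm > start_nm
    absorb_lo = -np.inf if forward else target_nm
    absorb_hi = target_nm if forward else np.inf
    samples = np.full(n_samples, np.nan)
    for i in range(n_samples):
        status, t_end, _, _ = _run_1d(
            cfg.seed + i, start_nm, xg, sg, d_nm2, cfg.timestep_s, max_steps,
            lo, hi, absorb_lo, absorb_hi, max_steps + 1, rec,
        )
        if status == 1:
            samples[i] = t_end
    ok = np.isfinite(samples)
    if np.sum(ok) < 0.5 * n_samples:
        raise RuntimeError(
            f"only {int(np.sum(ok))}/{n_samples} trajectories reached the "
            f"target within max_time_s={cfg.max_time_s}; increase max_time_s "
            "or reduce the barrier"
        )
    vals = samples[ok]
    mean = float(np.mean(vals))
    if vals.size > 1:
        sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size))
    else:
        sem = None
        warnings.warn("single sample: standard error undefined", RuntimeWarning)
    return FPTResult(
        mean_time_s=mean,
        method="simulation",
        start_nm=start_nm,
        end_nm=target_nm,
        description=f"Euler-Maruyama, {vals.size} passages",
        sem_s=sem,
        n_samples=int(vals.size),
        samples_s=samples,
    )


@dataclass(frozen=True)
class OccupancyResult:
    """Residence-time ratio T_n/T_{n+1} with replica statistics."""

    ratio: float
    sem: float
    crossings: int
    n_replicas: int


def occupancy_ratio(
    axial,
    cfg: SimConfig,
    env: ThermalEnvironment,
    *,
    n_replicas: int = 8,
    min_crossings: int = 100,
    max_widenings: int = 3,
) -> OccupancyResult:
    """Residence-time ratio T_n/T_{n+1} of a two-well landscape.

    ``max_time_s`` is split over ``n_replicas`` independent runs (seeds
    ``cfg.seed + i``); positions are assigned to the nearer well by the
    midpoint partition, the ratio is estimated from the pooled residence
    times and its standard error from the replica-to-replica spread.  If
    fewer than ``min_crossings`` barrier crossings accumulate, the run is
    repeatedly doubled (with a warning) up to ``max_widenings`` times.
    """
    sites = axial.site_positions_nm
    if sites.size != 2:
        raise ValueError("occupancy_ratio expects a two-well landscape")
    lo, hi = float(sites[0]), float(sites[1])
    mid = 0.5 * (lo + hi)
    xg, _, sg = _slope_table(axial, lo, hi)
    d_nm2 = env.diffusion_coefficient_nm2_per_s
    _check_timestep(cfg.timestep_s, float(np.max(np.abs(sg))), d_nm2, 0.5 * (hi - lo))

    steps_per_rep = int(round(cfg.max_time_s / cfg.timestep_s / n_replicas))
    t_left = np.zeros(n_replicas)
    t_right = np.zeros(n_replicas)
    crossings = 0
    seed = cfg.seed
    for attempt in range(max_widenings + 1):
        for i in range(n_replicas):
            tl, tr, cr = _occupancy_1d(
                seed + i, lo, xg, sg, d_nm2, cfg.timestep_s,
                steps_per_rep, lo, hi, mid,
            )
            t_left[i] += tl
            t_right[i] += tr
            crossings += cr
        if crossings >= min_crossings:
            break
        warnings.warn(
            f"only {crossings} barrier crossings; widening max_time",
            RuntimeWarning,
        )
        seed += 1000 * n_replicas
    if np.any(t_right == 0):
        raise RuntimeError("a replica never visited the post-translocation well")
    ratios = t_left / t_right
    return OccupancyResult(
        ratio=float(np.sum(t_left) / np.sum(t_right)),
        sem=float(np.std(ratios, ddof=1) / math.sqrt(n_replicas)),
        crossings=crossings,
        n_replicas=n_replicas,
    )
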