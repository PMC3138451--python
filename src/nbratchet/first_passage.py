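"""Mean first-passage-time (MFPT) solvers for the ratchet landscapes.

For overdamped diffusion with diffusivity D in a potential V (in k_B*T)
with a reflecting boundary at the start and an absorbing boundary at the
end, the MFPT is the classic double Boltzmann-weighted integral

    T = (1/D) * int_start^end exp(+V(y)) [ int_start^y exp(-V(z)) dz ] dy.

This quadrature is the ground truth used throughout the package.  Two
closed forms are provided as fast cross-checks, each validated against the
quadrature: an exact piecewise-exponential formula for the symmetric
sawtooth segment between adjacent sites, and a factorized (Kramers-style,
separated-timescale) two-integral form for escape from a deep Morse well.

All MFPTs scale linearly in the viscosity through D = k_B*T/Gamma; well
depths enter through Arrhenius-like exponential factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
from scipy.integrate import cumulative_simpson, quad, simpson

from .core_units import Geometry, ThermalEnvironment, force_times_length_kt

__all__ = [
    "FPTResult",
    "FirstPassageError",
    "mfpt_quadrature",
    "dissociation_time",
    "moving_time",
    "sawtooth_mfpt_closed_form",
    "dwell_ratio",
]

#: Boltzmann factors beyond this many k_B*T are capped (with a warning):
#: exp(50) is already far outside the model's meaningful regime.
ENERGY_CAP_KT = 50.0


class FirstPassageError(RuntimeError):
    """Raised when a potential cannot be integrated (non-finite values)."""


@dataclass(frozen=True)
class FPTResult:
    """A mean first-passage time with provenance.

    ``mean_time_s`` is the MFPT in seconds; ``method`` records how it was
    obtained; ``start_nm``/``end_nm`` are the reflecting and absorbing
    coordinates; ``sem_s`` is populated only for simulation estimates.
    """

    mean_time_s: float
    method: Literal["quadrature", "closed_form", "simulation"]
    start_nm: float
    end_nm: float
    description: str = ""
    sem_s: Optional[float] = None
    n_samples: Optional[int] = None
    samples_s: Optional[np.ndarray] = None


def _capped(v: np.ndarray) -> np.ndarray:
    if np.max(np.abs(v)) > ENERGY_CAP_KT:
        warnings.warn(
            f"potential exceeds {ENERGY_CAP_KT} k_B*T; capping Boltzmann factors",
            RuntimeWarning,
            stacklevel=3,
        )
        v = np.clip(v, -ENERGY_CAP_KT, ENERGY_CAP_KT)
    return v


def mfpt_quadrature(
    potential_kt: Callable[[np.ndarray], np.ndarray],
    start_nm: float,
    end_nm: float,
    diffusion_m2_per_s: float,
    *,
    rtol: float = 1e-6,
    n_grid: int = 4097,
    max_refinements: int = 8,
    description: str = "",
) -> FPTResult:
    """MFPT from ``start_nm`` (reflecting) to ``end_nm`` (absorbing).

    ``potential_kt`` maps position in nm to energy in k_B*T and must be
    finite on the interval; the direction of integration follows the sign
    of ``end_nm - start_nm``.  The dominant Boltzmann exponentials are
    factored out before integration, and the composite-Simpson grid is
    refined (doubled) until two successive estimates agree to ``rtol``.
    """
    if end_nm == start_nm:
        raise ValueError("start and end coincide; MFPT undefined")
    span = abs(end_nm - start_nm)
    sgn = math.copysign(1.0, end_nm - start_nm)

    def estimate(n: int) -> float:
        s = np.linspace(0.0, span, n)
        v = np.asarray(potential_kt(start_nm + sgn * s), dtype=float)
        if not np.all(np.isfinite(v)):
            bad = np.flatnonzero(~np.isfinite(v))
            raise FirstPassageError(
                f"potential non-finite at x={start_nm + sgn * s[bad[0]]:.4g} nm "
                f"({bad.size} of {n} grid points)"
            )
        v = _capped(v)
        vmin, vmax = float(v.min()), float(v.max())
        inner = cumulative_simpson(np.exp(-(v - vmin)), x=s, initial=0.0)
        outer = simpson(np.exp(v - vmax) * inner, x=s)
        return float(outer) * math.exp(vmax - vmin)  # nm^2

    prev = estimate(n_grid)
    n = n_grid
    for _ in range(max_refinements):
        n = 2 * n - 1
        cur = estimate(n)
        if abs(cur - prev) <= rtol * abs(cur):
            prev = cur
            break
        prev = cur
    mean_time = prev * 1e-18 / diffusion_m2_per_s
    return FPTResult(
        mean_time_s=mean_time,
        method="quadrature",
        start_nm=start_nm,
        end_nm=end_nm,
        description=description,
    )


def _morse_factorized_nm2(depth_kt: float, range_nm: float, escape_nm: float) -> float:
    """Factorized (separated-timescale) escape integral for a Morse well, nm^2.

    T*D ~ [int_0^L exp(-W)] * [int_0^L exp(+W)]: valid when the well is deep
    enough (>= ~8 k_B*T) that the Boltzmann populations inside and outside
    the well are well separated.
    """

    def w(r: float) -> float:
        u = r / range_nm
        return -depth_kt * (2.0 * math.exp(-u) - math.exp(-2.0 * u))

    inside, _ = quad(lambda r: math.exp(-(w(r) - (-depth_kt))), 0.0, escape_nm, limit=200)
    outside, _ = quad(lambda r: math.exp(w(r)), 0.0, escape_nm, limit=200)
    return inside * math.exp(depth_kt) * outside


def dissociation_time(
    rp,
    env: ThermalEnvironment,
    *,
    method: Literal["quadrature", "closed_form"] = "quadrature",
    rtol: float = 1e-6,
) -> FPTResult:
    """Mean dissociation time T_d: radial escape from r=0 to r=L_escape.

    ``rp`` is a :class:`~nbratchet.landscape.RadialPotential`.  T_d grows
    essentially as exp(E_r) with the well depth and is proportional to the
    viscosity.  The closed-form variant uses the factorized Kramers-style
    product of one-dimensional integrals (accurate to <1% for deep wells,
    E_r >= ~10 k_B*T); the quadrature is exact for any depth.
    """
    D = env.diffusion_coefficient_m2_per_s
    if method == "closed_form":
        t = _morse_factorized_nm2(rp.depth_kt, rp.range_nm, rp.escape_distance_nm)
        return FPTResult(
            mean_time_s=t * 1e-18 / D,
            method="closed_form",
            start_nm=0.0,
            end_nm=rp.escape_distance_nm,
            description=f"Morse escape, E_r={rp.depth_kt} kT (factorized)",
        )
    return mfpt_quadrature(
        rp,
        0.0,
        rp.escape_distance_nm,
        D,
        rtol=rtol,
        description=f"Morse escape, E_r={rp.depth_kt} kT",
    )


def _sawtooth_potential(e_from_kt: float, e_to_kt: float, half_nm: float):
    """V(x) for one sawtooth segment: well -e_from at 0, barrier 0 at l, well -e_to at 2l."""

    def v(x_nm):
        x = np.asarray(x_nm, dtype=float)
        rising = -e_from_kt * (1.0 - x / half_nm)
        falling = -e_to_kt * (x - half_nm) / half_nm
        return np.where(x <= half_nm, rising, falling)

    return v


def sawtooth_mfpt_closed_form(
    e_from_kt: float, e_to_kt: float, half_nm: float, diffusion_m2_per_s: float
) -> float:
    """Exact MFPT (s) over one symmetric sawtooth segment.

    Reflecting at the starting well minimum (depth ``e_from_kt``), barrier
    top at ``half_nm``, absorbing at the destination minimum (depth
    ``e_to_kt``).  Obtained by integrating the double integral segment by
    segment (each flank is linear, so every integral is elementary).  In
    the deep-well limit it approaches
    l^2 e^{E_from} (1/E_from^2 + 1/(E_from*E_to)) / D; with both depths
    zero it reduces to the free-diffusion result (2l)^2/(2D).
    """
    l_m = half_nm * 1e-9
    ef, et = float(e_from_kt), float(e_to_kt)

    # piece 1: start well flank, int_0^l e^{V} * inner
    if ef > 1e-6:
        piece1 = (l_m / ef) ** 2 * math.expm1(ef) - l_m**2 / ef
        c = (l_m / ef) * math.expm1(ef)  # inner integral at the barrier top
    else:
        piece1 = l_m**2 * (0.5 + ef / 6.0)
        c = l_m * (1.0 + ef / 2.0)
    # piece 2: descent flank
    if et > 1e-6:
        frac = -math.expm1(-et) / et  # (1 - e^{-E_to}) / E_to
        piece2 = l_m * (c * frac + (l_m / et) * (1.0 - frac))
    else:
        piece2 = l_m * (c * (1.0 - et / 2.0) + l_m * (0.5 - et / 6.0))
    return (piece1 + piece2) / diffusion_m2_per_s


def moving_time(
    e_from_kt: float,
    e_to_kt: float,
    geom: Geometry,
    env: ThermalEnvironment,
    *,
    method: Literal["quadrature", "closed_form"] = "quadrature",
    rtol: float = 1e-6,
) -> FPTResult:
    """Mean inter-site moving time over one sawtooth period p = 2l.

    Forward translocation (n -> n+1) uses ``e_from_kt = E_n + E0`` and
    ``e_to_kt = E_{n+1} + E0``; the backward time is the same call with the
    depths exchanged.  Dominated by the Arrhenius escape from the starting
    well, hence nearly insensitive to the destination depth.
    """
    if e_from_kt < 0 or e_to_kt < 0:
        raise ValueError("well depths must be non-negative")
    D = env.diffusion_coefficient_m2_per_s
    l_nm = geom.half_spacing_nm
    if method == "closed_form":
        t = sawtooth_mfpt_closed_form(e_from_kt, e_to_kt, l_nm, D)
        return FPTResult(
            mean_time_s=t,
            method="closed_form",
            start_nm=0.0,
            end_nm=geom.site_spacing_nm,
            description=f"sawtooth hop, {e_from_kt} -> {e_to_kt} kT",
        )
    return mfpt_quadrature(
        _sawtooth_potential(e_from_kt, e_to_kt, l_nm),
        0.0,
        geom.site_spacing_nm,
        D,
        rtol=rtol,
        description=f"sawtooth hop, {e_from_kt} -> {e_to_kt} kT",
    )


def dwell_ratio(
    delta_e_kt: float, force_pN: float, geom: Geometry, env: ThermalEnvironment
) -> float:
    """Equilibrium residence-time ratio T_n / T_{n+1} of the two-site window.

    The Boltzmann ratio of the tilted well depths:
    ``exp[(E_n - E_{n+1} + F*p) / k_B*T]`` -- a backward load F deepens the
    pre-translocation well by F*p/2 and shallows the post-translocation
    well by the same amount.
    """
    fp_kt = force_times_length_kt(force_pN, geom.site_spacing_nm, env)
    return math.exp(delta_e_kt + fp_kt)
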