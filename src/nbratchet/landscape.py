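"""Energy landscapes of the polymerase-DNA interaction.

The translocation coordinate ``x`` runs along the template (site spacing
p = 0.34 nm, one base-pair rise); the coordinate ``r`` is the perpendicular
separation between the polymerase and the DNA.  The axial potential V(x) is
a sawtooth over the discrete template sites: well minima at the site
positions, linear flanks meeting at a common barrier-top reference at the
midpoint between sites.  Only the well *depths* carry the physics -- they
are set by how many template bases / backbone segments each of the two
DNA-binding sites of the polymerase covers in the pre- (site n) and
post-translocation (site n+1) registers:

* ``dpo4_like``  (structural offset L = 0):  E_n = E1' + E2,   E_{n+1} = E1 + E2'
* ``dbh_like``   (L = 1 bp):                 E_n = E1' + E2,   E_{n+1} = E1 + E2
* ``lesion_at_n`` (mismatch/lesion at n):    E_n = E1  + E2',  E_{n+1} = E1 + E2''
* ``replicative``:                           E_n - E_{n+1} = E1' - E1 < 0

Here E1 (E1') is the single-strand-binding affinity of the fingers site for
N1 (N1-1) template bases, E2/E2'/E2'' the duplex-binding affinity of the
thumb + little-finger site for backbones connecting N2/N2-1/N2-2 base
pairs, and E0 a long-range electrostatic offset (V0 = -E0) that deepens
every well equally.  A backward load F (positive toward -x) tilts the
landscape, changing the well depths by +F*p/2 at site n and -F*p/2 at
site n+1.

The radial escape potential has the Morse form
``W(r) = -E_r [2 exp(-r/r_d) - exp(-2 r/r_d)]`` with depth
``E_r = E_site + E0``, and the full two-dimensional potential factorizes as
``U(x, r) = V(x) [2 exp(-r/r_d) - exp(-2 r/r_d)]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .core_units import Geometry, ThermalEnvironment, force_times_length_kt

__all__ = [
    "Scenario",
    "RatchetEnergies",
    "AxialLandscape",
    "RadialPotential",
    "Potential2D",
    "site_affinities",
    "build_axial",
    "potential_2d",
]

Scenario = Literal["dpo4_like", "dbh_like", "replicative", "lesion_at_n"]


class RatchetEnergies(BaseModel):
    """Well-depth parameters of the two DNA-binding sites, in k_B*T.

    ``e0_kt`` may be given directly, or left ``None`` with
    ``e0_rule="Er/5"`` to apply the conservative estimate E0 = E_r/5
    (equivalently E0 = E_site/4, since E_r = E_site + E0).
    """

    model_config = ConfigDict(frozen=True)

    e1_kt: float = Field(0.0, ge=0, description="S1 affinity for N1 ssDNA bases")
    e1p_kt: float = Field(0.0, ge=0, description="S1 affinity for N1-1 bases")
    e2_kt: float = Field(..., gt=0, description="S2 affinity, N2 bp backbones")
    e2p_kt: float = Field(..., ge=0, description="S2 affinity, N2-1 bp backbones")
    e2pp_kt: Optional[float] = Field(
        None, ge=0, description="S2 affinity, N2-2 bp (lesion/mismatch case)"
    )
    e0_kt: Optional[float] = Field(None, ge=0, description="electrostatic offset")
    e0_rule: Optional[Literal["Er/5"]] = None

    def model_post_init(self, __context) -> None:
        if self.e1_kt < self.e1p_kt:
            raise ValueError("require E1 >= E1' (more covered bases bind tighter)")
        if self.e2_kt <= self.e2p_kt:
            raise ValueError("require E2 > E2'")
        if self.e2pp_kt is not None and self.e2p_kt <= self.e2pp_kt:
            raise ValueError("require E2' > E2''")
        if self.e0_kt is None and self.e0_rule is None:
            raise ValueError("give e0_kt directly or set e0_rule='Er/5'")

    def e0_for(self, site_affinity_kt: float) -> float:
        """Electrostatic offset E0 for a well of binding affinity E_site."""
        if self.e0_kt is not None:
            return self.e0_kt
        # E0 = E_r/5 with E_r = E_site + E0  =>  E0 = E_site/4
        return site_affinity_kt / 4.0


def site_affinities(e: RatchetEnergies, scenario: Scenario) -> tuple[float, float]:
    """Pre-/post-translocation binding affinities (E_n, E_{n+1}) in k_B*T."""
    if scenario == "dpo4_like":
        return e.e1p_kt + e.e2_kt, e.e1_kt + e.e2p_kt
    if scenario == "dbh_like" or scenario == "replicative":
        # Replicative enzymes share the Dbh-like register bookkeeping: the
        # duplex site keeps full coverage at both registers, so the
        # difference E_n - E_{n+1} = E1' - E1 <= 0 comes from the
        # single-strand site alone (strongly negative for replicative
        # polymerases, ~0 for Dbh/Pol iota/Pol eta).
        return e.e1p_kt + e.e2_kt, e.e1_kt + e.e2_kt
    if scenario == "lesion_at_n":
        if e.e2pp_kt is None:
            raise ValueError("lesion_at_n scenario requires e2pp_kt")
        return e.e1_kt + e.e2p_kt, e.e1_kt + e.e2pp_kt
    raise ValueError(f"unknown scenario: {scenario!r}")


@dataclass(frozen=True)
class AxialLandscape:
    """Piecewise-linear sawtooth V(x) over discrete template sites, in k_B*T.

    The zero of energy is the dissociated state (r -> infinity).  Well
    minima sit at ``-well_depths_kt`` (the full depths E_site + E0) and
    the common barrier-top reference between sites at ``barrier_kt``
    (-E0 for landscapes carrying the electrostatic offset), so the axial
    hopping barrier out of a well is E_site while the radial escape depth
    at a well is E_site + E0.  A backward load tilts the potential
    additively by +beta*F*x, which shifts the well depths relative to the
    barrier by +F*p/2 at site n and -F*p/2 at site n+1.  The terminal
    wells are reflecting: the primer terminus cannot advance past the
    active site, and the forward jump out of the last site is not part of
    the model.
    """

    site_positions_nm: np.ndarray
    well_depths_kt: np.ndarray
    force_pN: float
    env: ThermalEnvironment
    barrier_kt: float = 0.0

    @property
    def _knots(self) -> tuple[np.ndarray, np.ndarray]:
        x_sites = self.site_positions_nm
        mids = 0.5 * (x_sites[:-1] + x_sites[1:])
        xs = np.empty(x_sites.size + mids.size)
        xs[0::2] = x_sites
        xs[1::2] = mids
        vs = np.full_like(xs, self.barrier_kt)
        vs[0::2] = -self.well_depths_kt
        return xs, vs

    @property
    def tilt_kt_per_nm(self) -> float:
        """Potential gradient of the load: beta*F, in k_B*T per nm."""
        return force_times_length_kt(self.force_pN, 1.0, self.env)

    def __call__(self, x_nm) -> np.ndarray:
        """Evaluate V(x) in k_B*T; x may be scalar or array (nm)."""
        xs, vs = self._knots
        x = np.asarray(x_nm, dtype=float)
        return np.interp(x, xs, vs) + self.tilt_kt_per_nm * x

    def slope(self, x_nm) -> np.ndarray:
        """dV/dx in k_B*T per nm (piecewise constant; right-continuous)."""
        xs, vs = self._knots
        x = np.asarray(x_nm, dtype=float)
        seg = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, xs.size - 2)
        base = (vs[seg + 1] - vs[seg]) / (xs[seg + 1] - xs[seg])
        return base + self.tilt_kt_per_nm

    def depth_at(self, k: int) -> float:
        """Axial depth of well k below the adjacent barrier top, load included.

        Measured against the barrier toward the next site (toward the
        previous one for the last well), so under a backward load F the
        two-site window gives E_n + F*p/2 and E_{n+1} - F*p/2; the E0
        offset cancels (it shifts wells and barriers alike).
        """
        x_sites = self.site_positions_nm
        if k < x_sites.size - 1:
            m = 0.5 * (x_sites[k] + x_sites[k + 1])
        else:
            m = 0.5 * (x_sites[k - 1] + x_sites[k])
        return float(self(m) - self(x_sites[k]))

    @property
    def x_min_nm(self) -> float:
        return float(self.site_positions_nm[0])

    @property
    def x_max_nm(self) -> float:
        return float(self.site_positions_nm[-1])

    def to_frame(self, points_per_segment: int = 50) -> pd.DataFrame:
        """Tabulate the landscape as (x_nm, V_kT) for plotting/inspection."""
        xs, _ = self._knots
        x = np.unique(
            np.concatenate(
                [np.linspace(a, b, points_per_segment) for a, b in zip(xs[:-1], xs[1:])]
            )
        )
        return pd.DataFrame({"x_nm": x, "V_kT": self(x)})

    def to_csv(self, path, points_per_segment: int = 50) -> None:
        self.to_frame(points_per_segment).to_csv(path, index=False)


def build_axial(
    e: RatchetEnergies,
    env: ThermalEnvironment,
    scenario: Scenario,
    force_pN: float = 0.0,
    n_sites: int = 2,
    geom: Geometry | None = None,
) -> AxialLandscape:
    """Build the sawtooth landscape for a scenario, with optional load.

    Sites alternate between the pre- and post-translocation affinities
    (E_n, E_{n+1}, E_n, ...); the standard two-site window is ``n_sites=2``.
    Well minima sit at -(E_site + E0) and barrier tops at -E0, so the
    axial hopping barrier is E_site while the full radial escape depth at
    a well is E_site + E0.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    geom = geom or Geometry()
    e_n, e_n1 = site_affinities(e, scenario)
    e0 = e.e0_for(e_n1)
    depths = np.array(
        [(e_n if k % 2 == 0 else e_n1) + e0 for k in range(n_sites)]
    )
    if np.any(depths < 0):
        raise ValueError("negative well depth; check energy parameters")
    positions = np.arange(n_sites) * geom.site_spacing_nm
    return AxialLandscape(
        site_positions_nm=positions,
        well_depths_kt=depths,
        force_pN=force_pN,
        env=env,
        barrier_kt=-e0,
    )


class RadialPotential(BaseModel):
    """Morse-form radial escape potential, in k_B*T.

    ``W(r) = -E_r [2 exp(-r/r_d) - exp(-2 r/r_d)]`` -- a well of depth E_r
    at contact (r = 0) rising monotonically to zero at large separation.
    Dissociation is scored at ``r = escape_distance_nm``.
    """

    model_config = ConfigDict(frozen=True)

    depth_kt: float = Field(..., ge=0)
    range_nm: float = Field(0.5, gt=0)
    escape_distance_nm: float = Field(5.0, gt=0)

    def model_post_init(self, __context) -> None:
        if self.escape_distance_nm <= 2.0 * self.range_nm:
            raise ValueError("escape distance must exceed the interaction range 2*r_d")

    def __call__(self, r_nm) -> np.ndarray:
        u = np.asarray(r_nm, dtype=float) / self.range_nm
        return -self.depth_kt * (2.0 * np.exp(-u) - np.exp(-2.0 * u))

    def slope(self, r_nm) -> np.ndarray:
        """dW/dr in k_B*T per nm; >= 0 for r >= 0."""
        u = np.asarray(r_nm, dtype=float) / self.range_nm
        return (2.0 * self.depth_kt / self.range_nm) * (np.exp(-u) - np.exp(-2.0 * u))


@dataclass(frozen=True)
class Potential2D:
    """Separable 2-D potential U(x, r) = V(x) * [2 exp(-r/r_d) - exp(-2 r/r_d)].

    At r = 0 the Morse factor is 1 so U(x, 0) = V(x); at a well position
    with V = -(E_site + E0) the radial section is a Morse well of depth
    E_r = E_site + E0.  Analytic partial derivatives feed the Langevin
    integrator.  The factorized form describes the unloaded landscape; the
    axial load tilt, if any, is carried inside V.
    """

    axial: AxialLandscape
    range_nm: float
    e0_offset_kt: float = 0.0

    def _v(self, x_nm):
        return self.axial(x_nm) - self.e0_offset_kt

    def _g(self, r_nm):
        u = np.asarray(r_nm, dtype=float) / self.range_nm
        return 2.0 * np.exp(-u) - np.exp(-2.0 * u)

    def _dg(self, r_nm):
        u = np.asarray(r_nm, dtype=float) / self.range_nm
        return (2.0 / self.range_nm) * (np.exp(-2.0 * u) - np.exp(-u))

    def __call__(self, x_nm, r_nm) -> np.ndarray:
        return self._v(x_nm) * self._g(r_nm)

    def du_dx(self, x_nm, r_nm) -> np.ndarray:
        return self.axial.slope(x_nm) * self._g(r_nm)

    def du_dr(self, x_nm, r_nm) -> np.ndarray:
        return self._v(x_nm) * self._dg(r_nm)


def potential_2d(
    axial: AxialLandscape, e0_offset_kt: float = 0.0, r_d_nm: float = 0.5
) -> Potential2D:
    """Compose the 2-D potential from an axial landscape and the Morse factor.

    ``axial`` should already include the E0 offset in its well depths (the
    standard :func:`build_axial` output); ``e0_offset_kt`` is an additional
    uniform deepening applied here for landscapes built without it.
    """
    return Potential2D(axial=axial, range_nm=r_d_nm, e0_offset_kt=e0_offset_kt)
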