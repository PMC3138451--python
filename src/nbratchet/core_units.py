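"""Physical constants, unit conversions, and the thermal environment.

The polymerase is treated as a Stokes sphere of radius ``R`` diffusing in a
medium of viscosity ``eta`` at temperature ``T``.  Everything downstream
(mean first-passage times, dissociation rates, Langevin dynamics) needs only
the drag coefficient ``Gamma = 6*pi*eta*R``, the thermal energy ``k_B*T``
and the diffusion coefficient ``D = k_B*T/Gamma`` derived here.

Internally all computation is in SI; the user-facing convention follows the
single-molecule literature: energies in units of ``k_B*T``, lengths in nm,
forces in pN.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ThermalEnvironment",
    "Geometry",
    "make_environment",
    "energy_to_joules",
    "joules_to_energy",
    "force_times_length_kt",
]

#: Boltzmann constant (exact, SI 2019), J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

# Defaults: water-like viscosity (0.01 g cm^-1 s^-1 = 1e-3 Pa s) and a
# 5 nm Stokes radius for the polymerase; room temperature.
DEFAULT_TEMPERATURE_K = 300.0
DEFAULT_VISCOSITY_PA_S = 1.0e-3
DEFAULT_STOKES_RADIUS_NM = 5.0


class ThermalEnvironment(BaseModel):
    """Temperature/viscosity/size of the diffusing polymerase sphere.

    Derived quantities are exact consequences of the Stokes-Einstein
    relations: ``Gamma = 6*pi*eta*R`` and ``D = k_B*T/Gamma``.
    """

    model_config = ConfigDict(frozen=True)

    temperature_K: float = Field(DEFAULT_TEMPERATURE_K, gt=0)
    viscosity_Pa_s: float = Field(DEFAULT_VISCOSITY_PA_S, gt=0)
    stokes_radius_nm: float = Field(DEFAULT_STOKES_RADIUS_NM, gt=0)

    @property
    def thermal_energy_J(self) -> float:
        """k_B*T in joules."""
        return BOLTZMANN_J_PER_K * self.temperature_K

    @property
    def drag_coefficient_kg_per_s(self) -> float:
        """Stokes drag Gamma = 6*pi*eta*R, kg/s."""
        import math

        return 6.0 * math.pi * self.viscosity_Pa_s * self.stokes_radius_nm * 1e-9

    @property
    def diffusion_coefficient_m2_per_s(self) -> float:
        """Einstein relation D = k_B*T/Gamma, m^2/s."""
        return self.thermal_energy_J / self.drag_coefficient_kg_per_s

    @property
    def diffusion_coefficient_nm2_per_s(self) -> float:
        """D expressed in nm^2/s, the unit used by the nm-scale solvers."""
        return self.diffusion_coefficient_m2_per_s * 1e18


class Geometry(BaseModel):
    """Geometric parameters of the polymerase-DNA interaction.

    ``site_spacing_nm`` is the base-pair rise p = 0.34 nm (one translocation
    step); the barrier between adjacent sites sits at the half spacing
    l = p/2.  ``radial_range_nm`` is the Morse range r_d (half the ~1 nm
    Debye screening length of the dominant electrostatic interaction) and
    ``escape_distance_nm`` the radial separation at which the polymerase is
    counted as dissociated, taken well beyond the interaction range.
    ``structural_offset_bp`` is the distance L (in base pairs) from the
    active site to the nearest duplex-binding residue of the little-finger
    domain: 0 for Dpo4-like enzymes, 1 for Dbh/Pol iota/Pol eta-like.
    """

    model_config = ConfigDict(frozen=True)

    site_spacing_nm: float = Field(0.34, gt=0)
    radial_range_nm: float = Field(0.5, gt=0)
    escape_distance_nm: float = Field(5.0, gt=0)
    structural_offset_bp: int = Field(0)
    footprint_ss_bases: int = Field(4, gt=0)   # N_1, descriptive only
    footprint_ds_bp: int = Field(8, gt=0)      # N_2, descriptive only

    @property
    def half_spacing_nm(self) -> float:
        """l = p/2, position of the inter-site barrier."""
        return 0.5 * self.site_spacing_nm

    def model_post_init(self, __context) -> None:
        if self.escape_distance_nm <= 2.0 * self.radial_range_nm:
            raise ValueError(
                "escape_distance_nm must exceed the interaction distance "
                f"2*r_d = {2 * self.radial_range_nm} nm"
            )
        if self.structural_offset_bp not in (0, 1):
            raise ValueError("structural_offset_bp must be 0 or 1")


def make_environment(
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S,
    stokes_radius_nm: float = DEFAULT_STOKES_RADIUS_NM,
) -> ThermalEnvironment:
    """Build a :class:`ThermalEnvironment`; all inputs must be positive.

    Defaults reproduce the canonical parameterization (300 K, water
    viscosity, R = 5 nm), for which Gamma = 9.4e-11 kg/s.
    """
    return ThermalEnvironment(
        temperature_K=temperature_K,
        viscosity_Pa_s=viscosity_Pa_s,
        stokes_radius_nm=stokes_radius_nm,
    )


def energy_to_joules(energy_kt: float, env: ThermalEnvironment) -> float:
    """Convert an energy from k_B*T units to joules."""
    return energy_kt * env.thermal_energy_J


def joules_to_energy(energy_J: float, env: ThermalEnvironment) -> float:
    """Convert an energy from joules to k_B*T units."""
    return energy_J / env.thermal_energy_J


def force_times_length_kt(force_pN: float, length_nm: float, env: ThermalEnvironment) -> float:
    """Mechanical work F*x of a pN-scale force over an nm-scale length, in k_B*T.

    Handy scale: 12.18 pN x 0.34 nm is one k_B*T at 300 K.
    """
    return force_pN * 1e-12 * length_nm * 1e-9 / env.thermal_energy_J
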