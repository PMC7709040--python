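"""Stokes-Einstein physics: D from a radius, MSD, and empirical corrections.

The translational diffusion coefficient of a sphere of radius r in a
solvent of viscosity eta_0 at absolute temperature T is

    D = k_B T / (6 pi r eta_0),

and the one-dimensional mean-square displacement after time t is 2 D t.
Radii enter in Å, viscosity in mPa s, and D is reported in the
conventional 1e-6 cm^2/s used for small solutes in water (water at 298 K:
eta_0 = 0.8902 mPa s).

Two optional empirical corrections are provided: a constant shift that
maps finite-concentration measurements D_c onto infinite-dilution D_0, and
a multiplicative factor for very small solutes (r_s below ~3 Å), where the
continuum Stokes picture underestimates D.  Both are explicit opt-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_input import InputError

__all__ = [
    "BOLTZMANN_J_PER_K",
    "PhysicalConditions",
    "DiffusionResult",
    "WATER_298K",
    "stokes_einstein",
    "radius_from_d",
    "msd",
    "derive_d0_from_dc",
    "small_radius_correction",
    "round_half_up",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class PhysicalConditions:
    """Solvent conditions: temperature (K) and viscosity (mPa s)."""

    temperature: float = 298.0
    viscosity: float = 0.8902

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InputError("temperature must be positive (K)")
        if self.viscosity <= 0:
            raise InputError("viscosity must be positive (mPa s)")


#: Water at 298 K.
WATER_298K = PhysicalConditions()


def stokes_einstein(
    radius: float, conditions: PhysicalConditions = WATER_298K
) -> float:
    """Diffusion coefficient (1e-6 cm^2/s) of a sphere of ``radius`` Å.

    D = k_B T / (6 pi r eta_0) with r in m and eta_0 in Pa s gives m^2/s;
    1 m^2/s = 1e10 * 1e-6 cm^2/s.
    """
    if radius <= 0:
        raise InputError("radius must be positive (Å)")
    r_m = radius * 1e-10
    eta_pa_s = conditions.viscosity * 1e-3
    d_m2_s = BOLTZMANN_J_PER_K * conditions.temperature / (
        6.0 * 3.141592653589793 * r_m * eta_pa_s
    )
    return d_m2_s * 1e10


def radius_from_d(d: float, conditions: PhysicalConditions = WATER_298K) -> float:
    """Inverse Stokes-Einstein: radius (Å) from D (1e-6 cm^2/s)."""
    if d <= 0:
        raise InputError("diffusion coefficient must be positive")
    return stokes_einstein(1.0, conditions) / d


def msd(d: float, time: float) -> float:
    """One-dimensional mean-square displacement 2 D t (units follow D and t)."""
    if d < 0 or time < 0:
        raise InputError("D and time must be non-negative")
    return 2.0 * d * time


def derive_d0_from_dc(d_c: float, shift: float) -> float:
    """Infinite-dilution estimate D_0 = D_c + shift (both 1e-6 cm^2/s).

    ``shift`` is the calibrated mean D_0 - D_c gap of reference solutes
    with both values measured (see ``benchmark.calibrate_shift``).
    """
    if d_c <= 0:
        raise InputError("D_c must be positive")
    return d_c + shift


def small_radius_correction(
    d: float, r_s: float, factor: float = 1.1, threshold: float = 3.0
) -> float:
    """Multiply D by ``factor`` when r_s < threshold Å; identity otherwise.

    Continuum hydrodynamics underestimates D for solutes much smaller than
    the solvent correlation length; a modest multiplicative factor (~1.1
    for r_s around 2.7 Å) compensates.  Off by default in the pipeline.
    """
    if factor < 1.0:
        raise InputError("correction factor must be >= 1")
    if threshold <= 0:
        raise InputError("radius threshold must be positive")
    return d * factor if r_s < threshold else d


@dataclass(frozen=True)
class DiffusionResult:
    """D_s and D_e (1e-6 cm^2/s) for one molecule, with provenance."""

    name: str
    d_s: float
    d_e: float
    r_s: float
    r_e: float
    conditions: PhysicalConditions = WATER_298K
    corrections: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.d_s <= 0 or self.d_e <= 0:
            raise InputError("diffusion coefficients must be positive")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in printed report tables."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )
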