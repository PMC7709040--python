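"""Molecular radius estimates: simple radius r_s, effective radius r_e.

Two approximate radii are computed per conformer from its occupancy grid:

* the simple radius ``r_s``, the radius of the sphere whose volume equals
  the van der Waals volume: V_vdw = 4/3 pi r_s^3;
* the effective radius ``r_e = K r_g``, where r_g is the grid radius of
  gyration and K = sqrt(5/3) ~ 1.29 maps the r_g of a uniform sphere back
  to its geometric radius.  r_e folds overall shape (elongation) into an
  equivalent sphere and, empirically, tracks the hydrodynamic radius of
  strongly hydrated solutes such as sugars.

Per-conformer radii are Boltzmann-averaged over the energy-window-filtered
ensemble *before* any Stokes-Einstein conversion; mixtures (e.g. anomeric
equilibria) combine the per-species ensemble averages by mole fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem_input import InputError, MoleculeSpec
from .conformers import (
    DEFAULT_TEMPERATURE_K,
    DEFAULT_WINDOW_KCAL,
    ConformerEnsemble,
    filter_energy_window,
    generate_conformers,
)
from .molgrid import (
    BONDI_TABLE,
    DEFAULT_SPACING_A,
    VdwRadiiTable,
    build_grid,
    gyration_radius,
    vdw_volume,
)

__all__ = [
    "K_SPHERE",
    "ConformerRadii",
    "RadiusEstimate",
    "simple_radius",
    "effective_radius",
    "average_radius",
    "mixture_radius",
    "estimate_radii",
]

#: Exact sphere conversion coefficient K = sqrt(5/3); rounds to 1.29.
K_SPHERE = math.sqrt(5.0 / 3.0)

WEIGHT_SUM_TOL = 1e-6


def simple_radius(v_vdw: float) -> float:
    """Radius (Å) of the sphere with volume ``v_vdw`` (ų): (3V/4pi)^(1/3)."""
    if v_vdw <= 0:
        raise InputError("van der Waals volume must be positive")
    return (3.0 * v_vdw / (4.0 * math.pi)) ** (1.0 / 3.0)


def effective_radius(r_g: float, k: float = K_SPHERE) -> float:
    """Effective radius r_e = K r_g (Å); default K = sqrt(5/3) ~ 1.29."""
    if r_g < 0:
        raise InputError("radius of gyration cannot be negative")
    if k <= 0:
        raise InputError("conversion coefficient K must be positive")
    return k * r_g


def average_radius(values, weights) -> float:
    """Weighted ensemble-average radius sum_i w_i r_i.

    Radii are averaged before the Stokes-Einstein step; averaging the
    diffusion coefficients instead would give a systematically different
    answer (Jensen's inequality for the convex map r -> 1/r).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise InputError("values and weights must have equal length")
    if abs(weights.sum() - 1.0) > WEIGHT_SUM_TOL:
        raise InputError(f"weights sum to {weights.sum()!r}, expected 1")
    return float(np.dot(weights, values))


@dataclass(frozen=True)
class ConformerRadii:
    """Radii of a single conformer with its ensemble weight."""

    v_vdw: float
    r_s: float
    r_g: float
    r_e: float
    weight: float


@dataclass(frozen=True)
class RadiusEstimate:
    """Ensemble (or mixture) radius estimate with full provenance."""

    name: str
    per_conformer: tuple[ConformerRadii, ...]
    r_s_mean: float
    r_e_mean: float
    k: float = K_SPHERE
    spacing: float = DEFAULT_SPACING_A
    radii_set: str = "bondi1964"
    window: float = DEFAULT_WINDOW_KCAL
    temperature: float = DEFAULT_TEMPERATURE_K
    extras: dict = field(default_factory=dict)

    @property
    def n_conformers(self) -> int:
        return len(self.per_conformer)

    def __post_init__(self) -> None:
        if self.r_s_mean <= 0 or self.r_e_mean <= 0:
            raise InputError("ensemble radii must be positive")


def _ensemble_estimate(
    name: str,
    ens: ConformerEnsemble,
    spacing: float,
    radii_table: VdwRadiiTable,
    k: float,
    window: float,
) -> RadiusEstimate:
    weights = ens.weights
    records = []
    for conf, w in zip(ens.conformers, weights):
        grid = build_grid(conf, spacing=spacing, radii=radii_table)
        v = vdw_volume(grid)
        rg = gyration_radius(grid)
        records.append(
            ConformerRadii(
                v_vdw=v,
                r_s=simple_radius(v),
                r_g=rg,
                r_e=effective_radius(rg, k),
                weight=float(w),
            )
        )
    r_s_mean = average_radius([r.r_s for r in records], weights)
    r_e_mean = average_radius([r.r_e for r in records], weights)
    return RadiusEstimate(
        name=name,
        per_conformer=tuple(records),
        r_s_mean=r_s_mean,
        r_e_mean=r_e_mean,
        k=k,
        spacing=spacing,
        radii_set=radii_table.name,
        window=window,
        temperature=ens.temperature,
    )


def mixture_radius(
    component_estimates: list[tuple[RadiusEstimate, float]], name: str | None = None
) -> RadiusEstimate:
    """Mole-fraction-weighted combination of per-species radius estimates.

    The combination happens at the radius level, after each species'
    Boltzmann average; per-conformer records are concatenated with their
    weights scaled by the mole fractions.
    """
    if not component_estimates:
        raise InputError("no components given")
    total = sum(f for _, f in component_estimates)
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise InputError(f"mixture fractions sum to {total!r}, expected 1")
    first = component_estimates[0][0]
    records = tuple(
        ConformerRadii(r.v_vdw, r.r_s, r.r_g, r.r_e, r.weight * frac)
        for est, frac in component_estimates
        for r in est.per_conformer
    )
    return RadiusEstimate(
        name=name or "+".join(est.name for est, _ in component_estimates),
        per_conformer=records,
        r_s_mean=sum(f * est.r_s_mean for est, f in component_estimates),
        r_e_mean=sum(f * est.r_e_mean for est, f in component_estimates),
        k=first.k,
        spacing=first.spacing,
        radii_set=first.radii_set,
        window=first.window,
        temperature=first.temperature,
    )


def estimate_radii(
    spec: MoleculeSpec,
    spacing: float = DEFAULT_SPACING_A,
    radii_table: VdwRadiiTable = BONDI_TABLE,
    window: float = DEFAULT_WINDOW_KCAL,
    temperature: float = DEFAULT_TEMPERATURE_K,
    k: float = K_SPHERE,
    seed: int = 1,
    n_embed: int | None = None,
) -> RadiusEstimate:
    """Full pipeline: conformers -> energy window -> grids -> averaged r_s, r_e.

    For a mixture spec each component is processed independently and the
    component averages are combined by mole fraction.
    """
    if spec.is_mixture:
        parts = []
        for comp, frac in spec.components:
            est = estimate_radii(
                comp,
                spacing=spacing,
                radii_table=radii_table,
                window=window,
                temperature=temperature,
                k=k,
                seed=seed,
                n_embed=n_embed,
            )
            parts.append((est, frac))
        return mixture_radius(parts, name=spec.name)

    ens = generate_conformers(
        spec, n_embed=n_embed, seed=seed, temperature=temperature
    )
    ens = filter_energy_window(ens, window)
    return _ensemble_estimate(spec.name, ens, spacing, radii_table, k, window)
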