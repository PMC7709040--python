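"""End-to-end convenience: spec -> radius estimate -> diffusion coefficients."""

from __future__ import annotations

from .chem_input import MoleculeSpec
from .diffusion import (
    DiffusionResult,
    PhysicalConditions,
    WATER_298K,
    small_radius_correction,
    stokes_einstein,
)
from .radii import RadiusEstimate, estimate_radii

__all__ = ["compute_diffusion", "diffusion_from_estimate"]


def diffusion_from_estimate(
    est: RadiusEstimate,
    conditions: PhysicalConditions = WATER_298K,
    small_radius_factor: float | None = None,
    small_radius_threshold: float = 3.0,
) -> DiffusionResult:
    """Stokes-Einstein conversion of an ensemble radius estimate.

    The ensemble-averaged radii (not per-conformer coefficients) are
    converted.  The small-radius multiplicative correction is applied to
    both channels only when a factor is given and r_s falls below the
    threshold.
    """
    d_s = stokes_einstein(est.r_s_mean, conditions)
    d_e = stokes_einstein(est.r_e_mean, conditions)
    corrections: tuple[str, ...] = ()
    if small_radius_factor is not None and est.r_s_mean < small_radius_threshold:
        d_s = small_radius_correction(
            d_s, est.r_s_mean, small_radius_factor, small_radius_threshold
        )
        d_e = small_radius_correction(
            d_e, est.r_s_mean, small_radius_factor, small_radius_threshold
        )
        corrections = (f"small_radius_factor={small_radius_factor}",)
    return DiffusionResult(
        name=est.name,
        d_s=d_s,
        d_e=d_e,
        r_s=est.r_s_mean,
        r_e=est.r_e_mean,
        conditions=conditions,
        corrections=corrections,
    )


def compute_diffusion(
    spec: MoleculeSpec,
    conditions: PhysicalConditions = WATER_298K,
    seed: int = 1,
    small_radius_factor: float | None = None,
    **radii_kwargs,
) -> tuple[RadiusEstimate, DiffusionResult]:
    """Full pipeline for one molecule or mixture; returns (radii, diffusion)."""
    est = estimate_radii(spec, seed=seed, temperature=conditions.temperature, **radii_kwargs)
    return est, diffusion_from_estimate(
        est, conditions, small_radius_factor=small_radius_factor
    )
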