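"""Conformer ensemble generation, energy-window filtering and Boltzmann weights.

Ensembles are produced by stochastic distance-geometry embedding (ETKDGv3)
followed by MMFF94 optimization.  Conformers within a relative-energy
window (default 3 kcal/mol, strict) of the minimum are retained and
populated with Boltzmann weights at a stated temperature; the 3 kcal/mol
cutoff keeps every conformer whose population exceeds ~1% of the most
stable one at 298 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign, rdMolDescriptors

from .chem_input import InputError, MoleculeSpec, UnsupportedStructureError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "Conformer",
    "ConformerEnsemble",
    "ConformerGenerationError",
    "generate_conformers",
    "filter_energy_window",
    "boltzmann_weights",
    "write_sdf",
]

#: Molar gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98720425e-3

DEFAULT_WINDOW_KCAL = 3.0
DEFAULT_TEMPERATURE_K = 298.0
#: Heavy-atom best-fit RMSD below which two conformers count as duplicates.
DEDUP_RMSD_A = 0.5


class ConformerGenerationError(RuntimeError):
    """Raised when 3-D embedding fails for a molecule."""


@dataclass(frozen=True)
class Conformer:
    """One optimized 3-D conformer: element symbols, coordinates (Å), energy (kcal/mol)."""

    elements: tuple[str, ...]
    coords: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.elements), 3):
            raise InputError("coordinate array does not match atom count")
        if not math.isfinite(self.energy):
            raise InputError("conformer energy is not finite")


@dataclass(frozen=True)
class ConformerEnsemble:
    """Energy-sorted conformers with relative energies and Boltzmann weights."""

    conformers: tuple[Conformer, ...]
    temperature: float = DEFAULT_TEMPERATURE_K

    @property
    def delta_e(self) -> np.ndarray:
        e = np.array([c.energy for c in self.conformers])
        return e - e[0]

    @property
    def weights(self) -> np.ndarray:
        return boltzmann_weights(self.delta_e, self.temperature)

    def __len__(self) -> int:
        return len(self.conformers)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise InputError("ensemble must contain at least one conformer")
        energies = [c.energy for c in self.conformers]
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise InputError("conformers must be sorted by energy ascending")


def boltzmann_weights(delta_e, temperature: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
    """Normalized Boltzmann populations w_i = exp(-dE_i/RT) / sum_j exp(-dE_j/RT).

    ``delta_e`` are energies in kcal/mol relative to the ensemble minimum, so
    the first entry (and all others) must be >= 0.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    if delta_e.size == 0:
        raise InputError("delta_e is empty")
    if np.any(delta_e < 0):
        raise InputError("delta_e contains negative entries; reference to the minimum")
    if temperature <= 0:
        raise InputError("temperature must be positive")
    w = np.exp(-delta_e / (GAS_CONSTANT_KCAL * temperature))
    return w / w.sum()


def filter_energy_window(
    ens: ConformerEnsemble, window: float = DEFAULT_WINDOW_KCAL
) -> ConformerEnsemble:
    """Retain conformers with dE strictly below ``window`` kcal/mol.

    The minimum-energy conformer is always retained; the threshold is
    exclusive, so a conformer at exactly the window energy is dropped.
    """
    if window <= 0:
        raise InputError("energy window must be positive")
    de = ens.delta_e
    kept = tuple(c for c, d in zip(ens.conformers, de) if d < window)
    return replace(ens, conformers=kept)


def _n_embeddings(mol: Chem.Mol, n_embed: int | None) -> int:
    if n_embed is not None:
        return n_embed
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    return int(min(500, 60 + 40 * n_rot))


def _deduplicate(mol: Chem.Mol, conf_ids: list[int], energies: dict[int, float]) -> list[int]:
    """Drop conformers within DEDUP_RMSD_A heavy-atom RMSD of a kept, lower-energy one."""
    heavy = Chem.RemoveHs(Chem.Mol(mol))
    kept: list[int] = []
    for cid in sorted(conf_ids, key=lambda c: energies[c]):
        dup = False
        for ref in kept:
            rms = rdMolAlign.GetBestRMS(heavy, heavy, prbId=cid, refId=ref, maxMatches=500)
            if rms < DEDUP_RMSD_A:
                dup = True
                break
        if not dup:
            kept.append(cid)
    return kept


def generate_conformers(
    spec: MoleculeSpec,
    n_embed: int | None = None,
    seed: int = 1,
    ff: str = "MMFF94",
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> ConformerEnsemble:
    """Generate an MMFF-optimized conformer ensemble for a single species.

    ETKDGv3 embedding is run ``n_embed`` times (by default scaled with the
    rotatable-bond count, capped at 500) with a fixed random seed, every
    embedding is MMFF-optimized, and near-identical geometries (heavy-atom
    best-fit RMSD < 0.5 Å) are collapsed onto the lower-energy member.
    Deterministic for a fixed seed.
    """
    if spec.is_mixture:
        raise InputError(
            f"{spec.name!r} is a mixture; generate conformers per component"
        )
    if ff.upper() not in ("MMFF", "MMFF94", "MMFF94S"):
        raise InputError(f"unsupported force field {ff!r}")
    variant = "MMFF94s" if ff.upper() == "MMFF94S" else "MMFF94"

    mol = Chem.Mol(spec.mol)
    if not AllChem.MMFFHasAllMoleculeParams(mol):
        raise UnsupportedStructureError(
            f"{spec.name!r}: MMFF94 parameters missing for some atoms"
        )

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = 0.1
    params.useRandomCoords = False
    n = _n_embeddings(mol, n_embed)
    cids = list(AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params))
    if not cids:
        params.useRandomCoords = True
        cids = list(AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params))
    if not cids:
        raise ConformerGenerationError(f"embedding failed for {spec.name!r}")

    results = AllChem.MMFFOptimizeMoleculeConfs(
        mol, mmffVariant=variant, maxIters=2000
    )
    energies = {cid: e for cid, (converged, e) in zip(cids, results)}
    kept = _deduplicate(mol, cids, energies)

    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    conformers = tuple(
        Conformer(
            elements=elements,
            coords=np.array(mol.GetConformer(cid).GetPositions(), dtype=float),
            energy=float(energies[cid]),
        )
        for cid in kept
    )
    return ConformerEnsemble(conformers=conformers, temperature=temperature)


def write_sdf(
    spec: MoleculeSpec, ens: ConformerEnsemble, path: str
) -> None:
    """Write retained conformers to an SDF with energy / dE / weight properties."""
    writer = Chem.SDWriter(str(path))
    de = ens.delta_e
    w = ens.weights
    try:
        for i, conf in enumerate(ens.conformers):
            mol = Chem.Mol(spec.mol)
            mol.RemoveAllConformers()
            c = Chem.Conformer(mol.GetNumAtoms())
            for j, (x, y, z) in enumerate(conf.coords):
                c.SetAtomPosition(j, (float(x), float(y), float(z)))
            mol.AddConformer(c, assignId=True)
            mol.SetProp("_Name", f"{spec.name}_conf{i}")
            mol.SetProp("energy_kcal_mol", f"{conf.energy:.6f}")
            mol.SetProp("delta_e_kcal_mol", f"{de[i]:.6f}")
            mol.SetProp("boltzmann_weight", f"{w[i]:.6f}")
            writer.write(mol)
    finally:
        writer.close()
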