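"""Molecule input handling: parsing, protonation conventions, mixtures.

Structures are parsed with RDKit from SMILES or MolBlock (V2000) records.
Before any 3-D work the ionization conventions used throughout the package
are applied: carboxylic acids are kept in their neutral (free) form and
basic amines are protonated.  These conventions reflect how small
zwitterionic solutes (amino acids, amino drugs) were modelled for the
radius estimates; they are deliberately not a pKa model.

A :class:`MoleculeSpec` is either a single species or a fixed-ratio mixture
of species (e.g. the alpha/beta anomeric equilibrium of d-glucose in water,
36:64).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "MoleculeSpec",
    "InputError",
    "UnsupportedStructureError",
    "parse_molecule",
    "apply_protonation_rules",
    "make_mixture",
]

FRACTION_TOL = 1e-9


class InputError(ValueError):
    """Raised for malformed records, bad fractions, or invalid parameters."""


class UnsupportedStructureError(ValueError):
    """Raised for structures the pipeline cannot handle (radicals, odd elements)."""


# Ionizable-group patterns.  The amine pattern deliberately excludes amides,
# sulfonamides, aromatic nitrogens and anilines (N bonded to an aromatic
# atom): those are not basic under the convention applied here.  Guanidines
# are matched separately on their sp2 imine nitrogen, so that the group as a
# whole gains one proton (guanidinium, +1).
_CARBOXYLATE = Chem.MolFromSmarts("[CX3](=O)[OX1-]")
_BASIC_AMINE = Chem.MolFromSmarts(
    "[NX3;+0;!$([N]C=[O,S,N]);!$([N]S(=O)=O);!$([N]a);!$([N]=*);!$([N][NX2]=*)]"
)
_GUANIDINE_N = Chem.MolFromSmarts("[NX2;+0]=[CX3]([NX3])[NX3]")

_SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "S", "Cl", "F", "Br", "I", "P"}


@dataclass(frozen=True)
class MoleculeSpec:
    """A named input structure, or a fixed-ratio mixture of structures.

    Attributes
    ----------
    name:
        Text label used in reports.
    mol:
        RDKit molecule with explicit hydrogens, after the protonation
        conventions.  ``None`` for mixtures.
    net_charge:
        Formal charge of the protonation-adjusted structure.
    components:
        For mixtures, a tuple of ``(MoleculeSpec, mole_fraction)`` pairs.
        Fractions sum to 1.  Empty for single species.
    """

    name: str
    mol: Chem.Mol | None = None
    net_charge: int = 0
    components: tuple[tuple["MoleculeSpec", float], ...] = field(default_factory=tuple)

    @property
    def is_mixture(self) -> bool:
        return len(self.components) > 0

    @property
    def smiles(self) -> str | None:
        if self.mol is None:
            return None
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))

    @property
    def mol_weight(self) -> float:
        if self.is_mixture:
            return sum(f * c.mol_weight for c, f in self.components)
        return Descriptors.MolWt(self.mol)

    def __post_init__(self) -> None:
        if self.mol is not None and self.components:
            raise InputError(
                f"{self.name!r}: a spec is either a single species or a mixture, not both"
            )
        if self.components:
            total = sum(f for _, f in self.components)
            if abs(total - 1.0) > FRACTION_TOL:
                raise InputError(
                    f"{self.name!r}: mole fractions sum to {total!r}, expected 1"
                )
            for _, f in self.components:
                if not (0.0 < f <= 1.0):
                    raise InputError(f"{self.name!r}: mole fraction {f!r} outside (0, 1]")


def _sanitize(mol: Chem.Mol, name: str) -> Chem.Mol:
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises many subclasses
        raise InputError(f"cannot sanitize record for {name!r}: {exc}") from exc
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons() > 0:
            raise UnsupportedStructureError(
                f"{name!r}: radical centre at atom {atom.GetIdx()} is not supported"
            )
        if atom.GetSymbol() not in _SUPPORTED_ELEMENTS:
            raise UnsupportedStructureError(
                f"{name!r}: unsupported element {atom.GetSymbol()!r}"
            )
    return mol


def parse_molecule(record: str, name: str) -> MoleculeSpec:
    """Parse a SMILES string or V2000 MolBlock into a protonation-adjusted spec.

    Explicit hydrogens are added and the carboxy/amine conventions applied
    (see :func:`apply_protonation_rules`).

    Raises
    ------
    InputError
        If the record cannot be parsed or sanitized.
    UnsupportedStructureError
        For radicals or elements outside the supported set.
    """
    if not record.strip():
        raise InputError(f"empty record for {name!r}")
    if "\n" in record or "M  END" in record:
        # keep leading blank title line intact: V2000 line numbering is fixed
        mol = Chem.MolFromMolBlock(record, sanitize=False, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(record.strip(), sanitize=False)
    if mol is None:
        raise InputError(f"unparsable record for {name!r}: {record[:60]!r}")
    mol = _sanitize(mol, name)
    mol = Chem.AddHs(mol)
    spec = MoleculeSpec(name=name, mol=mol, net_charge=Chem.GetFormalCharge(mol))
    return apply_protonation_rules(spec)


def apply_protonation_rules(spec: MoleculeSpec) -> MoleculeSpec:
    """Apply the fixed ionization conventions; idempotent.

    * every carboxylate (-COO-) becomes neutral -COOH;
    * every basic aliphatic amine (primary/secondary/tertiary; not amide,
      sulfonamide, aniline or aromatic N) is protonated to +1;
    * guanidine groups are protonated once on the imine nitrogen
      (guanidinium, +1);
    * all other groups, including sulfonates, keep their drawn charges.
    """
    if spec.is_mixture:
        comps = tuple(
            (apply_protonation_rules(c), f) for c, f in spec.components
        )
        return replace(spec, components=comps)

    mol = Chem.RWMol(spec.mol)

    for match in mol.GetSubstructMatches(_CARBOXYLATE):
        o = mol.GetAtomWithIdx(match[2])
        o.SetFormalCharge(0)
        o.SetNumExplicitHs(o.GetNumExplicitHs() + 1)

    for match in mol.GetSubstructMatches(_GUANIDINE_N):
        n = mol.GetAtomWithIdx(match[0])
        n.SetFormalCharge(1)
        n.SetNumExplicitHs(n.GetNumExplicitHs() + 1)

    for match in mol.GetSubstructMatches(_BASIC_AMINE):
        n = mol.GetAtomWithIdx(match[0])
        n.SetFormalCharge(1)
        n.SetNumExplicitHs(n.GetNumExplicitHs() + 1)

    out = mol.GetMol()
    Chem.SanitizeMol(out)
    out = Chem.AddHs(out)
    return replace(spec, mol=out, net_charge=Chem.GetFormalCharge(out))


def make_mixture(
    components: list[tuple[MoleculeSpec, float]], name: str | None = None
) -> MoleculeSpec:
    """Build a fixed-ratio mixture spec; fractions are renormalized to sum to 1.

    Raises
    ------
    InputError
        If fewer than two components are given or any fraction is not positive.
    """
    if len(components) < 2:
        raise InputError("a mixture needs at least two components")
    for comp, frac in components:
        if frac <= 0:
            raise InputError(f"non-positive mole fraction {frac!r} for {comp.name!r}")
    total = sum(f for _, f in components)
    norm = tuple((c, f / total) for c, f in components)
    if name is None:
        name = "+".join(c.name for c, _ in components)
    return MoleculeSpec(name=name, components=norm)
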