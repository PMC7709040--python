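"""The 18-compound benchmark set as SMILES, with mixture definitions.

Sugars are encoded as the pyranose/furanose form dominant in water;
d-glucose is a 36:64 alpha:beta anomeric mixture at equilibrium.  Amino
acids are the l-enantiomers; loxoprofen is the (2S,2'R)-isomer (the
(2S,2'S)-isomer gives an almost identical conformational profile).  Fast
Green FCF is modelled as the free dye anion (three sulfonates plus one
iminium, net charge -2) without counterions.
"""

from __future__ import annotations

from .chem_input import MoleculeSpec, make_mixture, parse_molecule

__all__ = ["SMILES", "MIXTURES", "benchmark_spec", "benchmark_names"]

SMILES: dict[str, str] = {
    # monosaccharides
    "xylose": "C1[C@@H]([C@H]([C@@H]([C@H](O1)O)O)O)O",
    "fructose": "C1[C@H]([C@H]([C@@H]([C@](O1)(CO)O)O)O)O",
    "galactose": "C([C@@H]1[C@@H]([C@@H]([C@H]([C@H](O1)O)O)O)O)O",
    "alpha-glucose": "C([C@@H]1[C@H]([C@@H]([C@H]([C@H](O1)O)O)O)O)O",
    "beta-glucose": "C([C@@H]1[C@H]([C@@H]([C@H]([C@@H](O1)O)O)O)O)O",
    # disaccharides
    "sucrose": "C([C@@H]1[C@H]([C@@H]([C@H]([C@H](O1)O[C@]2([C@H]([C@@H]([C@H](O2)CO)O)O)CO)O)O)O)O",
    "lactose": "C([C@@H]1[C@@H]([C@@H]([C@H]([C@@H](O1)O[C@@H]2[C@H](O[C@H]([C@@H]([C@H]2O)O)O)CO)O)O)O)O",
    "trehalose": "C([C@@H]1[C@H]([C@@H]([C@H]([C@H](O1)O[C@@H]2[C@@H]([C@H]([C@@H]([C@H](O2)CO)O)O)O)O)O)O)O",
    "maltose": "C([C@@H]1[C@H]([C@@H]([C@H]([C@H](O1)O[C@@H]2[C@H](O[C@H]([C@@H]([C@H]2O)O)O)CO)O)O)O)O",
    # amino acids (l)
    "alanine": "C[C@@H](C(=O)O)N",
    "proline": "C1C[C@H](NC1)C(=O)O",
    "threonine": "C[C@H]([C@@H](C(=O)O)N)O",
    "leucine": "CC(C)C[C@@H](C(=O)O)N",
    "aspartic acid": "C([C@@H](C(=O)O)N)C(=O)O",
    "arginine": "C(C[C@@H](C(=O)O)N)CN=C(N)N",
    # drugs
    "aspirin": "CC(=O)OC1=CC=CC=C1C(=O)O",
    "salbutamol": "CC(C)(C)NCC(C1=CC(=C(C=C1)O)CO)O",
    "loxoprofen": "C[C@@H](C(=O)O)c1ccc(C[C@H]2CCCC2=O)cc1",
    "fast green fcf": (
        "CCN(CC1=CC(=CC=C1)S(=O)(=O)[O-])C2=CC=C(C=C2)C(=C3C=CC(=[N+](CC)CC4=CC"
        "(=CC=C4)S(=O)(=O)[O-])C=C3)C5=CC(=C(C=C5)O)S(=O)(=O)[O-]"
    ),
}

#: Mixtures defined as {name: [(component name, mole fraction), ...]}.
MIXTURES: dict[str, list[tuple[str, float]]] = {
    "glucose": [("alpha-glucose", 0.36), ("beta-glucose", 0.64)],
}


def benchmark_spec(name: str) -> MoleculeSpec:
    """Protonation-adjusted spec for one benchmark compound (or mixture)."""
    if name in MIXTURES:
        comps = [
            (parse_molecule(SMILES[cname], cname), frac)
            for cname, frac in MIXTURES[name]
        ]
        return make_mixture(comps, name=name)
    return parse_molecule(SMILES[name], name)


def benchmark_names() -> list[str]:
    """The 18 benchmark compounds in report order."""
    return [
        "xylose", "fructose", "galactose", "glucose",
        "sucrose", "lactose", "trehalose", "maltose",
        "alanine", "proline", "threonine", "leucine",
        "aspartic acid", "arginine",
        "aspirin", "salbutamol", "loxoprofen", "fast green fcf",
    ]
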