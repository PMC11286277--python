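"""Deterministic synthetic molecule libraries for tests and demos.

Real runs would draw the reference library from a large purchasable-compound
collection; for desk-scale work this module enumerates small drug-like
molecules by decorating ring scaffolds with common substituents.  Every
product is valid, contains a ring, and carries at least one exocyclic
substituent, so it decomposes into >= 2 fragments.  Generation is seeded and
reproducible: the same arguments always yield the same SMILES list.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .chem import Molecule, Fragment, decompose_molecule
from .errors import ConfigError
from .space import MoleculeLibrary

__all__ = ["SCAFFOLDS", "SUBSTITUENTS", "make_fixture_library", "fixture_fragments"]

# ring scaffolds; substitution happens on ring atoms with free valence
SCAFFOLDS = [
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "C1CCCCC1",      # cyclohexane
    "c1ccsc1",       # thiophene
    "c1ccoc1",       # furan
    "c1cncnc1",      # pyrimidine
    "C1CCNCC1",      # piperidine
    "c1cc[nH]c1",    # pyrrole
]

# substituents attach through their first atom
SUBSTITUENTS = ["C", "O", "N", "F", "Cl", "CC", "C(C)C", "C(=O)N", "OC", "C#N"]


def _attach(scaffold: Chem.Mol, placements: list[tuple[int, str]]) -> Molecule | None:
    """Bond each substituent's first atom to the given scaffold ring atom."""
    rw = Chem.RWMol(scaffold)
    for ring_atom, sub_smiles in placements:
        sub = Chem.MolFromSmiles(sub_smiles)
        offset = rw.GetNumAtoms()
        rw.InsertMol(sub)
        rw.AddBond(ring_atom, offset, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Molecule(Chem.MolToSmiles(mol))


def _substitutable_atoms(scaffold: Chem.Mol) -> list[int]:
    out = []
    for atom in scaffold.GetAtoms():
        if atom.IsInRing() and atom.GetTotalNumHs() > 0 and atom.GetAtomicNum() == 6:
            out.append(atom.GetIdx())
    return out


def make_fixture_library(
    n_scaffolds: int = 4,
    n_substituents: int = 5,
    seed: int = 0,
    n_molecules: int | None = None,
    name: str = "fixture",
) -> MoleculeLibrary:
    """Scaffold-substituent enumeration: singles first, then seeded doubles.

    Default size is ``2 * n_scaffolds * n_substituents`` molecules (all
    mono-substituted products, then randomly placed di-substituted ones).
    """
    if n_scaffolds < 1 or n_substituents < 1:
        raise ConfigError("counts must be >= 1")
    if n_scaffolds > len(SCAFFOLDS) or n_substituents > len(SUBSTITUENTS):
        raise ConfigError(
            f"at most {len(SCAFFOLDS)} scaffolds and {len(SUBSTITUENTS)} substituents available"
        )
    rng = np.random.default_rng(seed)
    scaffolds = [Chem.MolFromSmiles(s) for s in SCAFFOLDS[:n_scaffolds]]
    subs = SUBSTITUENTS[:n_substituents]
    target = n_molecules if n_molecules is not None else 2 * n_scaffolds * n_substituents

    lib = MoleculeLibrary(name=name)
    for scaffold in scaffolds:  # all mono-substituted products, fixed order
        sites = _substitutable_atoms(scaffold)
        for sub in subs:
            if len(lib) >= target:
                return lib
            mol = _attach(scaffold, [(sites[0], sub)])
            if mol is not None:
                lib.add(mol)
    attempts = 0
    while len(lib) < target and attempts < 200 * target:  # seeded di-substituted fill
        attempts += 1
        scaffold = scaffolds[int(rng.integers(0, len(scaffolds)))]
        sites = _substitutable_atoms(scaffold)
        if len(sites) < 2:
            continue
        pos = rng.choice(len(sites), size=2, replace=False)
        placements = [
            (sites[int(p)], subs[int(rng.integers(0, len(subs)))]) for p in pos
        ]
        mol = _attach(scaffold, placements)
        if mol is not None:
            lib.add(mol)
    return lib


def fixture_fragments(n: int, seed: int = 0) -> list[Fragment]:
    """First ``n`` distinct fragments from decomposing a fixture library.

    Useful for building spaces of an exact fragment count (e.g. an
    eight-fragment tree).
    """
    lib = make_fixture_library(
        n_scaffolds=len(SCAFFOLDS), n_substituents=len(SUBSTITUENTS), seed=seed,
        n_molecules=10 * n,
    )
    out: list[Fragment] = []
    seen: set[str] = set()
    for mol in lib:
        for frag in decompose_molecule(mol).fragments:
            if frag.smiles not in seen:
                seen.add(frag.smiles)
                out.append(frag)
                if len(out) == n:
                    return out
    raise ConfigError(f"fixture library yielded only {len(out)} distinct fragments, need {n}")
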