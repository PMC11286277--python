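"""Molecules, fragments, and the cut/reassemble rule.

A molecule is decomposed by cutting every *acyclic single bond incident to a
ring atom* (ring-to-substituent bonds and single bonds linking two ring
systems).  Each cut leaves one attachment marker — a dummy atom, written ``*``
in SMILES — on both sides, so the pieces can later be rejoined through any
pairing of markers.  Bonds inside rings are never cut; a molecule without
rings decomposes to itself.

The :class:`Decomposition` remembers which marker was joined to which
(``topology``), so reassembly of an unmodified decomposition reproduces the
source molecule exactly, and substituting attachment-compatible fragments
yields structural analogues.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

from .errors import AssemblyError, InputError, ValidityError

RDLogger.DisableLog("rdApp.*")  # SMILES parse failures are handled explicitly

__all__ = [
    "Molecule",
    "Fragment",
    "Decomposition",
    "canonical_smiles",
    "decompose_molecule",
    "assemble_fragments",
]


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string, raising :class:`InputError` if invalid."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@functools.lru_cache(maxsize=16384)
def _mol_from_canonical(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - canonical SMILES always re-parse
        raise InputError(f"unparsable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class Molecule:
    """A chemically valid molecule identified by its canonical SMILES."""

    smiles: str
    id: str | None = field(default=None, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str, id: str | None = None) -> "Molecule":
        return cls(canonical_smiles(smiles), id=id)

    def to_rdkit(self) -> Chem.Mol:
        return _mol_from_canonical(self.smiles)

    @property
    def n_heavy_atoms(self) -> int:
        return self.to_rdkit().GetNumHeavyAtoms()


@dataclass(frozen=True)
class Fragment:
    """A fragment whose attachment points are ``*`` dummy atoms in its SMILES.

    ``n_attachments`` always equals the number of dummy atoms; a fragment with
    zero markers is a complete molecule.  Attachment *slots* are numbered by
    the order dummy atoms appear in the canonical SMILES, which is also atom
    order when the string is re-parsed — this makes topology records
    unambiguous without explicit marker labels.
    """

    smiles: str
    n_attachments: int
    source_molecule_id: str | None = field(default=None, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str, source_molecule_id: str | None = None) -> "Fragment":
        canon = canonical_smiles(smiles)
        n_att = sum(1 for a in _mol_from_canonical(canon).GetAtoms() if a.GetAtomicNum() == 0)
        return cls(canon, n_att, source_molecule_id=source_molecule_id)

    def to_rdkit(self) -> Chem.Mol:
        return _mol_from_canonical(self.smiles)

    @property
    def n_heavy_atoms(self) -> int:
        """Heavy atoms, excluding attachment markers."""
        return sum(1 for a in self.to_rdkit().GetAtoms() if a.GetAtomicNum() > 0)


# topology record: (fragment_index, attachment_slot, fragment_index, attachment_slot)
Bond = tuple[int, int, int, int]


@dataclass
class Decomposition:
    """An ordered fragment list plus the plan for joining their markers."""

    fragments: list[Fragment]
    topology: list[Bond]

    @property
    def r(self) -> int:
        """Number of fragments."""
        return len(self.fragments)

    @property
    def t(self) -> int:
        """Total number of attachment points."""
        return sum(f.n_attachments for f in self.fragments)


def _cuttable_bond_indices(mol: Chem.Mol) -> list[int]:
    """Acyclic single bonds with at least one end on a ring atom."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().IsInRing() or bond.GetEndAtom().IsInRing():
            out.append(bond.GetIdx())
    return out


def _dummy_slots(frag: Chem.Mol) -> tuple[str, dict[int, int]]:
    """Canonical SMILES of a labelled fragment piece and cut-id -> slot map.

    ``frag`` carries cut identifiers as isotope labels on its dummy atoms.
    Slots are the ranks of dummy atoms in canonical SMILES output order.
    """
    clean = Chem.Mol(frag)
    cut_of_atom = {}
    for atom in clean.GetAtoms():
        if atom.GetAtomicNum() == 0:
            cut_of_atom[atom.GetIdx()] = atom.GetIsotope()
            atom.SetIsotope(0)
    smiles = Chem.MolToSmiles(clean)
    order = list(
        clean.GetPropsAsDict(includePrivate=True, includeComputed=True)[
            "_smilesAtomOutputOrder"
        ]
    )
    dummy_rank = {}
    slot = 0
    for atom_idx in order:
        if atom_idx in cut_of_atom:
            dummy_rank[cut_of_atom[atom_idx]] = slot
            slot += 1
    return smiles, dummy_rank


def decompose_molecule(mol: Molecule | str) -> Decomposition:
    """Cut all ring-exocyclic single bonds and record the joining topology.

    Returns a single-fragment, zero-attachment decomposition for acyclic
    molecules (the rule has nothing to cut).
    """
    if isinstance(mol, str):
        mol = Molecule.from_smiles(mol)
    rdmol = mol.to_rdkit()
    bonds = _cuttable_bond_indices(rdmol)
    if not bonds:
        return Decomposition(
            fragments=[Fragment(mol.smiles, 0, source_molecule_id=mol.id)],
            topology=[],
        )
    # isotope labels 1..n_cuts identify each cut on both resulting dummies
    labelled = Chem.FragmentOnBonds(
        rdmol, bonds, addDummies=True, dummyLabels=[(i + 1, i + 1) for i in range(len(bonds))]
    )
    pieces = Chem.GetMolFrags(labelled, asMols=True, sanitizeFrags=True)

    fragments: list[Fragment] = []
    endpoints: dict[int, list[tuple[int, int]]] = {}
    for frag_idx, piece in enumerate(pieces):
        smiles, slots = _dummy_slots(piece)
        fragments.append(
            Fragment(smiles, len(slots), source_molecule_id=mol.id)
        )
        for cut_id, slot in slots.items():
            endpoints.setdefault(cut_id, []).append((frag_idx, slot))

    topology: list[Bond] = []
    for cut_id in sorted(endpoints):
        ends = endpoints[cut_id]
        if len(ends) != 2:  # pragma: no cover - FragmentOnBonds guarantees pairs
            raise AssemblyError(f"cut {cut_id} has {len(ends)} endpoints")
        (fi, si), (fj, sj) = sorted(ends)
        topology.append((fi, si, fj, sj))
    return Decomposition(fragments=fragments, topology=topology)


def assemble_fragments(fragments: list[Fragment], topology: list[Bond]) -> Molecule:
    """Join fragments through their attachment markers into one molecule.

    Every attachment slot must be consumed by exactly one topology record;
    each record resolves two markers into a single bond between their
    neighbouring atoms.  Raises :class:`AssemblyError` for unmatched markers
    and :class:`ValidityError` if the product fails sanitization.
    """
    total = sum(f.n_attachments for f in fragments)
    if total % 2 != 0:
        raise AssemblyError(f"odd total number of attachment points: {total}")
    if len(topology) * 2 != total:
        raise AssemblyError(
            f"topology joins {len(topology) * 2} attachment points, fragments carry {total}"
        )

    combined = Chem.RWMol()
    offsets: list[int] = []
    dummy_atoms: list[list[int]] = []  # per fragment, dummy atom indices by slot
    for frag in fragments:
        piece = frag.to_rdkit()
        offset = combined.GetNumAtoms()
        offsets.append(offset)
        combined.InsertMol(piece)
        dummy_atoms.append(
            [offset + a.GetIdx() for a in piece.GetAtoms() if a.GetAtomicNum() == 0]
        )

    seen: set[tuple[int, int]] = set()
    to_remove: list[int] = []
    for fi, si, fj, sj in topology:
        for frag_idx, slot in ((fi, si), (fj, sj)):
            if frag_idx >= len(fragments) or slot >= len(dummy_atoms[frag_idx]):
                raise AssemblyError(f"topology references missing slot ({frag_idx}, {slot})")
            if (frag_idx, slot) in seen:
                raise AssemblyError(f"attachment slot ({frag_idx}, {slot}) joined twice")
            seen.add((frag_idx, slot))
        da, db = dummy_atoms[fi][si], dummy_atoms[fj][sj]
        na = [n.GetIdx() for n in combined.GetAtomWithIdx(da).GetNeighbors()]
        nb = [n.GetIdx() for n in combined.GetAtomWithIdx(db).GetNeighbors()]
        if len(na) != 1 or len(nb) != 1:
            raise AssemblyError("attachment marker must have exactly one neighbour")
        combined.AddBond(na[0], nb[0], Chem.BondType.SINGLE)
        to_remove.extend((da, db))

    for idx in sorted(to_remove, reverse=True):
        combined.RemoveAtom(idx)

    product = combined.GetMol()
    attempted = Chem.MolToSmiles(product)
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise ValidityError(f"assembled structure is not valid: {exc}", attempted) from exc
    return Molecule(Chem.MolToSmiles(product))
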