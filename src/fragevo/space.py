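"""Molecule-specific fragment search spaces.

For each lead molecule a private fragment library is built in three steps:
filter a reference library down to molecules whose properties clear
task-specific thresholds (the *intermediate library*), keep the N members
most fingerprint-similar to the lead, and pool the fragments from their
decompositions (always including the lead's own fragments).  A similarity
tree over the pooled fragments provides the path-code embedding used by the
optimizer.

The space only ever grows: :func:`expand_space` unions in fragments from
newly generated molecules, rebuilds the tree (pair similarities are cached
across rebuilds) and appends to the size/property history used to audit how
the space evolved during a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import oracles
from .chem import Decomposition, Fragment, Molecule, decompose_molecule
from .errors import ConfigError, InputError
from .similarity import build_similarity_matrix, fingerprint_similarity
from .tree import FragmentTree, build_tree

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeLibrary",
    "MoleculeSpecificSpace",
    "build_intermediate_library",
    "select_top_n_similar",
    "build_space",
    "expand_space",
    "space_growth_percent",
]

DEFAULT_TOP_N = 20  # molecules most similar to the lead that seed the space


@dataclass
class MoleculeLibrary:
    """Unique molecules plus per-molecule cached property values."""

    molecules: list[Molecule] = field(default_factory=list)
    name: str = ""
    properties: list[dict[str, float]] = field(default_factory=list)
    n_skipped: int = 0  # invalid inputs dropped while reading

    def __post_init__(self) -> None:
        if not self.properties:
            self.properties = [{} for _ in self.molecules]
        seen = set()
        for mol in self.molecules:
            if mol.smiles in seen:
                raise InputError(f"duplicate molecule in library: {mol.smiles}")
            seen.add(mol.smiles)

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    def add(self, mol: Molecule, props: dict[str, float] | None = None) -> bool:
        if any(m.smiles == mol.smiles for m in self.molecules):
            return False
        self.molecules.append(mol)
        self.properties.append(dict(props or {}))
        return True

    def ensure_properties(self, names: list[str], lead: Molecule | None = None) -> None:
        """Fill missing property caches; SIM requires a lead molecule."""
        for mol, cache in zip(self.molecules, self.properties):
            missing = [p for p in names if p not in cache]
            if missing:
                if "SIM" in missing and lead is None:
                    raise ConfigError("SIM property requires a lead molecule")
                cache.update(oracles.score(mol, lead if lead is not None else mol, missing))


def build_intermediate_library(
    lib: MoleculeLibrary, thresholds: dict[str, float]
) -> MoleculeLibrary:
    """Molecules whose every listed property meets its minimum value."""
    unknown = [p for p in thresholds if p != "SIM" and p not in oracles.registered_properties()]
    if unknown:
        raise ConfigError(f"unknown properties in thresholds: {unknown}")
    lib.ensure_properties([p for p in thresholds if p != "SIM"])
    keep_mols, keep_props = [], []
    for mol, cache in zip(lib.molecules, lib.properties):
        if all(cache[p] >= v for p, v in thresholds.items()):
            keep_mols.append(mol)
            keep_props.append(dict(cache))
    if thresholds and not keep_mols:
        logger.warning("no molecule passed the thresholds %s", thresholds)
    return MoleculeLibrary(molecules=keep_mols, name=lib.name, properties=keep_props)


def select_top_n_similar(lead: Molecule, s: MoleculeLibrary, n: int) -> list[Molecule]:
    """The N library molecules most fingerprint-similar to the lead.

    Returns all of ``s`` (similarity-sorted) when it holds fewer than N;
    ties keep library order (stable sort).
    """
    if n < 1:
        raise ConfigError("N must be >= 1")
    if len(s) == 0:
        raise InputError("intermediate library is empty; relax the property thresholds")
    sims = np.array([fingerprint_similarity(lead, m) for m in s])
    order = np.argsort(-sims, kind="stable")
    return [s.molecules[i] for i in order[:n]]


@dataclass
class MoleculeSpecificSpace:
    """A lead's private fragment library, its tree, and growth history."""

    lead: Molecule
    lead_decomposition: Decomposition
    fragments: list[Fragment]
    tree: FragmentTree
    source_molecules: list[Molecule]
    size_history: list[tuple[int, int]] = field(default_factory=list)
    property_history: list[tuple[int, dict[str, float]]] = field(default_factory=list)
    tracked_properties: list[str] = field(default_factory=list)
    _sim_cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def _record(self, iteration: int) -> None:
        self.size_history.append((iteration, self.n_fragments))
        if self.tracked_properties:
            means = {
                p: float(
                    np.mean(
                        [
                            oracles.score(m, self.lead, [p])[p]
                            for m in self.source_molecules
                        ]
                    )
                )
                for p in self.tracked_properties
            }
            self.property_history.append((iteration, means))


def _dedupe(fragments: list[Fragment]) -> list[Fragment]:
    seen: set[str] = set()
    out: list[Fragment] = []
    for frag in fragments:
        if frag.smiles not in seen:
            seen.add(frag.smiles)
            out.append(frag)
    return out


def build_space(
    lead: Molecule,
    s: MoleculeLibrary,
    n: int = DEFAULT_TOP_N,
    tracked_properties: list[str] | None = None,
) -> MoleculeSpecificSpace:
    """Initial search space: lead fragments plus fragments of the top-N molecules."""
    top = select_top_n_similar(lead, s, n)
    lead_decomp = decompose_molecule(lead)
    pool = list(lead_decomp.fragments)
    for mol in top:
        pool.extend(decompose_molecule(mol).fragments)
    fragments = _dedupe(pool)
    cache: dict[tuple[str, str], float] = {}
    tree = build_tree(fragments, build_similarity_matrix(fragments, cache))
    space = MoleculeSpecificSpace(
        lead=lead,
        lead_decomposition=lead_decomp,
        fragments=fragments,
        tree=tree,
        source_molecules=list(top),
        tracked_properties=list(tracked_properties or []),
        _sim_cache=cache,
    )
    space._record(0)
    return space


def expand_space(
    space: MoleculeSpecificSpace,
    new_mols: list[Molecule],
    iteration: int,
    accept=None,
) -> MoleculeSpecificSpace:
    """Union in the fragments of ``new_mols`` and rebuild the tree in place.

    ``accept`` is an optional predicate ``Molecule -> bool`` applied before
    decomposition (default: validity only, which canonicalization already
    guarantees).  Invalid molecules are skipped with a log entry.  The
    fragment set never shrinks.
    """
    known = {f.smiles for f in space.fragments}
    grew = False
    for mol in new_mols:
        try:
            mol = Molecule.from_smiles(mol.smiles, id=mol.id)
        except InputError:
            logger.warning("skipping invalid molecule during expansion: %r", mol.smiles)
            continue
        if accept is not None and not accept(mol):
            continue
        for frag in decompose_molecule(mol).fragments:
            if frag.smiles not in known:
                known.add(frag.smiles)
                space.fragments.append(frag)
                grew = True
        if all(m.smiles != mol.smiles for m in space.source_molecules):
            space.source_molecules.append(mol)
    if grew:
        space.tree = build_tree(
            space.fragments, build_similarity_matrix(space.fragments, space._sim_cache)
        )
    space._record(iteration)
    return space


def space_growth_percent(space_or_history: MoleculeSpecificSpace | list[tuple[int, int]]) -> float:
    """Relative growth of the fragment library, 100 x (final - initial)/initial."""
    history = (
        space_or_history.size_history
        if isinstance(space_or_history, MoleculeSpecificSpace)
        else space_or_history
    )
    if len(history) < 2:
        raise InputError("size history needs at least two entries")
    initial, final = history[0][1], history[-1][1]
    if initial == 0:
        raise InputError("initial search-space size is zero; growth undefined")
    return 100.0 * (final - initial) / initial
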