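"""Fragment and molecule similarity.

Fragment similarity is the maximum of two complementary views:

* ``tanimoto_mcs`` — a graph view: the maximum common substructure (MCS)
  Tanimoto, |MCS| / (|f1| + |f2| - |MCS|) over heavy atoms, with attachment
  markers stripped before matching;
* ``levenshtein_similarity`` — a string view: 1 - d/max(len) on the canonical
  fragment SMILES (markers included), where d is the Levenshtein edit
  distance.  Normalizing the distance keeps both terms on [0, 1] so taking
  their maximum is meaningful.

Whole molecules are compared by Tanimoto similarity of Morgan (circular,
radius 2, 2048-bit) fingerprints.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import edlib
import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFMCS, rdFingerprintGenerator

from .chem import Fragment, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "tanimoto_mcs",
    "levenshtein_similarity",
    "pair_similarity",
    "build_similarity_matrix",
    "fingerprint_similarity",
]

MCS_TIMEOUT_S = 1  # per-pair cap; on timeout the best bound so far is used


@functools.lru_cache(maxsize=8192)
def _stripped(frag_smiles: str) -> Chem.Mol:
    """Fragment structure with attachment markers removed."""
    mol = Chem.RWMol(Chem.MolFromSmiles(frag_smiles))
    for idx in sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        mol.RemoveAtom(idx)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def tanimoto_mcs(f1: Fragment, f2: Fragment, timeout: int = MCS_TIMEOUT_S) -> float:
    """MCS Tanimoto similarity over heavy atoms, markers excluded."""
    m1, m2 = _stripped(f1.smiles), _stripped(f2.smiles)
    a1, a2 = m1.GetNumHeavyAtoms(), m2.GetNumHeavyAtoms()
    if a1 == 0 or a2 == 0:
        return 1.0 if a1 == a2 else 0.0
    result = rdFMCS.FindMCS(
        [m1, m2],
        timeout=timeout,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=True,
    )
    if result.canceled:
        logger.warning(
            "MCS search timed out for %s vs %s; using best-so-far bound", f1.smiles, f2.smiles
        )
    mcs = max(0, result.numAtoms)
    return mcs / (a1 + a2 - mcs)


def levenshtein_similarity(f1: Fragment, f2: Fragment) -> float:
    """1 - edit_distance/max(len) on canonical fragment SMILES; 1.0 for two empties."""
    s1, s2 = f1.smiles, f2.smiles
    longest = max(len(s1), len(s2))
    if longest == 0:
        return 1.0
    distance = edlib.align(s1, s2, task="distance")["editDistance"]
    return 1.0 - distance / longest


def pair_similarity(f1: Fragment, f2: Fragment) -> float:
    """The fragment similarity used throughout: max of graph and string views."""
    return max(tanimoto_mcs(f1, f2), levenshtein_similarity(f1, f2))


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise fragment similarity with unit diagonal."""

    values: np.ndarray
    labels: list[str]

    @property
    def n(self) -> int:
        return len(self.labels)


def build_similarity_matrix(
    fragments: list[Fragment],
    cache: dict[tuple[str, str], float] | None = None,
) -> SimilarityMatrix:
    """All-pairs :func:`pair_similarity`; ``cache`` persists pair values across calls."""
    n = len(fragments)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (fragments[i].smiles, fragments[j].smiles)
            if cache is not None and key in cache:
                sim = cache[key]
            else:
                sim = pair_similarity(fragments[i], fragments[j])
                if cache is not None:
                    cache[key] = sim
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix(values=values, labels=[f.smiles for f in fragments])


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@functools.lru_cache(maxsize=16384)
def _fingerprint(smiles: str):
    return _MORGAN.GetFingerprint(Chem.MolFromSmiles(smiles))


def fingerprint_similarity(m1: Molecule, m2: Molecule) -> float:
    """Morgan radius-2, 2048-bit Tanimoto similarity between whole molecules."""
    return DataStructs.TanimotoSimilarity(_fingerprint(m1.smiles), _fingerprint(m2.smiles))
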