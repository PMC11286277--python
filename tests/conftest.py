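import numpy as np
import pytest

from fragevo import (
    Fragment,
    Molecule,
    SimilarityMatrix,
    build_similarity_matrix,
    build_tree,
    decompose_molecule,
    make_fixture_library,
    fixture_fragments,
)
from fragevo.space import MoleculeSpecificSpace


@pytest.fixture(scope="session")
def fixture_library():
    return make_fixture_library(n_scaffolds=8, n_substituents=10, seed=0)


@pytest.fixture(scope="session")
def drug_like_smiles(fixture_library):
    """50 valid, ring-containing molecules for roundtrip checks."""
    return [m.smiles for m in list(fixture_library)[:50]]


@pytest.fixture(scope="session")
def eight_fragments():
    return fixture_fragments(8)


def engineered_matrix(n, structured, base=0.0005):
    """Distinct-similarity matrix: small distinct fill plus structured entries."""
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                values[i, j] = 1.0
            else:
                lo, hi = min(i, j), max(i, j)
                values[i, j] = base * (n * lo + hi + 1)
    for (i, j), v in structured.items():
        values[i, j] = values[j, i] = v
    return values


@pytest.fixture()
def fig3_space():
    """8-fragment space engineered so the lead's fragments sit at the
    leftmost and rightmost leaves (codes [0,0,0] and [1,1,1])."""
    frag_smiles = ["*C", "*O", "*N", "*F", "*Cl", "*CC", "*C(C)C", "*c1ccccc1"]
    frags = [Fragment.from_smiles(s) for s in frag_smiles]
    structured = {
        (0, 1): 0.99, (2, 3): 0.98, (4, 5): 0.97, (6, 7): 0.96,  # Step-1 pairs
        (1, 2): 0.90,  # merge ([0,1],[2,3]); lower index 1 -> left
        (5, 6): 0.89,  # merge ([4,5],[6,7]); lower index 5 -> left
        (3, 4): 0.80,  # final merge; lower index 3 in the first tree -> left
    }
    sim = SimilarityMatrix(
        values=engineered_matrix(8, structured), labels=[f.smiles for f in frags]
    )
    tree = build_tree(frags, sim)
    lead = Molecule.from_smiles("Cc1ccccc1")
    return MoleculeSpecificSpace(
        lead=lead,
        lead_decomposition=decompose_molecule(lead),
        fragments=frags,
        tree=tree,
        source_molecules=[lead],
        size_history=[(0, 8)],
    )


def toy_space(lead_smiles="Cc1ccncc1", n_fragments=16):
    """Deterministic space over fixture fragments, lead fragments included."""
    lead = Molecule.from_smiles(lead_smiles)
    decomp = decompose_molecule(lead)
    frags = list(decomp.fragments)
    seen = {f.smiles for f in frags}
    for frag in fixture_fragments(3 * n_fragments):
        if len(frags) == n_fragments:
            break
        if frag.smiles not in seen:
            seen.add(frag.smiles)
            frags.append(frag)
    tree = build_tree(frags, build_similarity_matrix(frags))
    return MoleculeSpecificSpace(
        lead=lead,
        lead_decomposition=decomp,
        fragments=frags,
        tree=tree,
        source_molecules=[lead],
        size_history=[(0, len(frags))],
    )
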