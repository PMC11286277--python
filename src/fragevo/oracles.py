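"""Property scoring, task success predicates, and the success-rate metric.

All objectives are maximized.  Standard physico-chemical scores are delegated
to RDKit:

* ``QED`` — quantitative estimate of drug-likeness, in [0, 1];
* ``PLogP`` — penalized octanol/water partition coefficient,
  logP − SA_raw − max(0, largest ring size − 6); unbounded;
* ``PLogP_imp`` — PLogP(candidate) − PLogP(lead);
* ``SA`` — synthetic accessibility rescaled to higher-is-better,
  (10 − raw)/9, in [0, 1] (raw score: 1 easy … 10 hard);
* ``SIM`` — Morgan-fingerprint Tanimoto similarity to the lead, in [0, 1].

``DRD2`` and ``GSK3B`` bioactivity scores are *synthetic surrogates*:
deterministic substructure-count heuristics mapped to [0, 1].  They are NOT
trained activity predictors and carry no pharmacological meaning; they exist
so the multi-objective pipeline can be exercised end-to-end, and real
predictors with the same ``(mol, lead) -> float`` signature can be registered
in their place via :func:`register_scorer`.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Callable

from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, QED

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, importable only after path setup)

from .chem import Molecule  # noqa: E402
from .errors import ConfigError  # noqa: E402
from .similarity import fingerprint_similarity  # noqa: E402

__all__ = [
    "ObjectiveVector",
    "TaskDefinition",
    "TASKS",
    "PROPERTY_DOMAIN_MIN",
    "register_scorer",
    "score",
    "is_success",
    "success_rate",
]

ObjectiveVector = dict[str, float]

# domain minima used when decaying sample thresholds are clipped
PROPERTY_DOMAIN_MIN: dict[str, float] = {
    "QED": 0.0,
    "SA": 0.0,
    "DRD2": 0.0,
    "GSK3B": 0.0,
    "SIM": 0.0,
    "PLogP": float("-inf"),
    "PLogP_imp": float("-inf"),
}


def _largest_ring_size(mol: Chem.Mol) -> int:
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def penalized_logp(mol: Chem.Mol) -> float:
    return (
        Crippen.MolLogP(mol)
        - sascorer.calculateScore(mol)
        - max(0, _largest_ring_size(mol) - 6)
    )


_BASIC_N = Chem.MolFromSmarts("[#7;+1,$([NX3;H2,H1,H0;!$(NC=O);!$(N=*);!a])]")
_AROMATIC_N = Chem.MolFromSmarts("[n]")
_HBD = Chem.MolFromSmarts("[NX3H,NX3H2,OX2H]")


def drd2_surrogate(mol: Chem.Mol) -> float:
    """Synthetic DRD2 stand-in: rewards basic amines plus aromatic rings.

    Deterministic substructure counting scaled to [0, 1]; not a predictor.
    """
    n_basic = len(mol.GetSubstructMatches(_BASIC_N))
    n_aromatic_rings = sum(
        1
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring)
    )
    return min(1.0, 0.35 * min(n_basic, 2) + 0.2 * min(n_aromatic_rings, 3))


def gsk3b_surrogate(mol: Chem.Mol) -> float:
    """Synthetic GSK3B stand-in: rewards aromatic nitrogens and H-bond donors.

    Deterministic substructure counting scaled to [0, 1]; not a predictor.
    """
    n_arn = len(mol.GetSubstructMatches(_AROMATIC_N))
    n_hbd = len(mol.GetSubstructMatches(_HBD))
    return min(1.0, 0.25 * min(n_arn, 3) + 0.15 * min(n_hbd, 2))


Scorer = Callable[[Chem.Mol, Chem.Mol], float]

_REGISTRY: dict[str, Scorer] = {
    "QED": lambda mol, lead: QED.qed(mol),
    "PLogP": lambda mol, lead: penalized_logp(mol),
    "PLogP_imp": lambda mol, lead: penalized_logp(mol) - penalized_logp(lead),
    "SA": lambda mol, lead: (10.0 - sascorer.calculateScore(mol)) / 9.0,
    "DRD2": lambda mol, lead: drd2_surrogate(mol),
    "GSK3B": lambda mol, lead: gsk3b_surrogate(mol),
}


def register_scorer(name: str, fn: Scorer, domain_min: float = 0.0) -> None:
    """Register (or replace) a property scorer under ``name``."""
    _REGISTRY[name] = fn
    PROPERTY_DOMAIN_MIN.setdefault(name, domain_min)


def registered_properties() -> list[str]:
    return sorted(_REGISTRY) + ["SIM"]


def score(mol: Molecule, lead: Molecule, properties: list[str]) -> ObjectiveVector:
    """Score ``mol`` on the requested properties (``SIM`` is relative to ``lead``)."""
    rd_mol, rd_lead = mol.to_rdkit(), lead.to_rdkit()
    out: ObjectiveVector = {}
    for prop in properties:
        if prop == "SIM":
            out[prop] = fingerprint_similarity(mol, lead)
        elif prop in _REGISTRY:
            out[prop] = float(_REGISTRY[prop](rd_mol, rd_lead))
        else:
            raise ConfigError(f"no scorer registered for property {prop!r}")
    return out


@dataclass(frozen=True)
class TaskDefinition:
    """A named optimization task: minimum acceptable value per property."""

    name: str
    success: dict[str, float] = field(hash=False)


TASKS: dict[str, TaskDefinition] = {
    "I": TaskDefinition("I", {"QED": 0.85, "PLogP_imp": 3.0, "SIM": 0.3}),
    "II": TaskDefinition("II", {"QED": 0.8, "DRD2": 0.4, "SIM": 0.3}),
    "III": TaskDefinition("III", {"QED": 0.7, "GSK3B": 0.4, "SA": 0.7, "SIM": 0.2}),
}


def is_success(v: ObjectiveVector, task: TaskDefinition) -> bool:
    """True iff every task threshold is met (inclusive >=)."""
    missing = [p for p in task.success if p not in v]
    if missing:
        raise ConfigError(f"objective vector lacks properties required by task: {missing}")
    return all(v[p] >= threshold for p, threshold in task.success.items())


def success_rate(outcomes: list[bool]) -> float:
    """Percentage of leads with at least one successful output molecule."""
    if not outcomes:
        raise ConfigError("success_rate needs at least one lead outcome")
    return 100.0 * sum(bool(o) for o in outcomes) / len(outcomes)
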