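"""Pluggable molecule generators for search-space expansion.

The expansion step needs a source of novel molecules built from the lead and
the sample molecules collected during optimization.  The interface is a
single ``generate(GeneratorRequest) -> list[Molecule]`` method so that any
generative model with that signature can be dropped in; the package ships a
default :class:`RecombinationGenerator` that swaps attachment-compatible
fragments from the samples into the lead's decomposition template —
fragment-level recombination, seeded and fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem import Molecule, decompose_molecule, assemble_fragments
from .errors import ConfigError, ValidityError

logger = logging.getLogger(__name__)

__all__ = ["GeneratorRequest", "RecombinationGenerator", "ExternalGeneratorStub", "get_generator"]


@dataclass(frozen=True)
class GeneratorRequest:
    lead: Molecule
    samples: tuple[Molecule, ...] | list[Molecule]
    n_out: int
    rng_seed: int

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ConfigError("generator request needs at least one sample molecule")
        if self.n_out < 1:
            raise ConfigError("generator request needs n_out >= 1")


class RecombinationGenerator:
    """Swap sample fragments into the lead's template, slot by slot.

    Every output molecule's fragments come from the decompositions of the
    lead or the samples (provenance closure); outputs are valid, canonical,
    and never duplicate an input molecule.
    """

    max_attempt_factor = 25  # attempts per requested output before giving up

    def generate(self, req: GeneratorRequest) -> list[Molecule]:
        rng = np.random.default_rng(req.rng_seed)
        template = decompose_molecule(req.lead)
        pool: dict[int, list] = {}
        seen_frag: set[str] = set()
        for mol in [req.lead, *req.samples]:
            for frag in decompose_molecule(mol).fragments:
                if frag.smiles not in seen_frag:
                    seen_frag.add(frag.smiles)
                    pool.setdefault(frag.n_attachments, []).append(frag)

        forbidden = {req.lead.smiles} | {m.smiles for m in req.samples}
        out: list[Molecule] = []
        out_smiles: set[str] = set()
        for _ in range(self.max_attempt_factor * req.n_out):
            if len(out) >= req.n_out:
                break
            n_swap = int(rng.integers(1, template.r + 1))
            slots = rng.choice(template.r, size=n_swap, replace=False)
            frags = list(template.fragments)
            for slot in slots:
                options = pool.get(frags[slot].n_attachments, [])
                if options:
                    frags[slot] = options[int(rng.integers(0, len(options)))]
            try:
                mol = assemble_fragments(frags, template.topology)
            except ValidityError:
                continue
            if mol.smiles in forbidden or mol.smiles in out_smiles:
                continue
            out_smiles.add(mol.smiles)
            out.append(mol)
        if len(out) < req.n_out:
            logger.info(
                "recombination produced %d of %d requested molecules", len(out), req.n_out
            )
        return out


class ExternalGeneratorStub:
    """Adapter template for a neural encoder-fusion-decoder generator.

    Documents the expected call signature: implement ``generate`` to encode
    the lead and the k samples, fuse their representations, decode candidate
    SMILES, and return them as canonical :class:`Molecule` objects (invalid
    or duplicate outputs filtered, at most ``n_out``).  No model ships with
    this package.
    """

    def generate(self, req: GeneratorRequest) -> list[Molecule]:  # pragma: no cover
        raise NotImplementedError(
            "plug in a trained generator; see RecombinationGenerator for the contract"
        )


_GENERATORS = {"recombine": RecombinationGenerator}


def get_generator(name: str):
    """Resolve a generator by registry name or ``external:<module>:<attr>`` path."""
    if name in _GENERATORS:
        return _GENERATORS[name]()
    if name.startswith("external:"):
        import importlib

        module_path, _, attr = name.removeprefix("external:").rpartition(":")
        if not module_path:
            raise ConfigError(f"external generator must be 'external:<module>:<attr>', got {name!r}")
        return getattr(importlib.import_module(module_path), attr)()
    raise ConfigError(f"unknown generator {name!r}; available: {sorted(_GENERATORS)}")
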