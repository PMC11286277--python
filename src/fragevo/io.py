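"""File I/O and run configuration.

Molecule files are plain text: ``.smi`` (one SMILES per line, optional
whitespace-separated id, ``#`` comments) or ``.csv`` with a ``smiles`` column
(optional ``id`` column).  Invalid entries are skipped, logged, and counted
on the returned library's ``n_skipped``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .chem import Molecule
from .errors import ConfigError, InputError
from .optimizer import TaskConfig
from .space import MoleculeLibrary

logger = logging.getLogger(__name__)

__all__ = ["read_molecules", "write_molecules", "RunConfig", "load_run_config"]


def _iter_records(path: Path, fmt: str):
    if fmt == "csv":
        frame = pd.read_csv(path)
        if "smiles" not in frame.columns:
            raise InputError(f"{path}: CSV needs a 'smiles' column")
        ids = frame["id"] if "id" in frame.columns else [None] * len(frame)
        yield from zip(frame["smiles"].astype(str), ids)
    else:
        with open(path) as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                yield parts[0], (parts[1].strip() if len(parts) > 1 else None)


def read_molecules(path: str | Path, fmt: str | None = None) -> MoleculeLibrary:
    """Read a molecule library; invalid lines are skipped and counted."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "smi")
    lib = MoleculeLibrary(name=path.stem)
    n_skipped = 0
    for smiles, mol_id in _iter_records(path, fmt):
        try:
            lib.add(Molecule.from_smiles(smiles, id=mol_id))
        except InputError:
            n_skipped += 1
            logger.warning("%s: skipping invalid SMILES %r", path, smiles)
    lib.n_skipped = n_skipped
    if len(lib) == 0:
        logger.warning("%s: no valid molecules read", path)
    return lib


def write_molecules(lib: MoleculeLibrary, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "smi")
    if fmt == "csv":
        rows = [{"smiles": m.smiles, "id": m.id, **props} for m, props in zip(lib, lib.properties)]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        with open(path, "w") as handle:
            for mol in lib:
                handle.write(f"{mol.smiles} {mol.id}\n" if mol.id else f"{mol.smiles}\n")


@dataclass
class RunConfig:
    """Fully resolved configuration for one optimization run."""

    lead_path: str
    library_path: str
    output_dir: str
    task: str | None = None  # named task; None -> inline thresholds
    objectives: list[str] = field(default_factory=list)
    success_thresholds: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)
    eta: dict[str, float] = field(default_factory=dict)
    library_thresholds: dict[str, float] = field(default_factory=dict)
    generator: str = "recombine"
    optimizer: dict = field(default_factory=dict)  # M, N, k, itermax0, p, q, E, seed...
    seed: int = 0

    def task_config(self) -> TaskConfig:
        from . import oracles

        if self.task is not None:
            if self.task not in oracles.TASKS:
                raise ConfigError(f"unknown task {self.task!r}; known: {sorted(oracles.TASKS)}")
            thresholds = dict(oracles.TASKS[self.task].success)
        elif self.success_thresholds:
            thresholds = dict(self.success_thresholds)
        else:
            raise ConfigError("config needs either 'task' or inline 'success_thresholds'")
        objectives = self.objectives or [p for p in thresholds]
        opt = dict(self.optimizer)
        if "E" in opt:
            opt["expansion_period"] = opt.pop("E")
        return TaskConfig(
            objectives=objectives,
            success_thresholds=thresholds,
            delta=dict(self.delta),
            eta=dict(self.eta),
            library_thresholds=dict(self.library_thresholds),
            seed=self.seed,
            **opt,
        )

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)


_REQUIRED_KEYS = ("lead_path", "library_path", "output_dir")


def load_run_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Parse and schema-check a YAML run configuration before any computation."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing required config keys: {missing}")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {unknown}")
    cfg = RunConfig(**raw)
    if seed is not None:
        cfg.seed = seed
    cfg.task_config()  # validate eagerly
    return cfg


def write_history(history: list[dict], path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(history, handle, indent=1)
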