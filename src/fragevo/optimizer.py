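"""Multi-objective evolutionary optimization over path-code embeddings.

A lead molecule with m fragments is represented as the concatenation of its
fragments' path codes (m x d bits, d = tree code length).  Offspring are
produced by one of two bit-flip mutation operators:

* *uniform* — every bit flips with the same probability; because front bits
  move a code across large subtrees, this favours exploration;
* *positional* — within each fragment code, bit i (1-based) flips with
  probability p + q*i, biased toward rear bits, i.e. toward leaves nearby in
  the tree; this favours local refinement.

The operator used for each offspring is drawn with cosine-scheduled weights
w_positional = 1 - cos(pi/2 * Iter/Itermax) and w_uniform = cos(pi/2 *
Iter/Itermax): the search starts fully exploratory and ends fully local.
Survivor selection is elitist non-dominated sorting with crowding-distance
splitting of the last front (all objectives maximized).

Offspring molecules whose every configured property clears the decaying
threshold delta_p - Iter*eta_p become *samples*; every E iterations the
pluggable generator turns the lead plus the k most recent samples into new
molecules whose fragments expand the search space.  If the iteration budget
ends with fewer than k samples, Itermax is extended (by Itermax0/2 at a
time, at most to 4x Itermax0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import oracles
from .chem import Decomposition, Molecule, decompose_molecule
from .errors import ConfigError, DegenerateSpaceError, ValidityError
from .space import MoleculeSpecificSpace, expand_space
from .tree import PathCode, decode_code, encode_fragment
from .chem import assemble_fragments

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeEmbedding",
    "TaskConfig",
    "OptimizerState",
    "OptimizationResult",
    "embed_molecule",
    "decode_embedding",
    "init_population",
    "mutate_uniform",
    "mutate_positional",
    "operator_weights",
    "pareto_fronts",
    "crowding_distance",
    "select_next_population",
    "sample_threshold",
    "run_optimization",
]


@dataclass(frozen=True)
class MoleculeEmbedding:
    """Ordered per-fragment path codes; ``bits`` is their concatenation."""

    codes: tuple[PathCode, ...]

    @property
    def bits(self) -> tuple[int, ...]:
        return tuple(b for code in self.codes for b in code)

    @property
    def m(self) -> int:
        return len(self.codes)

    def with_bits(self, bits) -> "MoleculeEmbedding":
        d = len(self.codes[0])
        it = iter(int(b) for b in bits)
        return MoleculeEmbedding(tuple(tuple(next(it) for _ in range(d)) for _ in self.codes))


@dataclass
class TaskConfig:
    """Objectives, success thresholds, and optimizer hyperparameters.

    ``objectives`` are property names, all maximized; ``SIM`` to the lead is
    always appended if absent, since every task requires structural
    similarity to the lead.  ``delta``/``eta`` drive the decaying sample
    thresholds; objectives missing from ``delta`` fall back to their success
    threshold with zero decay.
    """

    objectives: list[str]
    success_thresholds: dict[str, float]
    delta: dict[str, float] = field(default_factory=dict)
    eta: dict[str, float] = field(default_factory=dict)
    M: int = 20
    N: int = 20
    k: int = 10
    itermax0: int = 50
    p: float = 0.05
    q: float = 0.05
    expansion_period: int = 5
    n_generate: int = 10
    init_flip_frac: float = 0.25
    library_thresholds: dict[str, float] = field(default_factory=dict)
    tracked_properties: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if "SIM" not in self.objectives:
            self.objectives = list(self.objectives) + ["SIM"]
        if self.p < 0 or self.q < 0:
            raise ConfigError("mutation parameters p and q must be >= 0")
        if min(self.M, self.N, self.k, self.itermax0) < 1:
            raise ConfigError("M, N, k and itermax0 must all be >= 1")
        if self.expansion_period < 1:
            raise ConfigError("expansion_period must be >= 1")
        for prop, value in self.delta.items():
            if prop not in self.objectives:
                raise ConfigError(f"delta configured for non-objective property {prop!r}")
            if self.eta.get(prop, 0.0) < 0:
                raise ConfigError(f"eta must be >= 0 for property {prop!r}")

    def validate_against(self, d: int) -> None:
        if self.p + self.q * d > 1.0 + 1e-12:
            raise ConfigError(
                f"positional mutation probability p + q*d = {self.p + self.q * d:.3f} exceeds 1"
            )


def embed_molecule(mol: Molecule, space: MoleculeSpecificSpace) -> MoleculeEmbedding:
    """Concatenate the path codes of ``mol``'s fragments, in decomposition order."""
    decomp = decompose_molecule(mol)
    return MoleculeEmbedding(
        tuple(encode_fragment(space.tree, f) for f in decomp.fragments)
    )


def _resolve_code(space: MoleculeSpecificSpace, code: PathCode, n_attachments: int):
    """Leaf for ``code`` among attachment-compatible leaves, or None.

    The decode walk's natural target is used if compatible; otherwise the
    compatible leaf whose code shares the longest prefix with ``code`` wins
    (ties to the lexicographically smallest code) — the nearest compatible
    leaf along the walk.
    """
    natural = decode_code(space.tree, code)
    if natural.n_attachments == n_attachments:
        return natural
    compatible = [
        (frag, leaf_code)
        for frag, leaf_code in space.tree.leaves
        if frag.n_attachments == n_attachments
    ]
    if not compatible:
        return None

    def prefix_len(a: PathCode, b: PathCode) -> int:
        n = 0
        for x, y in zip(a, b):
            if x != y:
                break
            n += 1
        return n

    return max(compatible, key=lambda fc: (prefix_len(fc[1], code), tuple(-b for b in fc[1])))[0]


@dataclass
class DecodeFailure:
    reason: str
    attempted_smiles: str | None = None


def _decode_with_fragments(
    e: MoleculeEmbedding, space: MoleculeSpecificSpace, template: Decomposition
):
    if e.m != template.r:
        return DecodeFailure(f"embedding has {e.m} slots, template has {template.r}"), None
    chosen = []
    for code, slot_frag in zip(e.codes, template.fragments):
        frag = _resolve_code(space, code, slot_frag.n_attachments)
        chosen.append(slot_frag if frag is None else frag)
    try:
        return assemble_fragments(chosen, template.topology), chosen
    except ValidityError as exc:
        return DecodeFailure(str(exc), exc.attempted_smiles), chosen


def decode_embedding(
    e: MoleculeEmbedding, space: MoleculeSpecificSpace, template: Decomposition
) -> Molecule | DecodeFailure:
    """Realize an embedding as a molecule on the lead's attachment topology.

    Each slot's code picks a fragment with the same number of attachment
    points as the template slot (falling back to the template's own fragment
    when no compatible leaf exists); fragments are joined via the template
    topology.  Chemically invalid assemblies are returned as
    :class:`DecodeFailure` values, never raised.
    """
    result, _ = _decode_with_fragments(e, space, template)
    return result


@dataclass
class Individual:
    embedding: MoleculeEmbedding
    molecule: Molecule | None
    objectives: oracles.ObjectiveVector
    failure: str | None = None
    fragments: list | None = None  # per-slot fragments realized at decode time


@dataclass
class OptimizerState:
    population: list[Individual]
    iteration: int
    itermax: int
    samples: list[Individual]
    rng: np.random.Generator


def _score_embedding(
    e: MoleculeEmbedding,
    space: MoleculeSpecificSpace,
    cfg: TaskConfig,
) -> Individual:
    decoded, chosen = _decode_with_fragments(e, space, space.lead_decomposition)
    if isinstance(decoded, DecodeFailure):
        # recorded failure: dominated by every scored individual, never scored
        worst = {p: float("-inf") for p in cfg.objectives}
        return Individual(e, None, worst, failure=decoded.reason, fragments=chosen)
    return Individual(
        e,
        decoded,
        oracles.score(decoded, space.lead, cfg.objectives),
        fragments=chosen,
    )


def init_population(
    lead: Molecule, space: MoleculeSpecificSpace, cfg: TaskConfig, rng: np.random.Generator
) -> OptimizerState:
    """2M distinct random perturbations of the lead embedding, selected down to M."""
    lead_emb = embed_molecule(lead, space)
    d = space.tree.depth_code
    cfg.validate_against(d)
    length = lead_emb.m * d
    max_flips = max(1, int(cfg.init_flip_frac * length))
    capacity = sum(math.comb(length, k) for k in range(1, max_flips + 1))
    if capacity < 2 * cfg.M:
        raise DegenerateSpaceError(
            f"only {capacity} distinct perturbations of a {length}-bit embedding "
            f"exist within {max_flips} flips; cannot draw {2 * cfg.M}"
        )
    seen: set[tuple[int, ...]] = set()
    candidates: list[MoleculeEmbedding] = []
    attempts = 0
    while len(candidates) < 2 * cfg.M:
        attempts += 1
        if attempts > 2000 * cfg.M:
            raise DegenerateSpaceError("could not draw enough distinct initial embeddings")
        n_flips = int(rng.integers(1, max_flips + 1))
        positions = rng.choice(length, size=n_flips, replace=False)
        bits = list(lead_emb.bits)
        for pos in positions:
            bits[pos] ^= 1
        key = tuple(bits)
        if key in seen or key == lead_emb.bits:
            continue
        seen.add(key)
        candidates.append(lead_emb.with_bits(bits))
    scored = [_score_embedding(e, space, cfg) for e in candidates]
    population = select_next_population(scored, cfg.M)
    return OptimizerState(
        population=population, iteration=0, itermax=cfg.itermax0, samples=[], rng=rng
    )


def mutate_uniform(
    e: MoleculeEmbedding, prob: float, rng: np.random.Generator
) -> MoleculeEmbedding:
    """Flip every bit independently with probability ``prob``."""
    if not 0.0 <= prob <= 1.0:
        raise ConfigError(f"mutation probability {prob} outside [0, 1]")
    bits = [b ^ int(rng.random() < prob) for b in e.bits]
    return e.with_bits(bits)


def mutate_positional(
    e: MoleculeEmbedding, p: float, q: float, rng: np.random.Generator
) -> MoleculeEmbedding:
    """Flip bit i (1-based, per fragment code) with probability p + q*i."""
    d = len(e.codes[0])
    if p < 0 or q < 0 or p + q * d > 1.0 + 1e-12:
        raise ConfigError(f"positional probabilities p+q*i outside [0, 1] for d={d}")
    codes = []
    for code in e.codes:
        codes.append(
            tuple(
                b ^ int(rng.random() < min(1.0, p + q * (i + 1)))
                for i, b in enumerate(code)
            )
        )
    return MoleculeEmbedding(tuple(codes))


def operator_weights(iteration: int, itermax: int) -> tuple[float, float]:
    """(w_positional, w_uniform) = (1 - cos(pi/2 * Iter/Itermax), cos(...))."""
    if itermax < 1 or not 0 <= iteration <= itermax:
        raise ConfigError("need 0 <= Iter <= Itermax and Itermax >= 1")
    c = math.cos(math.pi / 2 * iteration / itermax)
    return 1.0 - c, c


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a >= b) and np.any(a > b))


def pareto_fronts(vectors: list) -> list[list[int]]:
    """Non-dominated sorting (all objectives maximized); fronts of input indices."""
    arr = np.asarray(vectors, dtype=float)
    n = len(arr)
    dominated_by: list[list[int]] = [[] for _ in range(n)]  # i dominates these
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(arr[i], arr[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif _dominates(arr[j], arr[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominating[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = sorted(nxt)
    return fronts


def crowding_distance(front: list) -> list[float]:
    """Range-normalized neighbour-gap sum per point; boundaries are infinite."""
    arr = np.asarray(front, dtype=float)
    n = len(arr)
    if n == 0:
        raise ConfigError("crowding_distance needs a nonempty front")
    if n <= 2:
        return [float("inf")] * n
    dist = np.zeros(n)
    for obj in range(arr.shape[1]):
        order = np.argsort(arr[:, obj], kind="stable")
        lo, hi = arr[order[0], obj], arr[order[-1], obj]
        dist[order[0]] = dist[order[-1]] = float("inf")
        span = hi - lo
        if span <= 0:
            continue
        for pos in range(1, n - 1):
            gap = arr[order[pos + 1], obj] - arr[order[pos - 1], obj]
            dist[order[pos]] += gap / span
    return dist.tolist()


def select_next_population(pool: list[Individual], m: int) -> list[Individual]:
    """Elitist survivor selection: fill by front, split the last by crowding."""
    if len(pool) < m:
        raise ConfigError(f"selection pool of {len(pool)} cannot fill population of {m}")
    obj_names = sorted(pool[0].objectives)
    vectors = [[ind.objectives[p] for p in obj_names] for ind in pool]
    survivors: list[Individual] = []
    for front in pareto_fronts(vectors):
        if len(survivors) + len(front) <= m:
            survivors.extend(pool[i] for i in front)
        else:
            dist = crowding_distance([vectors[i] for i in front])
            ranked = sorted(range(len(front)), key=lambda r: (-dist[r], front[r]))
            survivors.extend(pool[front[r]] for r in ranked[: m - len(survivors)])
        if len(survivors) == m:
            break
    return survivors


def sample_threshold(prop: str, iteration: int, cfg: TaskConfig) -> float:
    """Decaying sample-collection threshold delta_p - Iter*eta_p, domain-clipped."""
    if prop in cfg.delta:
        delta = cfg.delta[prop]
    elif prop in cfg.success_thresholds:
        delta = cfg.success_thresholds[prop]
    else:
        raise ConfigError(f"no sample threshold (delta) configured for property {prop!r}")
    eta = cfg.eta.get(prop, 0.0)
    value = delta - iteration * eta
    return max(value, oracles.PROPERTY_DOMAIN_MIN.get(prop, float("-inf")))


def _ranks(population: list[Individual]) -> list[tuple[int, float]]:
    obj_names = sorted(population[0].objectives)
    vectors = [[ind.objectives[p] for p in obj_names] for ind in population]
    rank = [0] * len(population)
    crowd = [0.0] * len(population)
    for fi, front in enumerate(pareto_fronts(vectors)):
        dist = crowding_distance([vectors[i] for i in front])
        for r, i in enumerate(front):
            rank[i] = fi
            crowd[i] = dist[r]
    return list(zip(rank, crowd))


def _tournament(population, ranks, rng) -> Individual:
    i, j = rng.integers(0, len(population), size=2)
    ri, rj = ranks[i], ranks[j]
    better_i = (ri[0], -ri[1]) <= (rj[0], -rj[1])
    return population[i if better_i else j]


@dataclass
class OptimizationResult:
    final_population: list[Individual]
    samples: list[Individual]
    history: list[dict]
    space: MoleculeSpecificSpace
    success: bool
    itermax_final: int

    def successful_molecules(self, task: oracles.TaskDefinition) -> list[Individual]:
        return [
            ind
            for ind in self.final_population + self.samples
            if ind.molecule is not None and oracles.is_success(ind.objectives, task)
        ]


def run_optimization(
    lead: Molecule,
    space: MoleculeSpecificSpace,
    cfg: TaskConfig,
    generator=None,
) -> OptimizationResult:
    """Full optimization loop for one lead on a prebuilt search space.

    Per iteration: operator weights -> M offspring by tournament + mutation
    -> decode and score -> elitist selection back to M -> sample collection
    -> (every E iterations) generator-driven space expansion with tree
    rebuild and population re-embedding.  Itermax extends until at least k
    samples exist or the 4x cap is reached.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_population(lead, space, cfg, rng)
    sample_smiles: set[str] = set()
    history: list[dict] = []
    task = oracles.TaskDefinition("run", cfg.success_thresholds)
    best_so_far = float("-inf")

    def scalar(ind: Individual) -> float:
        return sum(v for v in ind.objectives.values() if math.isfinite(v))

    while state.iteration < state.itermax:
        state.iteration += 1
        w_pos, _w_uni = operator_weights(state.iteration, state.itermax)
        ranks = _ranks(state.population)
        offspring: list[Individual] = []
        for _ in range(cfg.M):
            parent = _tournament(state.population, ranks, rng)
            if rng.random() < w_pos:
                child = mutate_positional(parent.embedding, cfg.p, cfg.q, rng)
            else:
                child = mutate_uniform(parent.embedding, cfg.p, rng)
            offspring.append(_score_embedding(child, space, cfg))

        state.population = select_next_population(state.population + offspring, cfg.M)

        for ind in offspring:
            if ind.molecule is None or ind.molecule.smiles in sample_smiles:
                continue
            if all(
                ind.objectives[p] >= sample_threshold(p, state.iteration, cfg)
                for p in cfg.objectives
                if p in cfg.delta or p in cfg.success_thresholds
            ):
                sample_smiles.add(ind.molecule.smiles)
                state.samples.append(ind)

        if generator is not None and state.iteration % cfg.expansion_period == 0 and state.samples:
            from .generation import GeneratorRequest  # local import to avoid a cycle

            recent = [s.molecule for s in state.samples[-cfg.k :]]
            new_mols = generator.generate(
                GeneratorRequest(
                    lead=lead,
                    samples=recent,
                    n_out=cfg.n_generate,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            before = space.n_fragments
            expand_space(space, new_mols, state.iteration)
            if space.n_fragments != before:
                # the tree changed: re-encode each survivor's realized fragments
                # (all provably in the enlarged space) against the new tree
                state.population = [
                    _score_embedding(
                        MoleculeEmbedding(
                            tuple(encode_fragment(space.tree, f) for f in ind.fragments)
                        ),
                        space,
                        cfg,
                    )
                    if ind.fragments is not None
                    else ind
                    for ind in state.population
                ]

        best_now = max(scalar(ind) for ind in state.population)
        best_so_far = max(best_so_far, best_now)
        history.append(
            {
                "iteration": state.iteration,
                "itermax": state.itermax,
                "w_positional": w_pos,
                "best_scalar": best_now,
                "best_scalar_so_far": best_so_far,
                "n_samples": len(state.samples),
                "space_size": space.n_fragments,
                "n_failures": sum(1 for ind in offspring if ind.failure is not None),
            }
        )

        if (
            state.iteration == state.itermax
            and len(state.samples) < cfg.k
            and state.itermax < 4 * cfg.itermax0
        ):
            step = max(1, cfg.itermax0 // 2)
            state.itermax = min(state.itermax + step, 4 * cfg.itermax0)
            logger.info(
                "only %d/%d samples at Itermax; extending to %d",
                len(state.samples),
                cfg.k,
                state.itermax,
            )

    success = any(
        ind.molecule is not None and oracles.is_success(ind.objectives, task)
        for ind in state.population + state.samples
    )
    return OptimizationResult(
        final_population=state.population,
        samples=state.samples,
        history=history,
        space=space,
        success=success,
        itermax_final=state.itermax,
    )
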