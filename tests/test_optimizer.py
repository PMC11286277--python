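"""Embeddings, mutation operators, Pareto selection, and the optimization loop."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragevo import (
    Molecule,
    MoleculeEmbedding,
    TaskConfig,
    crowding_distance,
    decode_embedding,
    embed_molecule,
    init_population,
    mutate_positional,
    mutate_uniform,
    operator_weights,
    pareto_fronts,
    sample_threshold,
    select_next_population,
)
from fragevo.errors import ConfigError
from fragevo.optimizer import Individual, run_optimization
from fragevo.generation import RecombinationGenerator

from conftest import toy_space


def brute_force_fronts(vectors):
    """O(n^2) dominance oracle: peel non-dominated layers."""

    def dominates(a, b):
        return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))

    remaining = list(range(len(vectors)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(vectors[j], vectors[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestEmbedding:
    def test_lead_at_extreme_leaves_concatenates_000_111(self, fig3_space):
        emb = embed_molecule(fig3_space.lead, fig3_space)
        assert emb.bits == (0, 0, 0, 1, 1, 1)
        assert emb.m == 2

    def test_embedding_roundtrips_to_the_lead(self, fig3_space):
        emb = embed_molecule(fig3_space.lead, fig3_space)
        decoded = decode_embedding(emb, fig3_space, fig3_space.lead_decomposition)
        assert decoded.smiles == fig3_space.lead.smiles

    def test_single_fragment_molecule_has_length_d(self):
        space = toy_space("C1CCCCC1", n_fragments=8)
        emb = embed_molecule(space.lead, space)
        assert emb.m == 1
        assert len(emb.bits) == space.tree.depth_code

    def test_alternative_code_changes_exactly_one_slot(self, fig3_space):
        lead_emb = embed_molecule(fig3_space.lead, fig3_space)
        alt = MoleculeEmbedding(((0, 0, 1), lead_emb.codes[1]))  # slot 0 -> sibling leaf
        decoded = decode_embedding(alt, fig3_space, fig3_space.lead_decomposition)
        assert decoded.smiles != fig3_space.lead.smiles
        assert decoded.smiles == "Oc1ccccc1"  # sibling fragment *O on the ring

    def test_incompatible_region_falls_back_to_the_template_fragment(self):
        # space engineered so the lead's two-attachment ring is the ONLY
        # two-attachment leaf: every code for that slot must fall back to it
        from fragevo import build_similarity_matrix, build_tree, decompose_molecule
        from fragevo.fixtures import fixture_fragments
        from fragevo.space import MoleculeSpecificSpace

        lead = Molecule.from_smiles("CC1CCC(N)CC1")
        decomp = decompose_molecule(lead)
        frags = list(decomp.fragments)
        seen = {f.smiles for f in frags}
        for frag in fixture_fragments(40):
            if len(frags) == 12:
                break
            if frag.n_attachments == 1 and frag.smiles not in seen:
                seen.add(frag.smiles)
                frags.append(frag)
        space = MoleculeSpecificSpace(
            lead=lead,
            lead_decomposition=decomp,
            fragments=frags,
            tree=build_tree(frags, build_similarity_matrix(frags)),
            source_molecules=[lead],
            size_history=[(0, len(frags))],
        )
        slot = next(i for i, f in enumerate(decomp.fragments) if f.n_attachments == 2)
        assert sum(1 for f in frags if f.n_attachments == 2) == 1
        emb = embed_molecule(lead, space)
        ring_smiles = decomp.fragments[slot].smiles
        for code in itertools.product((0, 1), repeat=space.tree.depth_code):
            codes = list(emb.codes)
            codes[slot] = code
            decoded = decode_embedding(MoleculeEmbedding(tuple(codes)), space, decomp)
            assert isinstance(decoded, Molecule)  # valid despite incompatible codes
            assert ring_smiles in {
                f.smiles for f in decompose_molecule(decoded).fragments
            }


class TestMutationOperators:
    def _embedding(self, m=10, d=6):
        return MoleculeEmbedding(tuple(tuple([0] * d) for _ in range(m)))

    def test_uniform_prob_zero_is_identity(self):
        e = self._embedding()
        assert mutate_uniform(e, 0.0, np.random.default_rng(0)).bits == e.bits

    def test_uniform_prob_one_is_complement(self):
        e = self._embedding()
        out = mutate_uniform(e, 1.0, np.random.default_rng(0))
        assert out.bits == tuple(1 - b for b in e.bits)

    def test_uniform_flip_count_matches_binomial_mean(self):
        # L=60, prob=0.1: mean 6, sd sqrt(60*0.1*0.9); 10k-trial mean within 3 SE
        e = self._embedding(m=10, d=6)
        rng = np.random.default_rng(42)
        n_trials = 10_000
        flips = [
            sum(a != b for a, b in zip(e.bits, mutate_uniform(e, 0.1, rng).bits))
            for _ in range(n_trials)
        ]
        se = math.sqrt(60 * 0.1 * 0.9 / n_trials)
        assert abs(np.mean(flips) - 6.0) < 3 * se

    def test_positional_with_q_zero_reduces_to_uniform_rate(self):
        e = self._embedding(m=4, d=3)
        rng = np.random.default_rng(1)
        n_trials = 10_000
        total = sum(
            sum(a != b for a, b in zip(e.bits, mutate_positional(e, 0.2, 0.0, rng).bits))
            for _ in range(n_trials)
        )
        rate = total / (n_trials * 12)
        assert abs(rate - 0.2) < 3 * math.sqrt(0.2 * 0.8 / (n_trials * 12))

    def test_positional_zero_parameters_is_identity(self):
        e = self._embedding()
        assert mutate_positional(e, 0.0, 0.0, np.random.default_rng(0)).bits == e.bits

    def test_positional_per_position_rates_match_closed_form(self):
        # p=0.05, q=0.05, d=3: rates (0.10, 0.15, 0.20) per fragment position
        e = self._embedding(m=2, d=3)
        rng = np.random.default_rng(7)
        n_trials = 10_000
        counts = np.zeros(3)
        for _ in range(n_trials):
            out = mutate_positional(e, 0.05, 0.05, rng)
            for code, orig in zip(out.codes, e.codes):
                counts += [a != b for a, b in zip(code, orig)]
        rates = counts / (2 * n_trials)
        for i, expected in enumerate([0.10, 0.15, 0.20]):
            se = math.sqrt(expected * (1 - expected) / (2 * n_trials))
            assert abs(rates[i] - expected) < 3 * se

    def test_positional_probability_overflow_is_a_config_error(self):
        e = self._embedding(m=1, d=6)
        with pytest.raises(ConfigError):
            mutate_positional(e, 0.5, 0.1, np.random.default_rng(0))


class TestOperatorSchedule:
    def test_limits_and_midpoint(self):
        assert operator_weights(0, 50) == pytest.approx((0.0, 1.0))
        assert operator_weights(50, 50) == pytest.approx((1.0, 0.0))
        w1, w2 = operator_weights(25, 50)
        assert (w1, w2) == pytest.approx((1 - math.sqrt(2) / 2, math.sqrt(2) / 2))

    def test_weights_sum_to_one_and_are_monotone(self):
        w1_prev = -1.0
        for it in range(0, 51):
            w1, w2 = operator_weights(it, 50)
            assert w1 + w2 == pytest.approx(1.0)
            assert w1 > w1_prev  # positional weight strictly increasing
            w1_prev = w1


class TestParetoSelection:
    def test_two_point_domination(self):
        assert pareto_fronts([(1, 1), (0, 0)]) == [[0], [1]]

    def test_identical_vectors_share_one_front(self):
        assert pareto_fronts([(1, 2)] * 5) == [[0, 1, 2, 3, 4]]

    @pytest.mark.parametrize("seed", range(10))
    def test_fronts_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vectors = [tuple(rng.integers(0, 6, size=3)) for _ in range(20)]
        assert [sorted(f) for f in pareto_fronts(vectors)] == brute_force_fronts(vectors)

    def test_crowding_small_fronts_are_infinite(self):
        assert crowding_distance([(1, 2)]) == [float("inf")]
        assert crowding_distance([(1, 2), (2, 1)]) == [float("inf")] * 2

    def test_crowding_middle_of_three_collinear_points_is_two(self):
        dist = crowding_distance([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
        assert dist[1] == pytest.approx(2.0)
        assert dist[0] == dist[2] == float("inf")

    def test_crowding_permutation_invariant(self):
        pts = [(0.0, 3.0), (1.0, 2.5), (2.0, 1.0), (3.0, 0.5)]
        base = crowding_distance(pts)
        perm = [2, 0, 3, 1]
        permuted = crowding_distance([pts[i] for i in perm])
        assert permuted == [base[i] for i in perm]

    @staticmethod
    def _individuals(vectors):
        return [
            Individual(
                embedding=MoleculeEmbedding(((0,),)),
                molecule=None,
                objectives={f"o{k}": float(v) for k, v in enumerate(vec)},
            )
            for vec in vectors
        ]

    def test_selection_pool_of_exactly_m_is_identity(self):
        pool = self._individuals([(1, 2), (2, 1), (0, 0)])
        assert select_next_population(pool, 3) == pool

    def test_nondominated_points_survive_dominated_ones(self):
        vectors = [(3, 3), (1, 4), (4, 1), (0, 0), (1, 1), (2, 2)]
        pool = self._individuals(vectors)
        survivors = select_next_population(pool, 3)
        assert {tuple(int(v) for v in s.objectives.values()) for s in survivors} == {
            (3, 3),
            (1, 4),
            (4, 1),
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_selection_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        vectors = [tuple(rng.uniform(0, 1, size=2).round(3)) for _ in range(12)]
        pool = self._individuals(vectors)
        m = 6
        survivors = select_next_population(pool, m)
        # oracle: brute-force fronts, then crowding-descending fill
        chosen = []
        for front in brute_force_fronts(vectors):
            if len(chosen) + len(front) <= m:
                chosen.extend(front)
            else:
                dist = crowding_distance([vectors[i] for i in front])
                order = sorted(range(len(front)), key=lambda r: (-dist[r], front[r]))
                chosen.extend(front[r] for r in order[: m - len(chosen)])
                break
        assert [pool.index(s) for s in survivors] == chosen


class TestParetoProperties:
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5), st.integers(0, 5)),
            min_size=1,
            max_size=15,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_fronts_partition_the_input_and_match_the_oracle(self, vectors):
        fronts = pareto_fronts(vectors)
        flat = sorted(i for front in fronts for i in front)
        assert flat == list(range(len(vectors)))  # every index in exactly one front
        assert [sorted(f) for f in fronts] == brute_force_fronts(vectors)


class TestSampleThreshold:
    def _cfg(self, **kw):
        return TaskConfig(
            objectives=["QED", "SIM"],
            success_thresholds={"QED": 0.8, "SIM": 0.3},
            **kw,
        )

    def test_iteration_zero_gives_delta(self):
        cfg = self._cfg(delta={"QED": 0.85}, eta={"QED": 0.001})
        assert sample_threshold("QED", 0, cfg) == 0.85

    def test_linear_decay(self):
        cfg = self._cfg(delta={"QED": 0.85}, eta={"QED": 0.001})
        assert sample_threshold("QED", 30, cfg) == pytest.approx(0.82)

    def test_non_increasing_in_iteration_and_domain_clipped(self):
        cfg = self._cfg(delta={"QED": 0.1}, eta={"QED": 0.01})
        values = [sample_threshold("QED", it, cfg) for it in range(0, 30)]
        assert values == sorted(values, reverse=True)
        assert values[-1] == 0.0  # clipped at the QED domain minimum

    def test_unconfigured_property_is_a_config_error(self):
        with pytest.raises(ConfigError):
            sample_threshold("DRD2", 0, self._cfg())


class TestInitPopulation:
    def test_population_size_and_distinct_perturbations(self):
        space = toy_space()
        cfg = TaskConfig(
            objectives=["QED"], success_thresholds={"QED": 0.5}, M=8, seed=0
        )
        rng = np.random.default_rng(0)
        state = init_population(space.lead, space, cfg, rng)
        assert len(state.population) == 8
        lead_bits = embed_molecule(space.lead, space).bits
        assert all(ind.embedding.bits != lead_bits for ind in state.population)

    def test_fixed_seed_reproduces_population(self):
        space = toy_space()
        cfg = TaskConfig(objectives=["QED"], success_thresholds={"QED": 0.5}, M=6)
        a = init_population(space.lead, space, cfg, np.random.default_rng(5))
        b = init_population(space.lead, space, cfg, np.random.default_rng(5))
        assert [i.embedding.bits for i in a.population] == [
            i.embedding.bits for i in b.population
        ]

    def test_degenerate_space_is_an_error(self):
        from fragevo.errors import DegenerateSpaceError

        space = toy_space("Cc1ccccc1", n_fragments=2)  # 2 bits total
        cfg = TaskConfig(objectives=["QED"], success_thresholds={"QED": 0.5}, M=20)
        with pytest.raises(DegenerateSpaceError):
            init_population(space.lead, space, cfg, np.random.default_rng(0))


class TestRunOptimization:
    def _cfg(self, **kw):
        defaults = dict(
            objectives=["QED", "SIM"],
            success_thresholds={"QED": 0.55, "SIM": 0.3},
            delta={"QED": 0.5, "SIM": 0.4},
            eta={"QED": 0.002, "SIM": 0.002},
            M=10,
            k=5,
            itermax0=10,
            seed=11,
        )
        defaults.update(kw)
        return TaskConfig(**defaults)

    def test_fixed_seed_gives_identical_final_smiles(self):
        runs = []
        for _ in range(2):
            res = run_optimization(
                toy_space().lead, toy_space(), self._cfg(), RecombinationGenerator()
            )
            runs.append(
                sorted(i.molecule.smiles for i in res.final_population if i.molecule)
            )
        assert runs[0] == runs[1]

    def test_best_so_far_scalar_objective_never_regresses(self):
        res = run_optimization(toy_space().lead, toy_space(), self._cfg())
        best = [h["best_scalar_so_far"] for h in res.history]
        assert best == sorted(best)

    def test_population_size_invariant_after_every_selection(self):
        res = run_optimization(toy_space().lead, toy_space(), self._cfg())
        assert len(res.final_population) == 10

    def test_samples_satisfy_their_collection_time_thresholds(self):
        cfg = self._cfg()
        res = run_optimization(toy_space().lead, toy_space(), cfg)
        # post-hoc: every sample meets even the tightest (iteration-1) threshold
        # minus the total possible decay over the run
        for ind in res.samples:
            for prop in ("QED", "SIM"):
                floor = cfg.delta[prop] - cfg.eta[prop] * res.itermax_final
                assert ind.objectives[prop] >= floor

    def test_itermax_extends_when_samples_are_scarce(self):
        cfg = self._cfg(
            delta={"QED": 0.99, "SIM": 0.99}, eta={"QED": 0.0, "SIM": 0.0}, itermax0=4
        )
        res = run_optimization(toy_space().lead, toy_space(), cfg)
        assert len(res.samples) < cfg.k
        assert res.itermax_final == 4 * cfg.itermax0  # extended to the cap

    def test_space_history_non_decreasing_with_expansion(self):
        res = run_optimization(
            toy_space().lead, toy_space(), self._cfg(), RecombinationGenerator()
        )
        sizes = [s for _, s in res.space.size_history]
        assert sizes == sorted(sizes)
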