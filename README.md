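# fragevo

Fragment-based multi-objective lead optimization with adaptive,
molecule-specific search spaces.

## The problem

In lead optimization a medicinal chemist wants analogues of a *lead*
molecule with better properties — drug-likeness (QED), penalized logP,
synthetic accessibility, predicted bioactivity — while staying structurally
similar to the lead. Enumerating the whole of chemical space is hopeless;
fragment-based searches are tractable but usually draw replacements from one
big, fixed fragment library, much of which is irrelevant to any particular
lead.

`fragevo` builds a *private* fragment library per lead and grows it as the
search learns:

1. **Molecule-specific search space.** Reference molecules that clear the
   task's property thresholds are ranked by fingerprint Tanimoto similarity
   to the lead; the top *N* are decomposed by cutting every acyclic single
   bond incident to a ring atom (cut sites become attachment markers `*`).
   The pooled fragments form the lead's search space.
2. **Similarity-tree embedding.** Fragments are arranged in a binary tree by
   greedy most-similar pairing under
   `A_sim(i,j) = max(Tanimoto_MCS(f_i, f_j), Lev(f_i, f_j))` —
   the maximum of the maximum-common-substructure Tanimoto similarity and
   the normalized Levenshtein similarity of the fragment SMILES. Each leaf's
   root-to-leaf path (left = 0, right = 1, padded to `d = ⌈log₂ n⌉` bits) is
   the fragment's code; a molecule with *m* fragments is the concatenation
   of its fragments' codes (`m·d` bits). Hamming-near codes are chemically
   similar fragments, so bit flips are structure-aware moves.
3. **Evolutionary optimization.** A population of *M* embeddings evolves
   under two mutation operators — uniform (every bit flips with probability
   *p*) and positional (bit *i* of each fragment code flips with probability
   *p + q·i*, biased to rear bits, i.e. nearby leaves) — mixed with
   cosine-scheduled weights `1 − cos(π/2·Iter/Itermax)` and
   `cos(π/2·Iter/Itermax)`: global early, local late. Survivors are chosen
   by non-dominated sorting with crowding distance (all objectives
   maximized; similarity to the lead, SIM, is always one of them).
4. **Adaptive expansion.** Offspring clearing the decaying thresholds
   `δ_p − Iter·η_p` become *samples*; a pluggable generator (default:
   seeded fragment recombination of lead + samples) proposes new molecules
   whose fragments are unioned into the space, and the tree is rebuilt.
   If fewer than *k* samples exist at Itermax, the budget extends.

## Worked example

```python
import fragevo as fv
from fragevo.optimizer import run_optimization

library = fv.make_fixture_library(n_scaffolds=8, n_substituents=10, seed=0)
lead = fv.Molecule.from_smiles("Cc1ccncc1")

s = fv.build_intermediate_library(library, {"QED": 0.4})
space = fv.build_space(lead, s, n=15)

cfg = fv.TaskConfig(
    objectives=["QED", "SIM"],
    success_thresholds={"QED": 0.6, "SIM": 0.3},
    delta={"QED": 0.55, "SIM": 0.4}, eta={"QED": 0.002, "SIM": 0.002},
    M=10, k=5, itermax0=20, seed=1,
)
result = run_optimization(lead, space, cfg, fv.get_generator("recombine"))
```

Output:

```
library: 160 molecules, filtered to 158
search space: 16 fragments, code length 4, lead slots m=2
success: True, samples collected: 6
space grew +62.5% (16 -> 26 fragments)
Pareto front (unique molecules):
  c1cc(-c2ccncc2)ccn1       QED=0.632 SIM=0.500
  Cc1ccncc1                 QED=0.472 SIM=1.000
```

The 4-methylpyridine lead lives in a 16-fragment space (two slots of four
bits each). The optimizer finds 4,4'-bipyridine — the methyl slot replaced
by a second pyridine ring — raising QED from 0.472 to 0.632 while keeping
SIM = 0.5 to the lead; it passes both success thresholds, so the lead counts
as successfully optimized. Six offspring cleared the decaying sample
thresholds, and recombining them with the lead grew the fragment library
from 16 to 26 fragments (+62.5%).

The same run is available from the shell:

```bash
fragevo fixtures --n-scaffolds 8 --n-substituents 10 --out library.smi
fragevo optimize --config run.yaml --seed 1
fragevo evaluate --results out/ --task I
```

`fragevo optimize` writes `final_molecules.csv`, `samples.csv`, per-lead
JSON histories, a summary with the success rate (SR, the percentage of
leads with at least one output meeting every task threshold), and the fully
resolved config for auditability.

## Layout

| module | contents |
| --- | --- |
| `fragevo.chem` | decomposition/assembly, `Molecule`/`Fragment`/`Decomposition` |
| `fragevo.similarity` | MCS-Tanimoto, Levenshtein, pair similarity, fingerprints |
| `fragevo.tree` | similarity-tree construction, path codes, Newick-like I/O |
| `fragevo.space` | library filtering, top-N selection, space build/expansion |
| `fragevo.optimizer` | embeddings, mutation, Pareto + crowding, the main loop |
| `fragevo.oracles` | QED/PLogP/SA scorers, surrogate bioactivity, task predicates |
| `fragevo.generation` | pluggable generators, default fragment recombination |
| `fragevo.fixtures`, `fragevo.io`, `fragevo.cli` | synthetic libraries, files, CLI |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
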