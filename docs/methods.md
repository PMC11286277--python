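# Methods

This note documents the models and procedures implemented in `fragevo`, the
choices made where the design was genuinely open, and what the synthetic
test conditions do and do not demonstrate.

## Decomposition rule

A molecule is fragmented by cutting every *acyclic single bond incident to a
ring atom*: ring-to-substituent bonds, and single bonds joining two ring
systems. Bonds inside rings are never cut (that would open the ring), and
exocyclic double bonds (e.g. the C=O of a cyclic ketone) are left intact
because only single bonds are eligible. A molecule without ring atoms has
nothing to cut and decomposes to itself — a single fragment with zero
attachment points. Each cut leaves a dummy-atom marker (`*`) on both sides.

Attachment *slots* are numbered by the order dummy atoms appear in the
fragment's canonical SMILES; since re-parsing a canonical SMILES yields
atoms in string order, slot numbering survives serialization without
explicit marker labels. The `Decomposition.topology` records which slot was
joined to which, so reassembling an unmodified decomposition reproduces the
source molecule exactly (round-trip identity is asserted over the fixture
set in the test suite), and substituting any attachment-compatible fragment
into a slot yields a valid analogue or a reported failure.

Stereochemistry is preserved where RDKit can carry it through
fragmentation; fragments that lose stereo on cutting are accepted.

## Fragment similarity

Two complementary views are combined as `A_sim = max(Tan, Lev)`:

* **MCS Tanimoto** `|MCS| / (|f1| + |f2| − |MCS|)` over heavy atoms.
  Attachment markers are stripped before matching. The MCS search requires
  element and bond-order matches and ring-bond-to-ring-bond pairing, with a
  1 s per-pair timeout; on timeout the best-so-far bound is used and a
  warning logged. An empty MCS gives similarity 0.
* **Levenshtein similarity** `1 − d/max(len)` on the canonical fragment
  SMILES including markers (1.0 for two empty strings). The raw edit
  distance is a *distance*, so it is normalized into [0, 1] before being
  maxed with a similarity — otherwise the max would compare incommensurable
  quantities. Edit distances come from `edlib`.

Whole molecules are compared by Tanimoto similarity of Morgan
(circular, radius 2, 2048-bit) fingerprints; this is the `SIM` objective.

## Similarity tree and path codes

Construction is bottom-up and greedy:

1. Repeatedly extract the globally most similar unpaired fragment pair;
   each pair becomes a two-leaf subtree (an odd leftover becomes a
   left-only leaf). This produces ⌈n/2⌉ subtrees.
2. In rounds, repeatedly extract the two most similar remaining subtrees
   (tree similarity = maximum cross-tree fragment-pair similarity) and
   merge them under a virtual parent; an odd leftover subtree advances
   unchanged. Each round takes the tree count to its ceiling half; rounds
   repeat until one tree remains.

Merging one pair at a time globally (instead of per round) would let early
merges chain and exceed the ⌈log₂ n⌉ depth bound; the round structure is
what guarantees code length `d = ⌈log₂ n⌉` (d = 1 for a single-fragment
tree by convention).

Determinism: ties in similarity are broken by the smallest index pair; the
lower-index member of a pair goes left; when two subtrees merge, the one
containing the lower-index fragment of the best cross pair goes left.

Path codes are the left=0/right=1 edge labels from root to leaf,
right-padded with 0 to length *d* (leaves above depth *d* exist for non
powers of two). Decoding is total: an early leaf absorbs remaining bits and
a missing child redirects into the existing child, so every *d*-bit string
maps to some fragment.

Two depth conventions coexist deliberately: `depth_code` (= *d*, the code
length, counting edges) and `node_levels` (counting node levels with the
root as level 1, i.e. *d* + 1 for a full tree). An eight-fragment tree has
`depth_code` 3 and `node_levels` 4.

## Molecule embeddings and decoding

A molecule with *m* fragments embeds as the concatenation of its fragments'
codes (*m·d* bits, slots in decomposition order). Decoding maps each slot's
code back to a fragment *restricted to leaves with the slot's attachment
count*: if the walk's natural target is incompatible, the compatible leaf
sharing the longest code prefix wins (ties to the lexicographically
smallest code), and if no compatible leaf exists the slot keeps its
template fragment. Decoded fragments are assembled on the lead's topology;
assembly failures (valence violations) are values, not exceptions, and such
individuals carry a −∞ objective vector so they are dominated by every
scored individual without ever reaching the property oracles.

The fragment count *m* is fixed during evolution; variable-length
embeddings are out of scope.

## Evolutionary loop

* **Initialization** — 2M distinct perturbations of the lead embedding,
  each flipping between 1 and max(1, ⌊0.25·m·d⌋) uniformly chosen bits;
  non-dominated sorting + crowding selects M. If fewer than 2M distinct
  perturbations exist within the flip cap (the capacity is
  Σ_k C(m·d, k)), the space is reported as degenerate rather than looping
  forever.
* **Mutation** — uniform (each bit w.p. *p*) or positional (bit *i* of each
  fragment code w.p. *p + q·i*, 1-based), chosen per offspring with
  weights `w_pos = 1 − cos(π/2·Iter/Itermax)`, `w_uni = cos(·)`. The
  cos-weight starts at 1, so early search favours uniform flips (including
  high-impact front bits) and late search favours the rear-position
  operator for local refinement. Parents are picked by binary tournament on
  (front rank, crowding distance); M offspring per iteration.
* **Selection** — elitist: parents ∪ offspring reduced to M by ascending
  front index, last front split by descending crowding distance
  (range-normalized neighbour-gap sum; boundary points infinite; fronts of
  ≤ 2 points all infinite).
* **Samples** — offspring whose every configured property clears
  `δ_p − Iter·η_p` (clipped below at the property's domain minimum, 0 for
  unit-interval properties) are collected, deduplicated by SMILES.
* **Expansion** — every E iterations (default 5), the generator receives
  the lead and the k most recent samples and its outputs' fragments are
  unioned into the space. The tree is rebuilt from scratch (pairwise
  similarities cached across rebuilds); every surviving individual is then
  re-encoded against the new tree *from the per-slot fragments realized at
  its decode*, which are provably members of the enlarged space — re-deriving
  them by re-decomposition would occasionally differ, because a join landing
  between two non-ring atoms is not re-cut by the decomposition rule.
* **Budget extension** — if the final iteration arrives with fewer than k
  samples, Itermax grows by Itermax0/2 at a time, capped at 4·Itermax0.

Defaults: p = q = 0.05, M = 20, N = 20 (library molecules seeding the
space), k = 10, Itermax0 = 50, E = 5, initial flip fraction 0.25. These are
desk-scale defaults, all exposed in `TaskConfig`. Note the positional
operator's constraint p + q·d ≤ 1 is validated against the tree depth at
initialization; on very deep trees, reduce q.

A single NumPy generator seeded from the config drives every stochastic
draw (initialization, parent choice, operator choice, bit flips, generator
seeds), so runs are bit-reproducible for a fixed seed.

## Property oracles

QED, Crippen logP and the synthetic-accessibility (SA) raw score come from
RDKit (including the SA-score contrib module). Derived scores:

* `PLogP = logP − SA_raw − max(0, largest ring − 6)` — the standard
  penalized-logP convention; `PLogP_imp` is the difference to the lead.
* `SA = (10 − raw)/9` — rescaled to [0, 1], higher is better, so that all
  bounded objectives share the maximization direction.
* `DRD2` and `GSK3B` are **synthetic surrogates**: deterministic
  substructure-count heuristics (basic amines + aromatic rings; aromatic
  nitrogens + H-bond donors) mapped into [0, 1]. They are not trained
  predictors and carry no pharmacological meaning; they keep the
  multi-objective pipeline exercisable end-to-end. Real predictors with the
  `(mol, lead) -> float` signature can replace them via `register_scorer`.

Named tasks ship with inclusive success thresholds: Task I
QED ≥ 0.85 ∧ PLogP_imp ≥ 3 ∧ SIM ≥ 0.3; Task II QED ≥ 0.8 ∧ DRD2 ≥ 0.4 ∧
SIM ≥ 0.3; Task III QED ≥ 0.7 ∧ GSK3B ≥ 0.4 ∧ SA ≥ 0.7 ∧ SIM ≥ 0.2. The
success rate (SR) is the percentage of leads with at least one output
meeting every threshold of its task.

## Synthetic data

`make_fixture_library` enumerates ring scaffolds (benzene, pyridine,
cyclohexane, thiophene, furan, pyrimidine, piperidine, pyrrole) decorated
with 1–2 common substituents (methyl, hydroxyl, amino, halogens, amide,
methoxy, nitrile, …), seeded and deterministic. Every product is valid and
decomposes into at least two fragments.

What this emulates: a small drug-like reference library with recurring,
mutually similar fragments — enough structure for similarity ranking,
tree building and recombination to be meaningful. What it does not emulate:
the size (hundreds vs hundreds of thousands of molecules), scaffold
diversity, property spread and fragment counts (dozens vs thousands) of a
real purchasable-compound collection, nor trained bioactivity landscapes.
Passing tests therefore demonstrate algorithmic correctness and closed-loop
behaviour at desk scale, not benchmark-level optimization performance on
real chemistry. The deliberately small problem sizes (spaces of 8–30
fragments, populations of 6–20, tens of iterations) keep the full suite
fast while still exercising every code path, including expansion-triggered
tree rebuilds. For the same reason the end-to-end recovery test uses a
population of 12: a 16-fragment space gives 8-bit embeddings, which admit
only 36 distinct perturbations within the 25 % initial flip cap, bounding
2M from above.

## Numerical and degenerate-case choices

* Similarities are plain doubles; no tolerance is applied when comparing
  them — ties are broken by index, which also makes permuted inputs give
  permuted (not identical) trees.
* Sample thresholds clip at the property domain minimum; PLogP has no
  lower bound and never clips.
* Crowding distance skips objectives with zero range (they contribute 0).
* Empty intermediate libraries raise with advice to relax thresholds;
  zero initial space size makes growth percentage undefined (error).
* Invalid molecules in input files or expansion batches are skipped,
  logged, and counted, never silently dropped.

## Known limitations

* The neural encoder–fusion–decoder generator is an interface stub; the
  shipped default is fragment recombination, which cannot invent fragments
  absent from lead ∪ samples.
* MCS similarity on large fragments can hit the 1 s timeout, degrading to
  a bound; with thousands of fragments the O(n²) similarity matrix and
  tree rebuilds would need batching/caching strategies beyond the
  per-pair cache implemented here.
* Fixed fragment count m per lead: attachment-point-preserving variable
  fragment counts are not explored.
* Tree rebuilds change code meanings between iterations; individuals are
  re-encoded, but embedding-space distances are not comparable across an
  expansion boundary.
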