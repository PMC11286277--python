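"""Binary fragment similarity trees and path-code embeddings.

The tree is grown bottom-up from a pairwise similarity matrix:

* Step 1 — greedy pairing: repeatedly extract the globally most similar
  unpaired fragment pair; each pair becomes a two-leaf tree under a virtual
  parent (an odd leftover becomes a left-only leaf).  This yields ⌈n/2⌉ trees.
* Step 2 — rounds of tree merging: within a round, repeatedly extract the two
  most similar remaining trees (tree similarity = max similarity over
  cross-tree fragment pairs) and merge them under a new virtual parent; an
  odd leftover tree advances to the next round unchanged.  Each round halves
  (ceiling) the tree count; rounds repeat until one tree remains.

Every left edge is labelled 0, every right edge 1; the root-to-leaf label
sequence, right-padded with 0 to d = ⌈log2 n⌉ bits, is the fragment's path
code.  Fragments paired early share long code prefixes, so Hamming-close
codes tend to be chemically similar fragments.

Ties are broken everywhere by smallest index pair, and the lower-index side
goes left, making construction fully deterministic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .chem import Fragment
from .errors import FragmentLookupError, InputError
from .similarity import SimilarityMatrix

__all__ = [
    "PathCode",
    "TreeNode",
    "FragmentTree",
    "build_tree",
    "encode_fragment",
    "decode_code",
    "code_prefix_similarity_check",
    "to_newick",
    "from_newick",
]

PathCode = tuple[int, ...]


@dataclass
class TreeNode:
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    fragment: Fragment | None = None  # set on leaves only

    @property
    def is_leaf(self) -> bool:
        return self.fragment is not None

    def leaf_fragments(self) -> list[Fragment]:
        if self.is_leaf:
            return [self.fragment]
        out = []
        for child in (self.left, self.right):
            if child is not None:
                out.extend(child.leaf_fragments())
        return out


@dataclass
class FragmentTree:
    root: TreeNode
    n_fragments: int
    depth_code: int  # d = ceil(log2 n); 1 when n == 1
    similarity: SimilarityMatrix | None = None
    _paths: dict[str, PathCode] = field(default_factory=dict, repr=False)

    @property
    def leaves(self) -> list[tuple[Fragment, PathCode]]:
        """(fragment, padded path code) in left-to-right leaf order."""
        out: list[tuple[Fragment, PathCode]] = []

        def walk(node: TreeNode, path: tuple[int, ...]) -> None:
            if node.is_leaf:
                out.append((node.fragment, _pad(path, self.depth_code)))
                return
            if node.left is not None:
                walk(node.left, path + (0,))
            if node.right is not None:
                walk(node.right, path + (1,))

        walk(self.root, ())
        return out

    @property
    def node_levels(self) -> int:
        """Number of node levels, counting the root as level 1."""

        def height(node: TreeNode) -> int:
            if node.is_leaf:
                return 1
            return 1 + max(height(c) for c in (node.left, node.right) if c is not None)

        return height(self.root)

    def fragments(self) -> list[Fragment]:
        return [f for f, _ in self.leaves]


def _pad(path: tuple[int, ...], d: int) -> PathCode:
    return tuple(path) + (0,) * (d - len(path))


def _argmax_pair(sim: np.ndarray, active: list[int]) -> tuple[int, int]:
    """Most similar pair among active indices; ties -> smallest (i, j)."""
    best, best_pair = -1.0, (active[0], active[0])
    for ai, i in enumerate(active):
        for j in active[ai + 1 :]:
            if sim[i, j] > best:
                best, best_pair = sim[i, j], (i, j)
    return best_pair


def build_tree(fragments: list[Fragment], sim: SimilarityMatrix) -> FragmentTree:
    """Construct the similarity tree for ``fragments`` using matrix ``sim``."""
    n = len(fragments)
    if n == 0:
        raise InputError("cannot build a tree from zero fragments")
    if sim.n != n:
        raise InputError(f"similarity matrix is {sim.n}x{sim.n} but there are {n} fragments")

    if n == 1:
        root = TreeNode(fragment=fragments[0])
        return _finalize(root, n, 1, sim)

    values = sim.values
    # Step 1: pair the fragments greedily into ceil(n/2) two-leaf trees.
    active = list(range(n))
    trees: list[tuple[TreeNode, list[int]]] = []  # (subtree, member fragment indices)
    while len(active) >= 2:
        i, j = _argmax_pair(values, active)
        trees.append(
            (
                TreeNode(left=TreeNode(fragment=fragments[i]), right=TreeNode(fragment=fragments[j])),
                [i, j],
            )
        )
        active.remove(i)
        active.remove(j)
    if active:  # odd n: leftover becomes a left-only leaf
        k = active[0]
        trees.append((TreeNode(left=TreeNode(fragment=fragments[k])), [k]))

    # Step 2: rounds of greedy tree merging until a single tree remains.
    while len(trees) > 1:
        remaining = list(range(len(trees)))
        next_round: list[tuple[TreeNode, list[int]]] = []
        while len(remaining) >= 2:
            best, pick = -1.0, (remaining[0], remaining[1])
            best_cross = (n, n)
            for ai, a in enumerate(remaining):
                for b in remaining[ai + 1 :]:
                    s, cross = _tree_similarity(values, trees[a][1], trees[b][1])
                    if s > best:
                        best, pick, best_cross = s, (a, b), cross
            a, b = pick
            # side containing the best cross pair's lower-index fragment goes left
            left, right = (a, b) if best_cross[0] in trees[a][1] else (b, a)
            next_round.append(
                (
                    TreeNode(left=trees[left][0], right=trees[right][0]),
                    trees[left][1] + trees[right][1],
                )
            )
            remaining.remove(a)
            remaining.remove(b)
        if remaining:  # odd count: leftover tree advances unchanged
            next_round.append(trees[remaining[0]])
        trees = next_round

    d = max(1, math.ceil(math.log2(n)))
    return _finalize(trees[0][0], n, d, sim)


def _tree_similarity(
    values: np.ndarray, members_a: list[int], members_b: list[int]
) -> tuple[float, tuple[int, int]]:
    """Max cross-pair similarity and the (sorted) achieving pair, ties -> smallest."""
    best, best_pair = -1.0, (min(members_a + members_b), max(members_a + members_b))
    for i in members_a:
        for j in members_b:
            lo, hi = (i, j) if i < j else (j, i)
            if values[i, j] > best or (values[i, j] == best and (lo, hi) < best_pair):
                best, best_pair = values[i, j], (lo, hi)
    return best, best_pair


def _finalize(root: TreeNode, n: int, d: int, sim: SimilarityMatrix | None) -> FragmentTree:
    tree = FragmentTree(root=root, n_fragments=n, depth_code=d, similarity=sim)
    for frag, code in tree.leaves:
        tree._paths[frag.smiles] = code
    if len(tree._paths) != n:
        raise InputError("duplicate fragments passed to build_tree")
    return tree


def encode_fragment(tree: FragmentTree, fragment: Fragment) -> PathCode:
    """Root-to-leaf path of ``fragment`` (left=0, right=1), 0-padded to depth_code."""
    try:
        return tree._paths[fragment.smiles]
    except KeyError:
        raise FragmentLookupError(f"fragment not in tree: {fragment.smiles}") from None


def decode_code(tree: FragmentTree, code: PathCode) -> Fragment:
    """Walk ``code`` from the root; total — every code reaches some leaf.

    An early leaf absorbs the remaining bits; a missing child (left-only
    nodes from odd pairings) redirects the walk into the existing child.
    """
    node = tree.root
    for bit in code:
        if node.is_leaf:
            break
        child = node.right if bit else node.left
        if child is None:
            child = node.left if bit else node.right
        node = child
    while not node.is_leaf:  # code exhausted above a leaf: descend leftmost
        node = node.left if node.left is not None else node.right
    return node.fragment


def code_prefix_similarity_check(tree: FragmentTree) -> dict[str, bool | None]:
    """Structural audit: was each leaf's Step-1 sibling its best available partner?

    Replays the greedy pairing on the tree's similarity matrix and reports,
    per fragment, whether the partner it was grouped with had the maximum
    similarity among fragments still unpaired at that moment (``None`` for an
    odd leftover).  With greedy global-argmax extraction this holds by
    construction; the function recomputes it independently as a test hook.
    """
    if tree.similarity is None:
        raise InputError("tree was built without a similarity matrix")
    values = tree.similarity.values
    labels = tree.similarity.labels
    active = list(range(len(labels)))
    report: dict[str, bool | None] = {}
    while len(active) >= 2:
        i, j = _argmax_pair(values, active)
        others_i = [k for k in active if k != i]
        others_j = [k for k in active if k != j]
        report[labels[i]] = bool(values[i, j] >= max(values[i, k] for k in others_i))
        report[labels[j]] = bool(values[i, j] >= max(values[j, k] for k in others_j))
        active.remove(i)
        active.remove(j)
    if active:
        report[labels[active[0]]] = None
    return report


# -- Newick-like serialization (leaf labels are quoted fragment SMILES) -------

def to_newick(tree: FragmentTree) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"'{node.fragment.smiles}'"
        children = [render(c) for c in (node.left, node.right) if c is not None]
        return "(" + ",".join(children) + ")"

    return render(tree.root) + ";"


_TOKEN = re.compile(r"\(|\)|,|;|'[^']*'")


def from_newick(text: str) -> FragmentTree:
    """Rebuild tree topology from :func:`to_newick` output (no similarity matrix)."""
    tokens = _TOKEN.findall(text)
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            children = [parse()]
            while tokens[pos] == ",":
                pos += 1
                children.append(parse())
            if tokens[pos] != ")":
                raise InputError("malformed tree text: expected ')'")
            pos += 1
            if len(children) > 2:
                raise InputError("malformed tree text: node with >2 children")
            node = TreeNode(left=children[0])
            if len(children) == 2:
                node.right = children[1]
            return node
        if tok.startswith("'"):
            pos += 1
            return TreeNode(fragment=Fragment.from_smiles(tok[1:-1]))
        raise InputError(f"malformed tree text at token {tok!r}")

    root = parse()
    n = len(root.leaf_fragments())
    return _finalize(root, n, max(1, math.ceil(math.log2(n))), None)
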