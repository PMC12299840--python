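"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by a different route than the package
(explicit dynamic programming, regex scanning, exhaustive enumeration) so
that agreement is meaningful.
"""

from __future__ import annotations

import itertools
import re
from typing import Mapping, Sequence

NEG_INF = float("-inf")


def gotoh_score(
    a: str,
    b: str,
    sub: Mapping[tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global affine-gap alignment score by explicit three-state DP.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps are
    penalized; transitions between gap states re-pay the opening cost.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to '-')
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[(a[i - 1], b[j - 1])]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)  # already set; keep explicit
    return max(M[n][m], X[n][m], Y[n][m])


_SEQUON_RE = re.compile(r"(?=N(.)[ST])")


def regex_sequons(seq: str) -> list[tuple[int, str, bool]]:
    """Overlap-aware regex scan for Asn-X-Ser/Thr motifs."""
    out = []
    for m in _SEQUON_RE.finditer(seq):
        x = m.group(1)
        out.append((m.start(), x, x != "P"))
    return out


# --- trees as nested tuples ------------------------------------------------
# A tree is either a leaf name (str) or a tuple of >= 2 child trees.


def tuple_tree_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    return [leaf for child in tree for leaf in tuple_tree_leaves(child)]


def tuple_tree_to_newick(tree) -> str:
    def fmt(t) -> str:
        if isinstance(t, str):
            return t
        return "(" + ",".join(fmt(c) for c in t) + ")"
    return fmt(tree) + ";"


def brute_force_parsimony(tree, leaf_labels: Mapping[str, str]) -> int:
    """Minimum label changes over all internal-node state assignments.

    Exhaustive: enumerates every assignment of a state to every internal
    node and counts edges whose endpoints differ.  Exponential — only for
    tiny trees.
    """
    states = sorted(set(leaf_labels.values()))

    internal: list[tuple] = []

    def collect(t) -> None:
        if not isinstance(t, str):
            internal.append(t)
            for c in t:
                collect(c)

    collect(tree)
    if not internal:
        return 0

    def node_state(t, assignment: dict) -> str:
        return leaf_labels[t] if isinstance(t, str) else assignment[id(t)]

    best = float("inf")
    for combo in itertools.product(states, repeat=len(internal)):
        assignment = {id(node): s for node, s in zip(internal, combo)}
        changes = 0
        for node in internal:
            for child in node:
                if node_state(node, assignment) != node_state(child, assignment):
                    changes += 1
        best = min(best, changes)
    return int(best)


def random_tuple_tree(rng, leaves: Sequence[str], polytomy_prob: float = 0.3):
    """Random topology over the given leaves, with occasional polytomies."""
    leaves = list(leaves)
    if len(leaves) == 1:
        return leaves[0]
    if len(leaves) >= 3 and rng.random() < polytomy_prob:
        k = 3
    else:
        k = 2
    idx = rng.permutation(len(leaves))
    cuts = sorted(rng.choice(range(1, len(leaves)), size=k - 1, replace=False))
    parts = []
    prev = 0
    shuffled = [leaves[i] for i in idx]
    for c in list(cuts) + [len(leaves)]:
        parts.append(shuffled[prev:c])
        prev = c
    return tuple(random_tuple_tree(rng, p, polytomy_prob) for p in parts)
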