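"""Label-parsimony congruence between a phylogeny and taxonomic classes.

A tree whose two classes are each monophyletic needs a single label change
(one origin per extra class); heavily interleaved classes need many.  The
minimum number of changes (small parsimony, unit cost) is normalized into a
mixing index in [0, 1]: 0 = classes perfectly monophyletic, 1 = maximal
interleaving.  This turns a qualitative "promiscuously grouped" impression
into a number comparable across trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import dendropy

from ghx.seqio import LabelTable

_INF = float("inf")


@dataclass
class LabeledTree:
    """A phylogeny over labeled leaves (classes from a label table)."""

    tree: dendropy.Tree
    leaf_labels: dict[str, str]

    def __post_init__(self) -> None:
        leaves = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(leaves) < 3:
            raise ValueError("tree needs at least 3 leaves")
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValueError(f"duplicate leaf ids: {dupes}")
        missing = sorted(set(leaves) - set(self.leaf_labels))
        if missing:
            raise ValueError(f"leaves absent from label table: {missing}")
        self.leaf_labels = {lf: self.leaf_labels[lf] for lf in leaves}

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.leaf_labels.values()))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.leaf_labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def supports(self) -> list[float]:
        """Support values attached to internal nodes (as internal labels)."""
        vals = []
        for node in self.tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            if node.label is not None:
                try:
                    vals.append(float(node.label))
                except ValueError:
                    pass
        return vals


def read_newick(path_or_string: str | Path, labels: LabelTable | Mapping[str, str]) -> LabeledTree:
    """Parse a Newick tree and attach class labels to its leaves.

    Accepts a path or a literal Newick string.  Internal node labels are
    retained as support values.  Unbalanced parentheses or leaves missing
    from the label table raise ``ValueError``.
    """
    text: str
    p = Path(str(path_or_string))
    if isinstance(path_or_string, Path) or (p.suffix in {".nwk", ".newick", ".tree", ".tre"} and p.exists()):
        text = p.read_text()
    elif isinstance(path_or_string, str) and not path_or_string.lstrip().startswith("("):
        if not p.exists():
            raise FileNotFoundError(path_or_string)
        text = p.read_text()
    else:
        text = str(path_or_string)

    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at character {offset}")
    if depth != 0:
        raise ValueError(f"unbalanced parentheses: {depth} '(' unclosed at end of input")

    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    table = labels.labels if isinstance(labels, LabelTable) else dict(labels)
    return LabeledTree(tree=tree, leaf_labels=table)


def fitch_steps(labeled: LabeledTree) -> int:
    """Minimum number of class changes on the tree (small parsimony).

    Computed by unit-cost dynamic programming over node state costs
    (Sankoff), which equals the Fitch count on binary trees and remains
    exact on polytomies.  The result is invariant to rooting.
    """
    states = labeled.classes
    if len(states) < 2:
        return 0
    index = {s: i for i, s in enumerate(states)}
    k = len(states)

    cost: dict[dendropy.Node, list[float]] = {}
    for node in labeled.tree.postorder_node_iter():
        if node.is_leaf():
            c = [_INF] * k
            c[index[labeled.leaf_labels[node.taxon.label]]] = 0.0
            cost[node] = c
        else:
            c = [0.0] * k
            for child in node.child_nodes():
                cc = cost[child]
                best = min(cc)
                for s in range(k):
                    c[s] += min(cc[s], best + 1.0)
            cost[node] = c
    return int(min(cost[labeled.tree.seed_node]))


def mixing_index(labeled: LabeledTree) -> tuple[int, Optional[float]]:
    """(parsimony steps, normalized mixing index) for a two-class tree.

    The index is ``(steps - 1) / (min(n1, n2) - 1)``: 0 when the classes are
    monophyletic (one change), 1 when the minority class is maximally
    interleaved.  With more than two classes, or a minority class of one,
    only the raw step count is returned (index ``None``).
    """
    steps = fitch_steps(labeled)
    counts = labeled.class_counts()
    if len(counts) != 2:
        return steps, None
    n_min = min(counts.values())
    if n_min <= 1:
        return steps, None
    if steps <= 1:
        return steps, 0.0
    return steps, (steps - 1) / (n_min - 1)


def support_summary(labeled: LabeledTree, threshold: float = 50.0) -> float:
    """Fraction of support-carrying internal nodes with support > threshold."""
    vals = labeled.supports()
    if not vals:
        raise ValueError("tree carries no support values")
    return sum(1 for v in vals if v > threshold) / len(vals)


def tree_report(labeled: LabeledTree, support_threshold: float = 50.0) -> dict:
    """JSON-ready congruence report for one labeled tree."""
    steps, index = mixing_index(labeled)
    report: dict[str, object] = {
        "n_leaves": len(labeled.leaf_labels),
        "class_counts": labeled.class_counts(),
        "parsimony_steps": steps,
        "mixing_index": index,
        "mixing_index_note": (
            "0 = classes monophyletic, 1 = maximal interleaving; "
            "label-parsimony operationalization, not a published statistic"
        ),
    }
    try:
        frac = support_summary(labeled, support_threshold)
        report["support_threshold"] = support_threshold
        report["fraction_support_above_threshold"] = frac
    except ValueError:
        report["fraction_support_above_threshold"] = None
    return report
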