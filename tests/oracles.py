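"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np

from shellstrata.strata import LINEAGE_SPECIFIC, SCATTERED
from shellstrata.tree import SpeciesTree


def clade_oracle(present: set[str], tree: SpeciesTree, focal: str) -> str:
    """Exhaustively test every clade for exclusivity + completeness.

    Independent of the classifier's MRCA walk: scans all node leaf sets for
    one exactly equal to the presence pattern; falls back to SCATTERED.
    """
    if present == {focal}:
        return LINEAGE_SPECIFIC
    for label in tree.node_labels:
        if tree.leaf_set(label) == present:
            return label
    return SCATTERED


def rooted_binary_shapes(n: int) -> list:
    """All rooted binary tree shapes with n leaves, as nested tuples."""
    if n == 1:
        return ["leaf"]
    shapes = []
    seen = set()
    for k in range(1, n // 2 + 1):
        for left in rooted_binary_shapes(k):
            for right in rooted_binary_shapes(n - k):
                key = tuple(sorted((repr(left), repr(right))))
                if key not in seen:
                    seen.add(key)
                    shapes.append((left, right))
    return shapes


def shape_to_newick(shape) -> str:
    """Label leaves L0.. and internal nodes N0.. deterministically."""
    counter = {"leaf": 0, "int": 0}

    def rec(s) -> str:
        if s == "leaf":
            name = f"L{counter['leaf']}"
            counter["leaf"] += 1
            return name
        left, right = s
        a, b = rec(left), rec(right)
        name = f"N{counter['int']}"
        counter["int"] += 1
        return f"({a},{b}){name}"

    return rec(shape) + ";"


def exact_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum test by full enumeration.

    Enumerates every assignment of the pooled ranks to the first group and
    counts rank sums at least as extreme (in |R1 - E[R1]|) as observed.
    Returns (U statistic of the first group, exact two-sided p).
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum()
        total += 1
        if abs(r - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    u = obs - n1 * (n1 + 1) / 2.0
    return u, count / total


def exact_rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    return exact_rank_sum(x, y)[1]
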