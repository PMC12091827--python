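"""Independent reference implementations used only by the tests.

Everything here is deliberately brute force (exhaustive enumeration,
direct rule transcription, subset search) and shares no code with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from barniche.trees import DatedTree, TreeNode

# ------------------------------------------------- 2-state CTMC oracle


def p_stay(rate: float, t: float) -> float:
    return 0.5 + 0.5 * math.exp(-2.0 * rate * t)


def prob_transition(rate: float, t: float, i: int, j: int) -> float:
    return p_stay(rate, t) if i == j else 1.0 - p_stay(rate, t)


def _tip_like(state: str) -> dict[int, float]:
    return {
        "0": {0: 1.0, 1: 0.0},
        "1": {0: 0.0, 1: 1.0},
        "?": {0: 1.0, 1: 1.0},
    }[state]


def enumeration_likelihood(
    tree: DatedTree, tip_states: dict[str, str], rate: float
) -> float:
    """Likelihood by summing over every internal-state assignment."""
    internal = tree.internal_ids()
    tips = {t: _tip_like(tip_states[tree.nodes[t].label]) for t in tree.tips()}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        p = 0.5  # root prior
        for nid in tree.preorder():
            node = tree.nodes[nid]
            if node.parent is None:
                continue
            t = max(node.length, 1e-8)
            parent_state = st[node.parent]
            if node.children:
                p *= prob_transition(rate, t, parent_state, st[nid])
            else:
                p *= sum(
                    prob_transition(rate, t, parent_state, j) * tips[nid][j]
                    for j in (0, 1)
                )
        total += p
    return total


def enumeration_marginals(
    tree: DatedTree, tip_states: dict[str, str], rate: float
) -> dict[int, float]:
    """Marginal P(present) per internal node by exhaustive Bayes.

    Tip ambiguity is handled by enumerating tip states too, weighting by
    the tips' partial likelihoods.
    """
    internal = tree.internal_ids()
    tip_ids = tree.tips()
    tips = {t: _tip_like(tip_states[tree.nodes[t].label]) for t in tip_ids}
    num = {nid: 0.0 for nid in internal}
    den = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal) + len(tip_ids)):
        st = dict(zip(internal + tip_ids, assign))
        p = 0.5
        for tid in tip_ids:
            p *= tips[tid][st[tid]]
        if p == 0.0:
            continue
        for nid in tree.preorder():
            node = tree.nodes[nid]
            if node.parent is None:
                continue
            t = max(node.length, 1e-8)
            p *= prob_transition(rate, t, st[node.parent], st[nid])
        den += p
        for nid in internal:
            if st[nid] == 1:
                num[nid] += p
    return {nid: num[nid] / den for nid in internal}


def all_tree_shapes(n_tips: int) -> list:
    """All distinct rooted binary shapes with exactly n_tips leaves,
    as nested tuples (leaf = None)."""
    if n_tips == 1:
        return [None]
    shapes = []
    for k in range(1, n_tips // 2 + 1):
        lefts = all_tree_shapes(k)
        rights = all_tree_shapes(n_tips - k)
        for i, a in enumerate(lefts):
            for j, b in enumerate(rights):
                if k == n_tips - k and j < i:
                    continue  # unordered pair
                shapes.append((a, b))
    return shapes


def shape_to_tree(shape, rng: np.random.Generator) -> DatedTree:
    """Materialize a shape with random branch lengths (not ultrametric;
    the CTMC machinery only needs lengths)."""
    nodes: list[TreeNode] = []

    def build(s, parent: int | None) -> int:
        nid = len(nodes)
        length = float(rng.uniform(0.1, 2.0)) if parent is not None else 0.0
        nodes.append(TreeNode(nid, parent=parent, length=length))
        if parent is not None:
            nodes[parent].children.append(nid)
        if s is not None:
            build(s[0], nid)
            build(s[1], nid)
        else:
            nodes[nid].label = f"t{nid}"
        return nid

    build(shape, None)
    tree = DatedTree(nodes, 0)
    return tree


# ---------------------------------------------------- BR coding oracle


def code_br_reference(
    occ_values, m_values, edges
) -> list[str]:
    """Direct transcription of the three coding rules.

    Rule 1: every bin holding an occurrence value, or lying between the
    occupied minimum and maximum, is present.  Rule 2: bins inside the
    accessible (M) environmental range but not occupied are absent.
    Rule 3: bins beyond the accessible range (or beyond the occupied
    range when no M exists) are uncertain.
    """
    edges = list(edges)
    n = len(edges) - 1

    def bin_of(v: float) -> int:
        for i in range(n - 1):
            if edges[i] <= v < edges[i + 1]:
                return i
        return n - 1

    a, b = min(occ_values), max(occ_values)
    out = []
    for i in range(n):
        lo, hi = edges[i], edges[i + 1]
        occupied = bin_of(a) <= i <= bin_of(b)
        if occupied:
            out.append("1")
        elif m_values is None:
            out.append("?")
        else:
            ma, mb = min(m_values), max(m_values)
            # positive-length overlap with the accessible range
            if min(hi, mb) - max(lo, ma) > 0:
                out.append("0")
            else:
                out.append("?")
    return out


# ------------------------------------------- change typology oracle


def classify_bins_reference(A, D) -> list[str]:
    out = []
    for a, d in zip(A, D):
        if a == "?" or d == "?":
            out.append("indeterminate")
        elif a == d:
            out.append("stasis")
        elif a == "1" and d == "0":
            out.append("retraction")
        else:
            out.append("expansion")
    return out


# ------------------------------------------------------- MIS oracle


def max_independent_set_size(points, min_dist, dist_fn) -> int:
    """Largest subset with all pairwise distances >= min_dist, by
    exhaustive subset search (n <= ~15)."""
    n = len(points)
    best = 0
    for mask in range(1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        if len(idx) <= best:
            continue
        ok = all(
            dist_fn(points[i], points[j]) >= min_dist
            for i, j in itertools.combinations(idx, 2)
        )
        if ok:
            best = len(idx)
    return best
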