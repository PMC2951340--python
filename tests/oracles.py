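"""Independent reference implementations used only by the tests.

These deliberately avoid scipy/statsmodels and the package's own code
paths: exact big-integer arithmetic, direct textbook formulas and
exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """Exact P(A >= a) with margins fixed, via big-integer binomials."""
    N = a + b + c + d
    K = a + c          # genes with the term
    n = a + b          # genes in the window
    denom = comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), denom)
    return float(total)


def binomial_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k), X ~ Binomial(n, p0), by direct summation."""
    frac = Fraction(p0).limit_denominator(10**12)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * frac**i * (1 - frac) ** (n - i)
    return float(total)


def bh_qvalues(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up: q_i = min_{p_j >= p_i} m*p_j/rank_j, clipped to 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, m * pvals[i] / rank_from_top)
        q[i] = min(1.0, val)
        prev = val
    return q


def ks_D_sweep(x: list[float], y: list[float]) -> float:
    """sup |ECDF_x - ECDF_y| by evaluating both ECDFs at every data point."""
    xs, ys = sorted(x), sorted(y)

    def ecdf(sample, t):
        return sum(v <= t for v in sample) / len(sample)

    return max(abs(ecdf(xs, t) - ecdf(ys, t)) for t in xs + ys)


def pearson_chi2(obs: list[float], exp: list[float]) -> float:
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


def pearson_r(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


# --- exhaustive Dollo oracle ------------------------------------------------
# trees are nested tuples of leaf labels, e.g. ((("a","b"),"c"),"d")


def tree_nodes(tree):
    """All nodes (subtrees) in post-order; leaves are strings."""
    if isinstance(tree, str):
        return [tree]
    out = []
    for child in tree:
        out.extend(tree_nodes(child))
    out.append(tree)
    return out


def tree_leaves(tree):
    return [n for n in tree_nodes(tree) if isinstance(n, str)]


def dollo_min_events(tree, presence: dict[str, int]) -> int:
    """Minimum events over every ancestral-state assignment with one gain.

    A gain is a 0->1 edge, or the root itself being in state 1; a loss is a
    1->0 edge. Exactly one gain is allowed (the character arises once).
    Leaf states are fixed by *presence*; internal states are enumerated.
    """
    internal = [n for n in tree_nodes(tree) if not isinstance(n, str)]
    best = None
    for states in itertools.product([0, 1], repeat=len(internal)):
        assign = dict(zip(map(id, internal), states))

        def state(node):
            return presence[node] if isinstance(node, str) else assign[id(node)]

        gains = 1 if state(tree) == 1 else 0
        losses = 0
        ok = True
        stack = [tree]
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                continue
            for child in node:
                s_p, s_c = state(node), state(child)
                if s_p == 0 and s_c == 1:
                    gains += 1
                elif s_p == 1 and s_c == 0:
                    losses += 1
                stack.append(child)
        if gains != 1:
            ok = False
        if ok:
            events = gains + losses
            if best is None or events < best:
                best = events
    assert best is not None, "no single-gain assignment exists"
    return best


def tuple_tree_to_newick(tree) -> str:
    def fmt(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(fmt(c) for c in node) + ")"

    return fmt(tree) + ";"
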