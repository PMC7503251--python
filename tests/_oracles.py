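"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: a textbook dynamic-programming edit distance and an
exhaustive enumeration of the transportation problem's basic feasible
solutions.  Kept free of any erppi internals.
"""

from __future__ import annotations

import itertools


def levenshtein_dp(a, b) -> int:
    """Classic O(len(a)*len(b)) edit distance over label sequences."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def transport_optimum(supply, demand, cost) -> float:
    """Exact optimal transportation cost by exhaustive enumeration.

    Recursively tries every cell order of the greedy reduction (allocate
    min(remaining supply, remaining demand) to a chosen cell, drop the
    exhausted row/column); every basic feasible solution of the
    transportation polytope arises from some order, so the minimum over
    all orders is the global optimum.  Exponential -- use only for tiny
    instances.
    """
    best = [float("inf")]
    n, m = len(supply), len(demand)

    def rec(s, d, acc):
        if acc >= best[0]:
            return
        rows = [i for i in range(n) if s[i] > 1e-15]
        cols = [j for j in range(m) if d[j] > 1e-15]
        if not rows or not cols:
            best[0] = min(best[0], acc)
            return
        for i, j in itertools.product(rows, cols):
            q = min(s[i], d[j])
            s2, d2 = list(s), list(d)
            s2[i] -= q
            d2[j] -= q
            rec(s2, d2, acc + q * cost[i][j])

    rec(list(supply), list(demand), 0.0)
    return best[0]


def dfg_edges_bruteforce(log) -> dict:
    """Edge frequencies by a literal double loop over effective events."""
    freq: dict = {}
    for case in log.cases:
        eff = case.effective_events()
        for i in range(len(eff)):
            for j in range(len(eff)):
                if j == i + 1:
                    key = (eff[i].activity, eff[j].activity)
                    freq[key] = freq.get(key, 0) + 1
    return freq
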