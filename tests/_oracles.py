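"""Independent brute-force oracles the fast implementations are checked against.

Everything here is deliberately naive — plain loops over definitions — and
shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ks_two_cdf_es(hit_mask: np.ndarray) -> float:
    """Classic two-sample KS deviation between hit and miss rank CDFs.

    Walks positions i = 1..N, tracks F_hit(i) = #hits<=i / N_H and
    F_miss(i) = #miss<=i / N_M, and returns the signed deviation of
    maximum magnitude (ties resolved toward the positive side).
    """
    n = len(hit_mask)
    n_h = int(np.sum(hit_mask))
    n_m = n - n_h
    assert 0 < n_h < n
    best_pos = best_neg = 0.0
    h = m = 0
    for i in range(n):
        if hit_mask[i]:
            h += 1
        else:
            m += 1
        d = h / n_h - m / n_m
        best_pos = max(best_pos, d)
        best_neg = min(best_neg, d)
    # magnitude ties (within round-off) resolve to the positive side
    return best_neg if -best_neg > best_pos + 1e-12 else best_pos


def running_sum_es(scores: np.ndarray, hit_mask: np.ndarray, p: int) -> float:
    """Weighted running-sum ES by direct accumulation (reference loop)."""
    n = len(hit_mask)
    n_h = int(np.sum(hit_mask))
    assert 0 < n_h < n
    w = [abs(scores[i]) ** p if hit_mask[i] else 0.0 for i in range(n)]
    n_r = sum(w)
    if n_r == 0.0:  # all-zero member scores: unweighted fallback
        w = [1.0 if hit_mask[i] else 0.0 for i in range(n)]
        n_r = float(n_h)
    rs = []
    acc = 0.0
    for i in range(n):
        if hit_mask[i]:
            acc += w[i] / n_r
        else:
            acc -= 1.0 / (n - n_h)
        rs.append(acc)
    mx, mn = max(rs), min(rs)
    return mn if -mn > mx + 1e-12 else mx


def exhaustive_null_es(scores: np.ndarray, set_size: int, p: int) -> np.ndarray:
    """ES of every possible gene set of the given size (all C(N, k) subsets)."""
    n = len(scores)
    out = []
    for combo in itertools.combinations(range(n), set_size):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        out.append(running_sum_es(scores, mask, p))
    return np.array(out)


def hypergeom_upper_tail(k: int, a: int, b: int, universe: int) -> float:
    """P(|A & B| >= k) by enumerating every size-b draw from the universe."""
    set_a = set(range(a))
    total = math.comb(universe, b)
    hits = sum(
        1
        for combo in itertools.combinations(range(universe), b)
        if len(set_a.intersection(combo)) >= k
    )
    return hits / total
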