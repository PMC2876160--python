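"""Independent brute-force oracles used by the tests.

These are deliberately naive (exhaustive enumeration, O(n^3) loops, exact
rational arithmetic) and share no code with the implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import permutations
from math import comb

import numpy as np


def brute_resnik(graph, ic, t1: str, t2: str) -> float:
    """Max IC over explicitly enumerated common reflexive ancestors."""

    def ancestors(t):
        out = {t}
        frontier = [t]
        while frontier:
            node = frontier.pop()
            for p, _ in graph.parents.get(node, ()):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    common = ancestors(t1) & ancestors(t2)
    best = 0.0
    for a in common:
        if a in ic.ic:
            best = max(best, ic.ic[a])
    return best


def brute_optimal_assignment(profile1, profile2, sim) -> float:
    """Exhaustive max over all injective maps of the smaller profile."""
    p1, p2 = sorted(profile1), sorted(profile2)
    if len(p1) > len(p2):
        p1, p2 = p2, p1
    best = -np.inf
    for perm in permutations(p2, len(p1)):
        best = max(best, sum(sim(a, b) for a, b in zip(p1, perm)))
    return best / len(p1)


def brute_global_align_score(s1, s2, score, gap_open, gap_extend):
    """Best global alignment score by exhaustive path enumeration.

    Affine gaps cost open + extend * length; gap runs touching either end of
    the alignment are free (end gaps are not penalized).
    """
    import re

    def score_moves(moves: str) -> float:
        total, i, j = 0.0, 0, 0
        for m in moves:
            if m == "M":
                total += score(s1[i], s2[j])
                i += 1
                j += 1
            elif m == "X":
                i += 1
            else:
                j += 1
        for run in re.finditer(r"X+|Y+", moves):
            if run.start() == 0 or run.end() == len(moves):
                continue  # end gaps are free
            total -= gap_open + gap_extend * (run.end() - run.start())
        return total

    best = [-np.inf]

    def recurse(i, j, moves):
        if i == len(s1) and j == len(s2):
            best[0] = max(best[0], score_moves(moves))
            return
        if i < len(s1) and j < len(s2):
            recurse(i + 1, j + 1, moves + "M")
        if i < len(s1):
            recurse(i + 1, j, moves + "X")
        if j < len(s2):
            recurse(i, j + 1, moves + "Y")

    recurse(0, 0, "")
    return best[0]


def naive_ward(dist: np.ndarray):
    """O(n^3) Lance-Williams Ward on squared dissimilarities.

    Returns (merge list [(a, b)], heights list) with scipy-style node
    numbering and heights equal to the Ward merge cost D^2/2; ties broken by
    smallest, then second-smallest cluster index.
    """
    n = dist.shape[0]
    d2 = {(i, j): dist[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    active = {i: 1 for i in range(n)}  # node -> leaf count
    merges, heights = [], []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = (i, j)
                if best is None or d2[key] < best[0] - 1e-15:
                    best = (d2[key], i, j)
        _, a, b = best
        merges.append((a, b))
        heights.append(d2[(a, b)] / 2.0)
        na, nb = active[a], active[b]
        for k in sorted(active):
            if k in (a, b):
                continue
            nk = active[k]
            dak = d2[tuple(sorted((a, k)))]
            dbk = d2[tuple(sorted((b, k)))]
            dab = d2[(a, b)]
            new = ((na + nk) * dak + (nb + nk) * dbk - nk * dab) / (na + nb + nk)
            d2[tuple(sorted((next_id, k)))] = new
        del active[a], active[b]
        active[next_id] = na + nb
        next_id += 1
    return merges, heights


def hypergeom_upper_tail(k_obs: int, m_pop: int, n_succ: int, n_draw: int) -> float:
    """Exact P(X >= k) by rational summation of the hypergeometric pmf."""
    denom = comb(m_pop, n_draw)
    total = Fraction(0)
    for k in range(k_obs, min(n_succ, n_draw) + 1):
        if n_draw - k > m_pop - n_succ:
            continue
        total += Fraction(comb(n_succ, k) * comb(m_pop - n_succ, n_draw - k), denom)
    return float(total)


def studentized_range_sf_quad(q: float, k: int, df: int) -> float:
    """Independent studentized-range tail via scipy's adaptive integration."""
    from scipy.stats import studentized_range

    return float(studentized_range.sf(q, k, df))
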