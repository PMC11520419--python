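"""Cluster–cluster matching: mutual-top-t selection and stable matching.

Given the combined score matrix m (K₁ × K₂, non-negative), the matching
S ∈ {0,1}^{K₁×K₂} is selected under the capacity constraints
Σ_{k₂} s_{k₁k₂} ≤ t and Σ_{k₁} s_{k₁k₂} ≤ t either by the mutual-nearest-
neighbor heuristic (the default) or, for t = 1, by Gale–Shapley deferred
acceptance.  Stability is the bipartite no-blocking-pair condition

    t² s_{k₁k₂} + t Σ_{j ∈ J_{k₁}} s_{k₁j} + Σ_{i ∈ I_{k₂}} s_{ik₂} ≥ t²

for every pair, where J_{k₁} (resp. I_{k₂}) indexes partners strictly
preferred by k₁ (resp. k₂) over the other side of the pair; an explicit
verifier reports violating pairs.

MNN keeps only strictly positive scores; Gale–Shapley deliberately admits
zero-score proposals (every proposer eventually matches while capacity
remains), which can be pruned afterwards with ``min_score``.
"""

from __future__ import annotations

import numpy as np

from .containers import MatchResult, ScoreMatrix


def _top_t(scores: np.ndarray, t: int) -> list:
    """Indices of the t largest entries, ties broken toward lower index."""
    order = sorted(range(scores.size), key=lambda i: (-scores[i], i))
    return order[:t]


def mnn_match(m: np.ndarray, t: int = 1,
              scores: ScoreMatrix | None = None) -> MatchResult:
    """Mutual top-t matching: s=1 iff the score is positive, k₂ is among
    row k₁'s top-t columns and k₁ among column k₂'s top-t rows."""
    m = np.asarray(m, dtype=float)
    if m.size and m.min() < 0:
        raise ValueError("scores must be non-negative")
    if t < 1:
        raise ValueError("capacity t must be ≥ 1")
    k1, k2 = m.shape
    row_top = [set(_top_t(m[i], t)) for i in range(k1)]
    col_top = [set(_top_t(m[:, j], t)) for j in range(k2)]
    s = np.zeros((k1, k2), dtype=np.int8)
    for i in range(k1):
        for j in row_top[i]:
            if m[i, j] > 0 and i in col_top[j]:
                s[i, j] = 1
    return MatchResult(s, t, "mnn", scores)


def gale_shapley(m: np.ndarray,
                 scores: ScoreMatrix | None = None,
                 min_score: float | None = None) -> MatchResult:
    """One-to-one stable matching by deferred acceptance (t = 1).

    Dataset-2 clusters propose down their preference lists (decreasing
    score, ties toward the lower dataset-1 index); dataset-1 clusters hold
    the best proposal so far.  Zero-score proposals are admitted, so every
    proposer on the smaller side ends up matched; pass ``min_score`` to
    drop matches at or below a floor afterwards.
    """
    m = np.asarray(m, dtype=float)
    if m.size and m.min() < 0:
        raise ValueError("scores must be non-negative")
    k1, k2 = m.shape
    pref = [sorted(range(k1), key=lambda i: (-m[i, j], i)) for j in range(k2)]
    next_choice = [0] * k2
    partner_of_1 = [-1] * k1  # holds the proposing k2, or -1
    freelist = list(range(k2 - 1, -1, -1))
    while freelist:
        j = freelist.pop()
        while next_choice[j] < k1:
            i = pref[j][next_choice[j]]
            next_choice[j] += 1
            cur = partner_of_1[i]
            if cur == -1:
                partner_of_1[i] = j
                break
            # strict preference of i, ties toward the lower proposer index
            if (m[i, j], -j) > (m[i, cur], -cur):
                partner_of_1[i] = j
                freelist.append(cur)
                break
    s = np.zeros((k1, k2), dtype=np.int8)
    for i, j in enumerate(partner_of_1):
        if j >= 0 and (min_score is None or m[i, j] > min_score):
            s[i, j] = 1
    return MatchResult(s, 1, "gale_shapley", scores)


def check_stability(
    match: MatchResult, m: np.ndarray, t: int | None = None
) -> tuple[bool, list]:
    """Verify the no-blocking-pair inequality for every cluster pair.

    Returns ``(stable, blocking_pairs)``.  A pair (k₁, k₂) blocks when its
    score is positive and the capacity-weighted inequality fails — i.e.
    neither side is saturated with strictly-preferred partners.  A score of
    0 sits at the clamped noise floor and denotes indifference, so such
    pairs never block (an empty matching on an all-zero score matrix is
    stable, and admitting zero-score matches cannot destabilize).  Capacity
    violations raise instead of reporting instability.
    """
    m = np.asarray(m, dtype=float)
    s = np.asarray(match.s)
    if s.shape != m.shape:
        raise ValueError("matching and score shapes differ")
    t = match.t if t is None else t
    if s.sum(axis=1).max(initial=0) > t or s.sum(axis=0).max(initial=0) > t:
        raise ValueError("capacity constraint violated")
    blocking = []
    for k1 in range(m.shape[0]):
        for k2 in range(m.shape[1]):
            if m[k1, k2] <= 0:
                continue
            better_row = m[k1] > m[k1, k2]      # J_{k1}
            better_col = m[:, k2] > m[k1, k2]   # I_{k2}
            lhs = (t * t * s[k1, k2]
                   + t * int(s[k1, better_row].sum())
                   + int(s[better_col, k2].sum()))
            if lhs < t * t:
                blocking.append((k1, k2))
    return (len(blocking) == 0, blocking)
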