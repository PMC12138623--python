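"""Independent brute-force oracles used by the test suite.

Each oracle enumerates the full space of its problem (alignments, group
assignments, sign flips, peak matchings) and is deliberately written with
different machinery from the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

MATCH, MISMATCH, GAP = 1, -1, -2


def enumerate_alignments(a: str, b: str):
    """Yield every gapped alignment (ga, gb) of two short strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def _terminal_span(ga: str, gb: str) -> tuple[int, int]:
    lo, hi = 0, len(ga)
    while lo < hi and ("-" in (ga[lo], gb[lo])):
        lo += 1
    while hi > lo and ("-" in (ga[hi - 1], gb[hi - 1])):
        hi -= 1
    return lo, hi


def score_alignment(ga: str, gb: str) -> int:
    """NW score with free terminal gaps: +1 match, -1 mismatch, -2 per
    internal gap column."""
    lo, hi = _terminal_span(ga, gb)
    s = 0
    for x, y in zip(ga[lo:hi], gb[lo:hi]):
        if "-" in (x, y):
            s += GAP
        elif x == y:
            s += MATCH
        else:
            s += MISMATCH
    return s


def identity_of(ga: str, gb: str) -> float:
    lo, hi = _terminal_span(ga, gb)
    if hi == lo:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in zip(ga[lo:hi], gb[lo:hi]))
    return matches / (hi - lo)


def optimal_identities(a: str, b: str) -> set[float]:
    """Identities of every maximum-score alignment (brute force)."""
    best = None
    idents: set[float] = set()
    for ga, gb in enumerate_alignments(a, b):
        s = score_alignment(ga, gb)
        if best is None or s > best:
            best, idents = s, {identity_of(ga, gb)}
        elif s == best:
            idents.add(identity_of(ga, gb))
    return idents


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    order = pooled.argsort(kind="stable")
    ranks = np.empty(pooled.size)
    # midranks, computed by hand (no scipy)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean = ranks.sum() * n1 / pooled.size
    dev = abs(w_obs - mean)
    hits = total = 0
    for idx in combinations(range(pooled.size), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= dev - 1e-12:
            hits += 1
    return hits / total


def exact_signed_rank_p(d) -> float:
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    mags = np.abs(d)
    order = mags.argsort(kind="stable")
    ranks = np.empty(d.size)
    sorted_m = mags[order]
    i = 0
    while i < d.size:
        j = i
        while j < d.size and sorted_m[j] == sorted_m[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2
    dev = abs(w_obs - mean)
    hits = 0
    n = d.size
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if abs(w - mean) >= dev - 1e-12:
            hits += 1
    return hits / 2**n


def optimal_assignment_cosine(a, b, params) -> float:
    """Exact (Hungarian) modified-cosine score over the candidate pairs."""
    from gutmetab.network import candidate_pairs

    pairs = candidate_pairs(a, b, params)
    if not pairs:
        return 0.0
    rows = sorted({i for i, _ in pairs})
    cols = sorted({j for _, j in pairs})
    w = np.zeros((len(rows), len(cols)))
    for (i, j), v in pairs.items():
        w[rows.index(i), cols.index(j)] = v
    ri, ci = linear_sum_assignment(-w)
    return float(w[ri, ci].sum())
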