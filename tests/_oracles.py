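"""Independent brute-force oracles used to verify the implementation.

Every function here recomputes a quantity by a route independent of the
package: dynamic programming, exhaustive enumeration, exact rational
arithmetic, or position-by-position scanning.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def lcs_length_dp(a: str, b: str) -> int:
    """Longest common substring by the O(n*m) dynamic program."""
    if not a or not b:
        raise ValueError("empty input")
    bb = np.frombuffer(b.encode(), dtype="S1")
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    for ca in a:
        eq = bb == ca.encode()
        cur = np.zeros(len(b), dtype=np.int32)
        cur[0] = 1 if eq[0] else 0
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        best = max(best, int(cur.max()))
        prev = cur
    return best


def partition_by_closure(seqs: dict[str, str], min_shared: int) -> set[frozenset[str]]:
    """Gene partition from the transitive closure of all-pairs LCS >= min_shared."""
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if lcs_length_dp(seqs[a], seqs[b]) >= min_shared:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def ungapped_contamination_decision(
    orf: str, subjects: dict[str, str], min_len: int = 100, min_identity: float = 0.90
) -> bool:
    """Discard decision by exhaustive ungapped window scanning.

    For every diagonal offset of the ORF against every subject, every window
    longer than ``min_len`` is checked for identity above ``min_identity``.
    Exact for substitution-only (indel-free) constructions.
    """
    for subject in subjects.values():
        la, lb = len(orf), len(subject)
        for offset in range(-(la - 1), lb):
            # positions i in orf align to offset + i in subject
            lo = max(0, -offset)
            hi = min(la, lb - offset)
            if hi - lo <= min_len:
                continue
            matches = np.array(
                [orf[i] == subject[i + offset] for i in range(lo, hi)], dtype=np.int32
            )
            csum = np.concatenate([[0], np.cumsum(matches)])
            n = len(matches)
            for length in range(min_len + 1, n + 1):
                window = csum[length:] - csum[:-length]
                if window.size and window.max() / length > min_identity:
                    return True
    return False


def hypergeom_upper_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact upper-tail P(X >= k) via big-integer binomials."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        acc += comb(K, x) * comb(N - K, n - x)
    return Fraction(acc, total)


def hypergeom_lower_exact(N: int, K: int, n: int, k: int) -> Fraction:
    total = comb(N, n)
    acc = 0
    for x in range(0, min(k, K, n) + 1):
        if n - x > N - K:
            continue
        acc += comb(K, x) * comb(N - K, n - x)
    return Fraction(acc, total)


def bh_stepup_by_hand(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up executed literally from its definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def scan_motif_brute(protein: str, tokens: list[str | None]) -> list[int]:
    """1-based start positions of every motif match, position by position."""
    seq = protein.upper()
    L, k = len(seq), len(tokens)
    starts = []
    for s in range(L - k + 1):
        ok = True
        for j, tok in enumerate(tokens):
            if tok is None:
                continue
            if seq[s + j] not in tok:
                ok = False
                break
        if ok:
            starts.append(s + 1)
    return starts


def mixed_expectation_enumerate(labels: list[str], k: int) -> Fraction:
    """Exact P(cluster of size k drawn without replacement holds up AND down),
    by enumerating all C(N, k) subsets."""
    from itertools import combinations

    n_mixed = 0
    total = 0
    for subset in combinations(labels, k):
        total += 1
        if "up" in subset and "down" in subset:
            n_mixed += 1
    return Fraction(n_mixed, total)
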