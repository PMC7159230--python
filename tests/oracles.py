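"""Independent brute-force oracles used to check the pipeline.

These are deliberately naive: exhaustive diagonal scans for exact repeats,
per-column counting with Python sets for alignment statistics, and
breadth-first search over genome states for rearrangement distance. They
share no code with the implementation they verify.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _true_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """0-based inclusive runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def brute_force_exact_repeats(seq: str, min_len: int = 50
                              ) -> Set[Tuple[Tuple[int, int], Tuple[int, int], str]]:
    """All maximal exact repeated pairs >= min_len, as 1-based intervals.

    Direct pairs come from runs of equality along every diagonal of the
    self-comparison matrix; inverted pairs from runs along every
    anti-diagonal of the complement comparison. Self-identical intervals
    (including perfect palindromes mapping onto themselves) are excluded.
    """
    n = len(seq)
    au = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_map = np.zeros(256, dtype=np.uint8)
    for x, y in _COMP.items():
        comp_map[ord(x)] = ord(y)
    cu = comp_map[au]  # complement; 0 for non-ACGT so N never matches
    valid = np.isin(au, np.frombuffer(b"ACGT", dtype=np.uint8))
    out = set()
    for d in range(1, n - min_len + 1):
        eq = (au[:-d] == au[d:]) & valid[:-d] & valid[d:]
        for s, e in _true_runs(eq):
            if e - s + 1 >= min_len:
                out.add(((s + 1, e + 1), (s + d + 1, e + d + 1), "direct"))
    for a in range(2 * min_len - 2, 2 * n - 2 * min_len + 1):
        u_lo = max(0, a - (n - 1))
        u_hi = min(n - 1, a)
        us = np.arange(u_lo, u_hi + 1)
        eq = (au[us] == cu[a - us]) & valid[us] & valid[a - us]
        for s, e in _true_runs(eq):
            if e - s + 1 < min_len:
                continue
            lo, hi = u_lo + s, u_lo + e
            mirror = (a - hi, a - lo)
            if (lo, hi) == mirror:
                continue  # palindrome mapping onto itself: a self-hit
            if lo < mirror[0]:
                out.add(((lo + 1, hi + 1), (mirror[0] + 1, mirror[1] + 1), "inverted"))
    return out


# ---------------------------------------------------------------------------
# parsimony-informative columns, the slow way


def classify_alignment(rows: List[str]) -> Tuple[int, float]:
    """(pi_sites, missing_fraction) by per-column counting."""
    if not rows:
        return 0, 0.0
    n_cols = len(rows[0])
    pi = 0
    missing = 0
    for j in range(n_cols):
        counts: Dict[str, int] = {}
        for row in rows:
            c = row[j].upper()
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
            else:
                missing += 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            pi += 1
    return pi, missing / (len(rows) * n_cols)


# ---------------------------------------------------------------------------
# DCJ by breadth-first search over circular genome states

Extremity = Tuple[str, str]
Matching = FrozenSet[FrozenSet[Extremity]]


def identity_matching(n: int) -> Matching:
    """Adjacency set of the circular genome (g1 g2 ... gn)."""
    adjs = []
    for i in range(n):
        j = (i + 1) % n
        adjs.append(frozenset({(f"g{i + 1}", "h"), (f"g{j + 1}", "t")}))
    return frozenset(adjs)


def dcj_neighbors(state: Matching) -> List[Matching]:
    """All states one DCJ away (circular intermediates only)."""
    adjs = list(state)
    out = []
    for x, y in combinations(adjs, 2):
        p, q = tuple(x)
        r, s = tuple(y)
        rest = state - {x, y}
        out.append(rest | {frozenset({p, r}), frozenset({q, s})})
        out.append(rest | {frozenset({p, s}), frozenset({q, r})})
    return out


def bfs_distances(n: int) -> Dict[Matching, int]:
    """BFS distance from the identity circular genome to every matching."""
    start = identity_matching(n)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        for nxt in dcj_neighbors(state):
            if nxt not in dist:
                dist[nxt] = dist[state] + 1
                queue.append(nxt)
    return dist


def matching_to_chromosomes(state: Matching, n: int) -> List[List[Tuple[str, int]]]:
    """Decompose an adjacency matching into circular chromosomes."""
    partner: Dict[Extremity, Extremity] = {}
    for adj in state:
        pair = tuple(adj)
        if len(pair) == 1:  # adjacency of an extremity with itself cannot occur
            continue
        partner[pair[0]] = pair[1]
        partner[pair[1]] = pair[0]
    genes = [f"g{i + 1}" for i in range(n)]
    seen: Set[str] = set()
    chroms = []
    for g in genes:
        if g in seen:
            continue
        chrom: List[Tuple[str, int]] = [(g, 1)]
        seen.add(g)
        cur = partner[(g, "h")]
        while cur[0] != g:
            gene, end = cur
            sign = 1 if end == "t" else -1
            chrom.append((gene, sign))
            seen.add(gene)
            cur = partner[(gene, "h" if sign == 1 else "t")]
        chroms.append(chrom)
    return chroms
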