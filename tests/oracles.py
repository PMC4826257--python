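"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: exhaustive enumeration wherever
feasible, sharing no code path with the package.
"""

from __future__ import annotations

import itertools
from collections import deque
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------- alignment

@lru_cache(maxsize=None)
def _alignment_paths(la: int, lb: int) -> tuple[str, ...]:
    """All global alignment op-sequences for lengths (la, lb).

    Ops: M consumes one residue of each sequence, D one of the first,
    I one of the second.
    """
    if la == 0 and lb == 0:
        return ("",)
    paths = []
    if la > 0 and lb > 0:
        paths.extend("M" + p for p in _alignment_paths(la - 1, lb - 1))
    if la > 0:
        paths.extend("D" + p for p in _alignment_paths(la - 1, lb))
    if lb > 0:
        paths.extend("I" + p for p in _alignment_paths(la, lb - 1))
    return tuple(paths)


def _score_path(path: str, a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    score = 0.0
    i = j = 0
    prev = None
    for op in path:
        if op == "M":
            score += matrix[a[i], b[j]]
            i += 1
            j += 1
        else:
            if op != prev:
                score -= gap_open  # new gap: open once ...
            score -= gap_extend  # ... and extend per position
            if op == "D":
                i += 1
            else:
                j += 1
        prev = op
    return score


def brute_local_alignment_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Max over all substring pairs of all global alignments; >= 0 (empty allowed)."""
    best = 0.0
    for i0, i1 in itertools.combinations(range(len(a) + 1), 2):
        for j0, j1 in itertools.combinations(range(len(b) + 1), 2):
            sa, sb = a[i0:i1], b[j0:j1]
            for path in _alignment_paths(len(sa), len(sb)):
                s = _score_path(path, sa, sb, matrix, gap_open, gap_extend)
                if s > best:
                    best = s
    return int(best)


# -------------------------------------------------------------- betweenness

def brute_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    """Normalized betweenness by enumerating every shortest path of every pair."""
    nodes = sorted(adj)
    n = len(nodes)
    through: dict[str, float] = {v: 0.0 for v in nodes}

    def shortest_paths(src: str, dst: str) -> list[list[str]]:
        dist = {src: 0}
        preds: dict[str, list[str]] = {v: [] for v in nodes}
        queue = deque([src])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist.get(w) == dist[v] + 1:
                    preds[w].append(v)
        if dst not in dist:
            return []
        paths: list[list[str]] = []

        def walk(v: str, acc: list[str]) -> None:
            if v == src:
                paths.append([src] + acc)
                return
            for p in preds[v]:
                walk(p, [v] + acc)

        walk(dst, [])
        return paths

    for i, j in itertools.permutations(nodes, 2):
        paths = shortest_paths(i, j)
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (i, j):
                continue
            sigma_v = sum(1 for p in paths if v in p)
            through[v] += sigma_v / sigma
    scale = 1.0 / ((n - 1) * (n - 2))
    return {v: through[v] * scale for v in nodes}


# ----------------------------------------------------------- rank statistics

def enum_rank_sum_p(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) labelings."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    sums = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    total = len(sums)
    lower = sum(1 for s in sums if s <= w_obs) / total
    upper = sum(1 for s in sums if s >= w_obs) / total
    return min(1.0, 2.0 * min(lower, upper))


def enum_signed_rank_p(diffs: list[float]) -> float:
    """Exact two-sided signed-rank p by enumerating all 2**n sign assignments."""
    d = [v for v in diffs if v != 0]
    absd = sorted(abs(v) for v in d)
    assert len(set(absd)) == len(absd), "oracle requires tie-free |differences|"
    rank = {v: r for r, v in enumerate(absd, start=1)}
    n = len(d)
    w_obs = sum(rank[abs(v)] for v in d if v > 0)
    ranks = list(range(1, n + 1))
    ws = [
        sum(r for r, pos in zip(ranks, signs) if pos)
        for signs in itertools.product((False, True), repeat=n)
    ]
    total = len(ws)
    lower = sum(1 for w in ws if w <= w_obs) / total
    upper = sum(1 for w in ws if w >= w_obs) / total
    return min(1.0, 2.0 * min(lower, upper))


def enum_signed_rank_p_vectorized(diffs: np.ndarray) -> float:
    """As :func:`enum_signed_rank_p` but numpy-vectorized over the 2**n
    assignments (handles midranks), usable up to n = 21."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    masks = np.arange(2**n, dtype=np.int64)
    w_all = np.zeros(2**n)
    for k in range(n):
        w_all += np.where(masks & (1 << k), ranks[k], 0.0)
    total = w_all.size
    lower = np.count_nonzero(w_all <= w_obs + 1e-9) / total
    upper = np.count_nonzero(w_all >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(lower, upper))
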