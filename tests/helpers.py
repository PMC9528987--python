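"""Independent brute-force oracles and small samplers shared by the tests.

Everything here is deliberately naive (exhaustive enumeration, per-density
re-evaluation, direct pmf summation) and never calls the production code
paths it is used to check.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# Alignment oracle: exhaustive monotone alignments, free target end gaps
# ---------------------------------------------------------------------------

def align_score_bruteforce(query: str, target: str, match: int = 1,
                           mismatch: int = -1, gap: int = -1) -> int:
    """Best score of a full query against a target substring, by recursion
    over all monotone alignments with free leading/trailing target gaps."""
    m, n = len(query), len(target)

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if i == m:
            return 0  # remaining target skipped for free
        best = f(i + 1, j) + gap  # query base against a gap
        if j < n:
            sub = match if (query[i] == target[j] and query[i] in "ACGT") \
                else mismatch
            best = max(best, f(i + 1, j + 1) + sub, f(i, j + 1) + gap)
        return best

    return max(f(0, j) for j in range(n + 1))


# ---------------------------------------------------------------------------
# Density-clustering oracle: per-density greedy weakest-split evaluation
# ---------------------------------------------------------------------------

def _seg_density_min(pos, cnt, i, j):
    """Min density over all prefixes and suffixes (inclusive) of sites i..j;
    +inf for a single site."""
    if i == j:
        return math.inf
    vals = []
    for k in range(i, j + 1):
        vals.append(sum(cnt[i:k + 1]) / (pos[k] - pos[i] + 1))
        vals.append(sum(cnt[k:j + 1]) / (pos[j] - pos[k] + 1))
    return min(vals)


def _split_point(pos, cnt, i, j):
    pref = [sum(cnt[i:k + 1]) / (pos[k] - pos[i] + 1) for k in range(i, j)]
    suff = [sum(cnt[k:j + 1]) / (pos[j] - pos[k] + 1) for k in range(i + 1, j + 1)]
    if min(pref) <= min(suff):
        return i + pref.index(min(pref))
    return i + suff.index(min(suff))


def _clusters_at_density(pos, cnt, d):
    segs, out = [(0, len(pos) - 1)], set()
    while segs:
        i, j = segs.pop()
        if _seg_density_min(pos, cnt, i, j) >= d:
            out.add((i, j))
            continue
        s = _split_point(pos, cnt, i, j)
        segs.append((i, s))
        segs.append((s + 1, j))
    return out


def paraclu_bruteforce(sites):
    """Cluster set with (start, end, d_min, d_max) by evaluating the greedy
    hierarchical splitter independently at every candidate density (each
    exact prefix/suffix density plus an epsilon probe above it)."""
    pos = [p for p, _ in sites]
    cnt = [c for _, c in sites]
    n = len(sites)
    exact = sorted(
        {_seg_density_min(pos, cnt, i, j) for i in range(n) for j in range(i, n)}
        - {math.inf}
    )
    probes = sorted({0.0, *exact, *[d * (1 + 1e-9) + 1e-9 for d in exact]})
    appear: dict[tuple[int, int], list[float]] = {}
    for d in probes:
        for seg in _clusters_at_density(pos, cnt, d):
            appear.setdefault(seg, []).append(d)
    out = []
    for (i, j), ds in appear.items():
        first = min(ds)
        below = [e for e in exact if e < first]
        d_min = below[-1] if below else 0.0
        d_max = _seg_density_min(pos, cnt, i, j)
        out.append((pos[i], pos[j] + 1, round(d_min, 9),
                    round(d_max, 9) if d_max != math.inf else math.inf))
    return sorted(out)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def nb_draws(rng: np.random.Generator, mean: float, alpha: float, size):
    """NB with variance mean + alpha*mean^2 (Poisson when alpha == 0)."""
    if alpha <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
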