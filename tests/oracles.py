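"""Independent brute-force oracles used to check the implementation.

Everything here is written from the definitions, not from the package's
code paths: plain-python formula evaluation, exhaustive enumeration of
subintervals for the density clustering, and hypergeometric tails for the
exact test.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

from scipy.spatial.distance import jensenshannon
from scipy.stats import hypergeom


def hellinger_oracle(u: Sequence[float], v: Sequence[float]) -> float:
    acc = 0.0
    for a, b in zip(u, v):
        acc += (math.sqrt(a) - math.sqrt(b)) ** 2
    return math.sqrt(acc) / math.sqrt(2.0)


def jsd_oracle(p: Sequence[float], q: Sequence[float]) -> float:
    return float(jensenshannon(p, q, base=2) ** 2)


def usage_oracle(counts: Sequence[int]) -> List[float] | None:
    total = sum(counts)
    if total == 0:
        return None
    return [c / total for c in counts]


def utpm_oracle(gene_counts: Dict[str, int]) -> Dict[str, float] | None:
    total = sum(gene_counts.values())
    if total == 0:
        return None
    return {g: c * 1e6 / total for g, c in gene_counts.items()}


def fisher_tail_oracle(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher p for a 2x2 table by summing hypergeometric points."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return float(sum(rv.pmf(x) for x in range(lo, hi + 1)
                     if rv.pmf(x) <= p_obs * (1 + 1e-9)))


def _trim_density(pos: Sequence[int], val: Sequence[float], beg: int,
                  end: int) -> float:
    """Max density at which [beg, end) beats all its prefix/suffix trims."""
    if end - beg == 1:
        return math.inf
    best = math.inf
    tot = 0.0
    for i in range(beg, end - 1):          # trim prefix sites[beg..i]
        tot += val[i]
        best = min(best, tot / (pos[i + 1] - pos[beg]))
    tot = 0.0
    for i in range(end - 1, beg, -1):      # trim suffix sites[i..end-1]
        tot += val[i]
        best = min(best, tot / (pos[end - 1] - pos[i - 1]))
    return best


def paraclu_oracle(pos: Sequence[int], val: Sequence[float],
                   min_total: float = 10, max_length: int = 200,
                   min_density_ratio: float = 2.0
                   ) -> List[Tuple[int, int, int, float, float]]:
    """All maximal-density clusters by exhaustive subinterval search.

    A contiguous index range S is a cluster over the density interval
    (d_min, d_max] where d_max is its weakest-trim density and d_min the
    largest d_max of any strict super-range (for the full range: its
    overall density, 0 for a singleton).  Passing clusters are filtered
    and, per nest, only the largest is kept.  Returns (start_pos,
    end_pos_inclusive, total, d_min, d_max), sorted by start.
    """
    n = len(pos)
    dmax: Dict[Tuple[int, int], float] = {}
    for beg in range(n):
        for end in range(beg + 1, n + 1):
            dmax[(beg, end)] = _trim_density(pos, val, beg, end)
    passing = []
    for (beg, end), dx in dmax.items():
        supers = [dmax[(b, e)] for (b, e) in dmax
                  if b <= beg and e >= end and (b, e) != (beg, end)]
        if supers:
            dmin = max(supers)
        elif end - beg == 1:
            dmin = 0.0
        else:
            dmin = sum(val[beg:end]) / (pos[end - 1] - pos[beg])
        if dx <= dmin:
            continue
        total = sum(val[beg:end])
        length = pos[end - 1] - pos[beg] + 1
        ratio = math.inf if dmin == 0 else dx / dmin
        if total >= min_total and length <= max_length \
                and ratio >= min_density_ratio:
            passing.append((beg, end, total, dmin, dx))
    # keep the largest passing cluster per nest
    passing.sort(key=lambda t: (t[0] - t[1], t[0]))  # widest first
    kept: List[Tuple[int, int, float, float, float]] = []
    for beg, end, total, dmin, dx in passing:
        if any(kb <= beg and ke >= end for kb, ke, *_ in kept):
            continue
        kept.append((beg, end, total, dmin, dx))
    return sorted((pos[beg], pos[end - 1], int(total), dmin, dx)
                  for beg, end, total, dmin, dx in kept)


def single_linkage_clusters_oracle(positions: Sequence[int],
                                   max_gap: int) -> List[List[int]]:
    """Transitive closure over all pairs within max_gap (brute force)."""
    ps = sorted(positions)
    n = len(ps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(ps[i] - ps[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ps[i])
    return sorted(groups.values())
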