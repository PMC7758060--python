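"""Independent brute-force oracles used by the tests.

An affine-gap alignment is fully determined by its monotone set of
matched index pairs: unmatched residues between consecutive pairs form
gaps, one per sequence per inter-pair region (a switch between a-gaps
and b-gaps opens a new gap).  Enumerating every monotone matching and
scoring it directly therefore gives the optimal score without any
dynamic programming, at cost sum_k C(n,k)*C(m,k) — fine for n, m <= 8.
"""

from __future__ import annotations


def _matchings(n: int, m: int):
    """Yield every monotone matching of {0..n-1} x {0..m-1} as a list."""
    def rec(i, j):
        yield []
        for ii in range(i, n):
            for jj in range(j, m):
                for rest in rec(ii + 1, jj + 1):
                    yield [(ii, jj)] + rest
    yield from rec(0, 0)


def _gap_cost(da: int, db: int, go: float, ge: float) -> float:
    c = 0.0
    if da > 0:
        c += go + ge * da
    if db > 0:
        c += go + ge * db
    return c


def global_score_bruteforce(a: str, b: str, score, go: float, ge: float) -> float:
    """Optimal global (end gaps penalized) score by matching enumeration."""
    n, m = len(a), len(b)
    best = None
    for match in _matchings(n, m):
        total = 0.0
        prev_i, prev_j = -1, -1
        for i, j in match:
            total += _gap_cost(i - prev_i - 1, j - prev_j - 1, go, ge) * -1
            total += score(a[i], b[j])
            prev_i, prev_j = i, j
        total -= _gap_cost(n - prev_i - 1, m - prev_j - 1, go, ge)
        if best is None or total > best:
            best = total
    return best


def local_score_bruteforce(a: str, b: str, score, go: float, ge: float) -> float:
    """Optimal local score: best non-empty matching, internal gaps only."""
    n, m = len(a), len(b)
    best = 0.0
    for match in _matchings(n, m):
        if not match:
            continue
        total = 0.0
        prev_i, prev_j = match[0][0], match[0][1]
        total += score(a[prev_i], b[prev_j])
        for i, j in match[1:]:
            total -= _gap_cost(i - prev_i - 1, j - prev_j - 1, go, ge)
            total += score(a[i], b[j])
            prev_i, prev_j = i, j
        if total > best:
            best = total
    return best
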