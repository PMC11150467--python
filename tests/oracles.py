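"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — exhaustive enumeration over simple
paths, direct triple loops, explicit rank sets — and shares no code with the
package's implementations.
"""

from itertools import permutations

import numpy as np


def brute_distance(w: np.ndarray, i: int, j: int) -> float:
    """Shortest 1/w path length by enumerating every simple path."""
    n = w.shape[0]
    others = [k for k in range(n) if k not in (i, j)]
    best = np.inf
    for r in range(len(others) + 1):
        for mid in permutations(others, r):
            path = (i, *mid, j)
            length = 0.0
            for a, b in zip(path, path[1:]):
                if w[a, b] <= 0:
                    length = np.inf
                    break
                length += 1.0 / w[a, b]
            best = min(best, length)
    return best


def brute_distance_matrix(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = brute_distance(w, i, j)
    return d


def brute_betweenness(w: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unnormalized betweenness with fractional credit for tied geodesics."""
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            best = brute_distance(w, s, t)
            if not np.isfinite(best):
                continue
            shortest = []
            others = [k for k in range(n) if k not in (s, t)]
            for r in range(len(others) + 1):
                for mid in permutations(others, r):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / w[a, b]
                    if ok and abs(length - best) <= tol * max(best, 1.0):
                        shortest.append(path)
            for path in shortest:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def brute_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d = brute_distance(w, i, j)
                total += 1.0 / d if np.isfinite(d) else 0.0
    return total / (n * (n - 1))


def brute_clustering_zhang(w: np.ndarray) -> np.ndarray:
    """Zhang-Horvath weighted clustering by direct triple loops."""
    what = w / w.max() if w.max() > 0 else w
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        if (w[i] > 0).sum() < 2:
            continue
        num = den = 0.0
        for j in range(n):
            for k in range(n):
                if j != i and k != i and j != k:
                    num += what[i, j] * what[j, k] * what[k, i]
                    den += what[i, j] * what[i, k]
        out[i] = num / den if den > 0 else 0.0
    return out


def brute_local_efficiency_wang(w: np.ndarray) -> np.ndarray:
    """Incident-weighted neighborhood efficiency by direct loops."""
    what = w / w.max() if w.max() > 0 else w
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if what[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = what[np.ix_(nbrs, nbrs)]
        num = den = 0.0
        for a in range(len(nbrs)):
            for b in range(len(nbrs)):
                if a == b:
                    continue
                pw = what[i, nbrs[a]] * what[i, nbrs[b]]
                d = brute_distance(sub, a, b)
                num += pw * (1.0 / d if np.isfinite(d) else 0.0)
                den += pw
        out[i] = num / den if den > 0 else 0.0
    return out


def brute_hubscore(values: dict[str, np.ndarray], q: float = 0.2) -> np.ndarray:
    """Independent re-ranking hubscore: build the explicit at-or-beyond-cutoff
    set per criterion from a sorted copy."""
    higher = dict(strength=True, betweenness=True,
                  path_length=False, clustering=False)
    some = next(iter(values.values()))
    ok = np.ones(len(some), dtype=bool)
    for v in values.values():
        ok &= np.isfinite(v)
    n_ret = int(ok.sum())
    m = int(np.ceil(q * n_ret))
    score = np.zeros(len(some))
    for name, v in values.items():
        vv = sorted(v[ok], reverse=higher[name])
        cutoff = vv[m - 1]
        for idx in np.flatnonzero(ok):
            if (v[idx] >= cutoff) if higher[name] else (v[idx] <= cutoff):
                score[idx] += 1
    score[~ok] = np.nan
    return score


def random_connected_weights(rng, n, p=0.6) -> np.ndarray:
    """Random connected weighted graph (weights in (0.2, 1.2))."""
    while True:
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    w[i, j] = w[j, i] = 0.2 + rng.random()
        # connectivity via reachability
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(w[i] > 0):
                if j not in seen:
                    seen.add(int(j))
                    stack.append(int(j))
        if len(seen) == n:
            return w
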