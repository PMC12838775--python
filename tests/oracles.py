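"""Independent brute-force oracles for the numeric tests.

Deliberately naive implementations — explicit loops, textbook formulas,
Floyd-Warshall instead of Dijkstra, hand-rolled Pearson — kept free of any
import from the package so they constitute an independent cross-check.
"""

import math


def floyd_warshall(lengths):
    """All-pairs shortest paths by triple-loop relaxation.

    ``lengths[i][j]`` is the direct connection length (math.inf = no edge).
    """
    n = len(lengths)
    D = [[0.0 if i == j else lengths[i][j] for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = D[i][k] + D[k][j]
                if alt < D[i][j]:
                    D[i][j] = alt
    return D


def lengths_from_weights(W, exponent=1.0):
    n = len(W)
    return [
        [math.inf if W[i][j] == 0 else 1.0 / (W[i][j] ** exponent) for j in range(n)]
        for i in range(n)
    ]


def cpl_brute(W):
    D = floyd_warshall(lengths_from_weights(W))
    n = len(W)
    vals = [D[i][j] for i in range(n) for j in range(n) if i != j]
    return sum(vals) / len(vals)


def ge_brute(W):
    D = floyd_warshall(lengths_from_weights(W))
    n = len(W)
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += 0.0 if math.isinf(D[i][j]) else 1.0 / D[i][j]
                count += 1
    return total / count


def cc_brute(W):
    """Weighted clustering by explicit triplet enumeration."""
    n = len(W)
    acc = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if W[i][j] > 0)
        if k < 2:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j != h:
                    tri += (W[i][j] * W[i][h] * W[j][h]) ** (1.0 / 3.0)
        acc += tri / (k * (k - 1))
    return acc / n


def le_brute(W):
    """Weighted local efficiency by explicit neighborhood extraction."""
    n = len(W)
    acc = 0.0
    for u in range(n):
        nbrs = [j for j in range(n) if W[u][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = [[W[a][b] for b in nbrs] for a in nbrs]
        cbrt_lengths = [
            [math.inf if sub[a][b] == 0 else 1.0 / (sub[a][b] ** (1.0 / 3.0))
             for b in range(k)]
            for a in range(k)
        ]
        D = floyd_warshall(cbrt_lengths)
        numer = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and not math.isinf(D[a][b]):
                    numer += (W[u][nbrs[a]] ** (1.0 / 3.0)) * (
                        W[u][nbrs[b]] ** (1.0 / 3.0)
                    ) / D[a][b]
        acc += numer / (k * (k - 1))
    return acc / n


def pearson_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def hofc_brute(W, clip=1.0 - 1e-12):
    """Loop-level high-order matrix: delete rows, clip, atanh, Pearson."""
    n = len(W)
    H = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            rows = [r for r in range(n) if r not in (i, j)]
            ci = [math.atanh(max(-clip, min(clip, W[r][i]))) for r in rows]
            cj = [math.atanh(max(-clip, min(clip, W[r][j]))) for r in rows]
            if len(set(ci)) == 1 or len(set(cj)) == 1:
                r = 0.0
            else:
                r = pearson_brute(ci, cj)
            H[i][j] = H[j][i] = r
    return H


def bh_stepup_brute(p, q_star):
    """Benjamini-Hochberg by literal step-up: largest k with p_(k) <= k q*/m."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q_star / m:
            kmax = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= kmax:
            reject[idx] = True
    # adjusted values: running minimum of m * p_(j) / j from the top
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    adjusted = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        adjusted[idx] = adj_sorted[rank - 1]
    return adjusted, reject


def entropy_brute(labels):
    """State entropy by direct pair counting and the entropy formula."""
    pairs = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
    counts = {}
    for pr in pairs:
        counts[pr] = counts.get(pr, 0) + 1
    total = len(pairs)
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log(p)
    return h / math.log(4.0)
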