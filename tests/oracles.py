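"""Independent brute-force reference implementations (plain Python loops).

These deliberately avoid the package's vectorized code paths: distances
come straight from the haversine formula, kernel weights and smoother
matrices are built element by element, and regions/thresholds are found
by exhaustive enumeration.
"""

import math

R_KM = 6371.0


def bf_distance(lat1, lon1, lat2, lon2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2) - math.radians(lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * R_KM * math.asin(min(1.0, math.sqrt(a)))


def bf_kernel_weights(target, sources, rho):
    """target: (lat, lon); sources: list of (lat, lon)."""
    ks = [
        math.exp(-bf_distance(target[0], target[1], s[0], s[1]) ** 2 / (2 * rho * rho))
        for s in sources
    ]
    total = sum(ks)
    if total == 0.0:
        ds = [bf_distance(target[0], target[1], s[0], s[1]) for s in sources]
        w = [0.0] * len(sources)
        w[ds.index(min(ds))] = 1.0
        return w
    return [k / total for k in ks]


def bf_smooth(presence, sources, rho, grid_points):
    out = []
    for t in grid_points:
        w = bf_kernel_weights(t, sources, rho)
        out.append(sum(wi * yi for wi, yi in zip(w, presence)))
    return out


def bf_gcv(presence, sources, rho):
    n = len(presence)
    W = [bf_kernel_weights(s, sources, rho) for s in sources]
    trace_ratio = sum(W[i][i] for i in range(n)) / n
    yhat = [sum(W[i][l] * presence[l] for l in range(n)) for i in range(n)]
    rss = sum((yhat[i] - presence[i]) ** 2 for i in range(n)) / n
    score = rss / (1 - trace_ratio) ** 2 if trace_ratio < 1 else math.inf
    return score, trace_ratio, rss


def bf_loglik_field(prob_surfaces, presence, eps):
    """prob_surfaces: list over taxa of per-cell probability lists."""
    n_cells = len(prob_surfaces[0]) if prob_surfaces else 0
    out = []
    for k in range(n_cells):
        total = 0.0
        for j, y in enumerate(presence):
            p = min(max(prob_surfaces[j][k], eps), 1 - eps)
            total += y * math.log(p) + (1 - y) * math.log(1 - p)
        out.append(total)
    return out


def bf_pmf(loglik):
    mx = max(loglik)
    ws = [math.exp(v - mx) for v in loglik]
    t = sum(ws)
    return [w / t for w in ws]


def bf_hdr_region(pmf, q):
    """Exhaustive highest-density region with the tie-inclusion rule."""
    if q <= 0:
        return set()
    order = sorted(range(len(pmf)), key=lambda i: (-pmf[i], i))
    cum, stop_value = 0.0, None
    for i in order:
        cum += pmf[i]
        if cum >= q:
            stop_value = pmf[i]
            break
    if stop_value is None:  # rounding left the total below q
        stop_value = pmf[order[-1]]
    return {i for i in range(len(pmf)) if pmf[i] >= stop_value and pmf[i] > 0}


def bf_smallest_covering_q(pmfs, true_cells, level, q_grid):
    """Exhaustive scan: smallest q in q_grid with empirical coverage >= level."""
    for q in q_grid:
        covered = sum(
            1 for pmf, tc in zip(pmfs, true_cells) if tc in bf_hdr_region(pmf, q)
        )
        if covered / len(pmfs) >= level:
            return q
    return 1.0
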