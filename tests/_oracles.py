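"""Independent, naive reference implementations used only as test oracles.

Everything here is written as directly as possible (explicit loops,
textbook formulas) and shares no code with the package implementation.
"""

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np


def naive_rank_walk_scores(gene_ids, values, set_genes, method="maxdiff",
                           kernel="ecdf", tau=1.0):
    """Materialize the full enrichment random walk per observation.

    ``values``: genes x observations array. Returns one score per column.
    """
    gene_ids = list(gene_ids)
    p, n = values.shape
    set_genes = [g for g in set_genes if g in gene_ids]
    in_set = {g: (g in set(set_genes)) for g in gene_ids}
    n_out = p - len(set_genes)

    # gene-level statistic
    z = np.zeros((p, n))
    for i in range(p):
        row = values[i]
        if kernel == "ecdf" or (kernel == "gaussian" and np.std(row, ddof=1) == 0):
            for j in range(n):
                less = np.sum(row < row[j])
                ties = np.sum(row == row[j])
                z[i, j] = (less + (ties + 1) / 2.0) / n  # mean rank / n
        elif kernel == "gaussian":
            h = np.std(row, ddof=1) / 4.0
            for j in range(n):
                z[i, j] = np.mean([0.5 * (1 + erf((row[j] - xk) / (h * sqrt(2))))
                                   for xk in row])
        else:
            raise ValueError(kernel)

    scores = np.zeros(n)
    for j in range(n):
        # descending z, ties broken lexically by gene id
        order = sorted(range(p), key=lambda i: (-z[i, j], gene_ids[i]))
        weights = [abs(p / 2.0 - r) ** tau for r in range(1, p + 1)]
        in_total = sum(w for w, i in zip(weights, order) if in_set[gene_ids[i]])
        if in_total == 0:  # all in-set genes at the zero-weight middle rank
            weights = [1.0] * p
            in_total = float(len(set_genes))
        dev = 0.0
        profile = []
        for r, i in enumerate(order):
            if in_set[gene_ids[i]]:
                dev += weights[r] / in_total
            else:
                dev -= 1.0 / n_out
            profile.append(dev)
        mx, mn = max(profile), min(profile)
        if method == "maxdev":
            scores[j] = mx if mx >= -mn else mn
        else:
            scores[j] = max(mx, 0.0) + min(mn, 0.0)
    return scores


def brute_force_bh(p):
    """BH adjusted p-values as min_{j>=i} p_(j) * m / j, by direct search."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for pos, i in enumerate(order, start=1):
        candidates = [p[order[k - 1]] * m / k for k in range(pos, m + 1)]
        adj[i] = min(1.0, min(candidates))
    return np.array(adj)


def rank_pearson(x, y):
    """Spearman rho as Pearson correlation of mean-tie ranks, from scratch."""
    def ranks(v):
        v = list(map(float, v))
        out = [0.0] * len(v)
        for j, vj in enumerate(v):
            less = sum(1 for u in v if u < vj)
            ties = sum(1 for u in v if u == vj)
            out[j] = less + (ties + 1) / 2.0
        return out

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def exact_wilcoxon_p(x, y):
    """Two-sided exact rank-sum p by full enumeration of rank assignments."""
    x, y = list(x), list(y)
    nx, n = len(x), len(x) + len(y)
    pooled = sorted(x + y)

    def mean_rank(v):
        idx = [i + 1 for i, u in enumerate(pooled) if u == v]
        return sum(idx) / len(idx)

    all_ranks = [mean_rank(v) for v in (x + y)]
    u_obs = sum(all_ranks[:nx]) - nx * (nx + 1) / 2.0
    le = ge = 0
    for subset in combinations(range(n), nx):
        ranks_all = [mean_rank(v) for v in (x + y)]
        u = sum(ranks_all[i] for i in subset) - nx * (nx + 1) / 2.0
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    total = comb(n, nx)
    return min(1.0, 2.0 * min(le, ge) / total)


def cox_grid_beta(times, events, x, lo=-5.0, hi=5.0, tol=1e-6):
    """Golden-section maximization of the 1-covariate Breslow partial likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)

    def ll(beta):
        eta = beta * x
        total = 0.0
        for t in sorted(set(times[events == 1])):
            dead = (times == t) & (events == 1)
            risk = times >= t
            total += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[risk]).sum())
        return total

    gr = (sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = ll(c), ll(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = ll(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = ll(d)
    return (a + b) / 2


def empirical_survival(times):
    """No-censoring survival function S(t) = #(T > t)/n at each event time."""
    times = sorted(times)
    n = len(times)
    return {t: sum(1 for u in times if u > t) / n for t in times}
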