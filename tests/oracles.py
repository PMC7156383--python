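"""Independent naive/brute-force reference implementations used only by tests.

Each function restates its statistic from first principles (explicit loops,
direct formulas) and is kept deliberately separate from the package code paths
it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_ssgsea(genes, values, set_genes, alpha):
    """Running-sum enrichment score via an explicit loop.

    Genes sorted by decreasing value, ties by symbol; rank N for the top gene.
    """
    order = sorted(range(len(genes)), key=lambda i: (-values[i], str(genes[i])))
    n = len(genes)
    in_set = [genes[i] in set_genes for i in order]
    m = sum(in_set)
    ranks = [n - pos for pos in range(n)]
    total_w = sum(abs(ranks[pos]) ** alpha for pos in range(n) if in_set[pos])
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for pos in range(n):
        if in_set[pos]:
            cum_in += abs(ranks[pos]) ** alpha
        else:
            cum_out += 1
        es += cum_in / total_w - cum_out / (n - m)
    return es


def naive_ned(M, labels):
    """Double-loop RMS distance of a consensus matrix from its perfect matrix."""
    n = len(labels)
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 if labels[i] == labels[j] else 0.0
            total += (M[i][j] - p) ** 2
            count += 1
    return math.sqrt(total / count)


def naive_km(times, events):
    """Product-limit estimator via an explicit risk-set loop.

    Returns (death_times, survival_probs); deaths precede censorings at ties.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out_t, out_s = [], []
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def naive_median_survival(death_times, survival_probs):
    for t, s in zip(death_times, survival_probs):
        if s <= 0.5 + 1e-12:
            return t
    return math.nan


def naive_logrank_two_group(t1, e1, t2, e2):
    """Two-group Mantel-Cox chi-square via risk-set enumeration."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    O1 = E1 = V = 0.0
    for t in sorted(set(all_t[all_e == 1])):
        at_risk = all_t >= t
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((all_t == t) & (all_e == 1) & (grp == 0)).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O1 - E1) ** 2 / V


def naive_bh(p):
    """Step-up BH adjusted p-values (monotone-enforced)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = min(running_min, 1.0)
    return adj


def naive_chi_square(table):
    """Pearson chi-square Sum (O - E)^2 / E without continuity correction."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = row[i] * col[j] / n
            stat += (table[i, j] - e) ** 2 / e
    return stat


def naive_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def naive_welch(a, b):
    """Welch t statistic and two-sided p via the direct formula."""
    from scipy import stats as sps

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def naive_consensus_tally(X, k, n_resamples, fraction, seed, base_cluster_fn):
    """Brute-force co-clustering tally over the same resample stream the
    package consumes (same generator seeding and draw order)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    co_cluster = [[0] * n for _ in range(n)]
    co_sample = [[0] * n for _ in range(n)]
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        labels = base_cluster_fn(X[idx], k)
        for a in range(m):
            for b in range(m):
                i, j = idx[a], idx[b]
                co_sample[i][j] += 1
                if labels[a] == labels[b]:
                    co_cluster[i][j] += 1
    M = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(n):
            if co_sample[i][j] > 0:
                M[i][j] = co_cluster[i][j] / co_sample[i][j]
    np.fill_diagonal(M, 1.0)
    return M
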