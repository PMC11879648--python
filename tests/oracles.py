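"""Independent reference implementations used only for cross-checking.

Each oracle is coded directly from the mathematical definition and stays
independent of the library code paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def huber_value(x, M):
    x = np.asarray(x, float)
    return np.where(np.abs(x) >= M, 2 * M * np.abs(x) - M ** 2, x ** 2)


def medpolish_sweeps(X, eps=1e-10, max_sweeps=100):
    """Sweep-by-sweep Tukey median polish (no missing-row/col handling)."""
    r = np.array(X, float)
    t = 0.0
    re = np.zeros(r.shape[0])
    ce = np.zeros(r.shape[1])
    last = 0.0
    for _ in range(max_sweeps):
        rm = np.nanmedian(r, axis=1)
        r = r - rm[:, None]
        re = re + rm
        shift = np.median(ce)
        ce = ce - shift
        t = t + shift
        cm = np.nanmedian(r, axis=0)
        r = r - cm[None, :]
        ce = ce + cm
        shift = np.median(re)
        re = re - shift
        t = t + shift
        s = float(np.nansum(np.abs(r)))
        if s == 0.0 or abs(s - last) < eps * max(s, 1.0):
            break
        last = s
    return t, re, ce, r


def huber_two_way_fit(X, M):
    """Per-channel summaries of the single-protein two-way model
    X_fc = m + a_f + b_c under Huber loss, via scipy.optimize.least_squares
    (whose 'huber' loss with f_scale=M equals the same loss up to a constant
    factor). Returns Y_c = m + mean_f(a_f) + b_c."""
    X = np.asarray(X, float)
    F, C = X.shape
    obs_f, obs_c = np.where(np.isfinite(X))
    y = X[obs_f, obs_c]

    def unpack(theta):
        m = theta[0]
        a = np.concatenate([[0.0], theta[1:F]])
        b = np.concatenate([[0.0], theta[F:F + C - 1]])
        return m, a, b

    def fun(theta):
        m, a, b = unpack(theta)
        return y - (m + a[obs_f] + b[obs_c])

    x0 = np.zeros(1 + (F - 1) + (C - 1))
    x0[0] = np.nanmean(X)
    res = optimize.least_squares(
        fun, x0, loss="huber", f_scale=M, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    m, a, b = unpack(res.x)
    return m + a.mean() + b


def grid_weight_search(b, p_first, p_second, M, step=0.001):
    """Best convex-combination weight of two profiles by brute grid search.

    For each candidate weight the feature-offset nuisance is minimized by a
    1-d Brent search; returns the grid weight of the first profile with the
    lowest Huber objective."""
    ts = np.arange(0.0, 1.0 + step / 2, step)
    best_t, best_v = 0.0, np.inf
    for t in ts:
        r = b - (t * p_first + (1 - t) * p_second)
        d = optimize.minimize_scalar(
            lambda d: float(huber_value(r - d, M).sum()),
            bracket=(float(r.min()) - 1.0, float(r.max()) + 1.0),
        ).x
        v = float(huber_value(r - d, M).sum())
        if v < best_v:
            best_t, best_v = float(t), v
    return best_t


def bh_step_up(p):
    """Benjamini-Hochberg adjusted p-values, coded from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def two_sample_t(a, b):
    """Classical pooled-variance two-sample t-test (two-sided)."""
    from scipy import stats as sps

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    t = (a.mean() - b.mean()) / se
    df = na + nb - 2
    return t, df, 2 * sps.t.sf(abs(t), df)


def connected_components_union_find(edges):
    """Union-find over an edge list; returns frozensets of node labels."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}
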