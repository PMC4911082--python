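"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive — enumeration, pairwise scans,
generic constrained optimization — and shares no code path with the
implementations it checks.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata


def ranksum_exact_p(case, control):
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    x = np.asarray(case, float)
    y = np.asarray(control, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    m = x.size
    w_obs = ranks[:m].sum()
    ws = np.array([sum(c) for c in combinations(ranks, m)])
    eps = 1e-9
    p_lo = np.mean(ws <= w_obs + eps)
    p_hi = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def ranksum_permutation_p(case, control, n_perm, rng):
    """Monte-Carlo permutation two-sided p for the rank-sum statistic."""
    x = np.asarray(case, float)
    y = np.asarray(control, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    m = x.size
    w_obs = ranks[:m].sum()
    ws = np.empty(n_perm)
    for i in range(n_perm):
        ws[i] = ranks[rng.permutation(ranks.size)[:m]].sum()
    eps = 1e-9
    p_lo = np.mean(ws <= w_obs + eps)
    p_hi = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        j = m - rank_from_top          # 1-based rank in sorted order
        running = min(running, m * p[idx] / j)
        adj[idx] = running
    return adj


def auc_pair_concordance(scores, labels):
    """AUC as the average pairwise concordance, ties counting one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def single_linkage_partition(peaks, mass_tol_ppm, ce_tol_min):
    """Connected components under the pairwise identity rule.

    ``peaks``: list of (mass, ce_time).  Two peaks are linked when their
    mass deviation (relative to the smaller mass) is within tolerance and
    their CE times are within tolerance.  Returns a set of frozensets of
    peak indices.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (m1, t1), (m2, t2) = peaks[i], peaks[j]
            if abs(m1 - m2) / min(m1, m2) * 1e6 <= mass_tol_ppm \
                    and abs(t1 - t2) <= ce_tol_min:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def svm_dual_qp(X, y, C, gamma):
    """Soft-margin RBF-SVM dual solved by generic SLSQP.

    Returns (alpha, bias); decision(x) = sum_i alpha_i y_i K(x_i, x) + bias.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    K = np.exp(-gamma * sq)
    Q = (y[:, None] * y[None, :]) * K

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    res = minimize(neg_dual, np.full(n, min(C, 1.0) / 2), jac=grad,
                   bounds=[(0.0, C)] * n, constraints=[cons],
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    alpha = res.x
    dec_wo_b = (alpha * y) @ K
    free = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    if free.any():
        bias = float(np.mean(y[free] - dec_wo_b[free]))
    else:
        lo = np.max((y - dec_wo_b)[(y > 0) & (alpha < C * (1 - 1e-6)) | (y < 0) & (alpha > 1e-6 * C)])
        hi = np.min((y - dec_wo_b)[(y < 0) & (alpha < C * (1 - 1e-6)) | (y > 0) & (alpha > 1e-6 * C)])
        bias = float(0.5 * (lo + hi))
    return alpha, bias


def svm_decision(X_train, y_train, alpha, bias, gamma, X_test):
    X_train = np.asarray(X_train, float)
    X_test = np.atleast_2d(np.asarray(X_test, float))
    sq = np.sum((X_test[:, None, :] - X_train[None, :, :]) ** 2, axis=2)
    K = np.exp(-gamma * sq)
    return K @ (alpha * np.asarray(y_train, float)) + bias
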