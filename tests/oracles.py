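"""Independent brute-force oracles the tests check the implementation against.

Everything here is written as plain loops over definitions, deliberately
sharing no code with the package.
"""

from itertools import combinations

import numpy as np


def brute_force_ssgsea(values, gene_ids, gene_set, alpha):
    """Running-sum enrichment by direct iteration over the ranked gene list."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    n = len(values)
    in_set = [gene_ids[i] in set(gene_set) for i in order]
    total_in = sum((n - pos) ** alpha for pos, flag in enumerate(in_set) if flag)
    total_out = sum(1 for flag in in_set if not flag)
    score = 0.0
    run_in = 0.0
    run_out = 0
    for pos, flag in enumerate(in_set):
        if flag:
            run_in += (n - pos) ** alpha
        else:
            run_out += 1
        score += run_in / total_in - run_out / total_out
    return score


def pearson_closed_form(x, y):
    """Product-moment correlation straight from the covariance definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def mannwhitney_exact_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group1, group2):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in group1 for y in group2)

    u_obs = u_stat(a, b)
    idx = range(len(pooled))
    us = []
    for chosen in combinations(idx, n1):
        g1 = [pooled[i] for i in chosen]
        g2 = [pooled[i] for i in idx if i not in chosen]
        us.append(u_stat(g1, g2))
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def logrank_statistic(times1, times2, events1, events2):
    """Log-rank chi-square from the hypergeometric increments at each event time."""
    times = np.concatenate([times1, times2])
    events = np.concatenate([events1, events2]).astype(bool)
    group1 = np.concatenate([np.ones(len(times1), bool), np.zeros(len(times2), bool)])
    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group1).sum()
        observed_minus_expected += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return observed_minus_expected**2 / variance


def cox_partial_likelihood_mle(x, times, events):
    """Maximize the Breslow partial likelihood over a scalar coefficient by search."""
    from scipy.optimize import minimize_scalar

    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)

    def neg_loglik(beta):
        ll = 0.0
        for t in np.unique(times[events]):
            dead = events & (times == t)
            at_risk = times >= t
            ll += beta * x[dead].sum() - dead.sum() * np.log(np.exp(beta * x[at_risk]).sum())
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-10, 10), method="bounded", options={"xatol": 1e-10})
    return float(res.x)
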