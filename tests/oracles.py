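"""Independent brute-force oracles used to cross-check the implementation.

Each function here is coded directly from the textbook definition of its
statistic, in plain scalar/loop form, deliberately sharing no code with the
package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def ttest_oracle(x, y, pooled: bool = True) -> tuple[float, float]:
    """Two-sample t from first principles (means, SDs, df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n0 = len(x), len(y)
    m1, m0 = sum(x) / n1, sum(y) / n0
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v0 = sum((yi - m0) ** 2 for yi in y) / (n0 - 1)
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n0))
        df = n1 + n0 - 2
    else:
        se = math.sqrt(v1 / n1 + v0 / n0)
        df = (v1 / n1 + v0 / n0) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
    t = (m1 - m0) / se
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def km_oracle(times, events) -> dict[float, float]:
    """Product-limit estimator: S(t) at each distinct observed time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.sort(np.unique(times)):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        if at_risk > 0 and d > 0:
            s *= 1 - d / at_risk
        out[float(t)] = s
    return out


def logrank_oracle(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square via the hypergeometric O-E/V form."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    glab = np.unique(groups)
    assert len(glab) == 2
    g1 = groups == glab[0]
    O = E = V = 0.0
    for t in np.sort(np.unique(times[events == 1])):
        at = times >= t
        n_all = int(at.sum())
        n1 = int((at & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        O += d1
        E += d * n1 / n_all
        if n_all > 1:
            V += d * (n1 / n_all) * (1 - n1 / n_all) * (n_all - d) / (n_all - 1)
    if V == 0:
        raise ValueError("degenerate design: log-rank variance is zero")
    chi2 = (O - E) ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, 1))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration over the fixed margins.

    Sums the hypergeometric probabilities of every table as or less likely
    than the observed one (the standard two-sided convention).
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def pearson_oracle(x, y) -> tuple[float, float]:
    """Pearson r from covariance/SDs; two-sided p from the t transform."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    r = cov / (sx * sy)
    t = r * math.sqrt(n - 2) / math.sqrt(max(1 - r * r, 1e-300))
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def bayes_posterior_oracle(c, mu_h, s_h, mu_c, s_c, pi_h=0.5, pi_c=0.5) -> float:
    """Posterior of the high class by the plain density-ratio formula."""
    f_h = math.exp(-0.5 * ((c - mu_h) / s_h) ** 2) / (s_h * math.sqrt(2 * math.pi))
    f_c = math.exp(-0.5 * ((c - mu_c) / s_c) ** 2) / (s_c * math.sqrt(2 * math.pi))
    return pi_h * f_h / (pi_h * f_h + pi_c * f_c)


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Written-out Cox partial log-likelihood for one covariate, no ties."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - math.log(sum(math.exp(beta * xj) for xj in x[risk]))
    return ll


def cox_mle_oracle(times, events, x) -> float:
    """Maximize the partial likelihood by golden-section search on beta."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, times, events, x),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
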