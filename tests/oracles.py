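"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own computational routes: the
tetrachoric oracle evaluates cell probabilities through scipy's
multivariate normal CDF, and the continuous-fit oracle evaluates the
bivariate normal log-density directly from its formula on a refined grid.
"""
import math

import numpy as np
from scipy import stats

LOG2PI = math.log(2 * math.pi)


def tetrachoric_grid_oracle(table, step=0.001):
    """Brute-force ML over (rho, t1, t2) for a 2x2 concordance table."""
    table = np.asarray(table, float)
    n = table.sum()
    t1c = stats.norm.ppf(table[0].sum() / n)
    t2c = stats.norm.ppf(table[:, 0].sum() / n)

    def ll(r, t1, t2):
        F = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([t1, t2])
        p1, p2 = stats.norm.cdf(t1), stats.norm.cdf(t2)
        cells = np.clip([[F, p1 - F], [p2 - F, 1 - p1 - p2 + F]],
                        1e-12, 1.0)
        return float(np.sum(table * np.log(cells)))

    best = (-np.inf, 0.0, t1c, t2c)
    for r in np.arange(-0.95, 0.96, 0.05):
        for t1 in t1c + np.arange(-0.2, 0.21, 0.1):
            for t2 in t2c + np.arange(-0.2, 0.21, 0.1):
                v = ll(r, t1, t2)
                if v > best[0]:
                    best = (v, r, t1, t2)
    _, r0, t10, t20 = best
    for r in np.arange(max(r0 - 0.06, -0.999), min(r0 + 0.06, 0.999), step):
        for t1 in t10 + np.arange(-0.12, 0.13, 0.02):
            for t2 in t20 + np.arange(-0.12, 0.13, 0.02):
                v = ll(r, t1, t2)
                if v > best[0]:
                    best = (v, r, t1, t2)
    return best[1]


def continuous_ae_grid_oracle(y, zygosity):
    """Refined grid maximum of the AE pair likelihood over
    (a2, sigma, intercept) for a tiny dataset; returns
    (max loglik, a2, sigma, intercept)."""
    y = np.asarray(y, float)
    zyg = np.asarray(zygosity)

    def negll(a2, sd, mu):
        r = (y - mu) / sd
        rho = np.where(zyg == "MZ", a2, a2 / 2)
        q = (r[:, 0] ** 2 + r[:, 1] ** 2
             - 2 * rho * r[:, 0] * r[:, 1]) / (1 - rho ** 2)
        return -float(np.sum(-LOG2PI - 2 * np.log(sd)
                             - 0.5 * np.log(1 - rho ** 2) - 0.5 * q))

    a_g = np.linspace(0.0, 0.99, 100)
    s_g = np.linspace(0.2, 1.5, 66)
    m_g = np.linspace(-1.0, 1.5, 51)
    best = min(((negll(a, s, m), a, s, m)
                for a in a_g for s in s_g for m in m_g))
    for _ in range(3):
        _, a0, s0, m0 = best
        a_g = np.clip(np.linspace(a0 - 0.02, a0 + 0.02, 21), 0, 0.999)
        s_g = np.linspace(max(s0 - 0.02, 0.01), s0 + 0.02, 21)
        m_g = np.linspace(m0 - 0.05, m0 + 0.05, 21)
        best = min(((negll(a, s, m), a, s, m)
                    for a in a_g for s in s_g for m in m_g))
    f, a, s, m = best
    return -f, a, s, m
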