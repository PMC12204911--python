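"""Liability-threshold twin models for dichotomous traits.

A binary trait (airflow obstruction, chronic bronchitis, clinical COPD) is
treated as the indicator that a standard-normal latent liability exceeds a
threshold.  Covariates (sex, age, height) shift the threshold on the probit
scale; the liability correlation between co-twins is structured through the
same A/D/C/E decomposition as the continuous models, with the total
liability variance fixed at 1 so the components are fractions directly.
Twin-pair concordance tables summarized as tetrachoric correlations provide
the model-free view of familial resemblance.

The workhorse is the standard bivariate normal rectangle probability,
computed from Owen's T function (vectorized, absolute error well below the
1e-7 contract).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import owens_t

from .cohort import PairData
from .continuous import (
    MODEL_LABELS, TwinModelFit, VarianceComponents, _fd_grad, _standardizer,
    fd_hessian, implied_correlations,
)

_norm = stats.norm


# ---------------------------------------------------------------------------
# Bivariate normal probabilities
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal correlation rho.

    Owen (1956): Phi2(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k)
    - beta, with beta = 1/2 when hk < 0 (or hk = 0 with h + k < 0).
    Vectorized; +/-inf margins allowed.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("|rho| must be < 1")
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape, dtype=float)

    neg_inf = (h == -np.inf) | (k == -np.inf)
    h_inf = (h == np.inf) & ~neg_inf
    k_inf = (k == np.inf) & ~neg_inf
    finite = ~(neg_inf | h_inf | k_inf)

    out[neg_inf] = 0.0
    out[h_inf & k_inf] = 1.0
    out[h_inf & ~k_inf] = _norm.cdf(k[h_inf & ~k_inf])
    out[k_inf & ~h_inf] = _norm.cdf(h[k_inf & ~h_inf])

    if np.any(finite):
        hf = h[finite].copy()
        kf = k[finite].copy()
        rf = rho[finite]
        # (near-)zeros shifted by a negligible amount so the Owen-T
        # arguments stay finite; the induced error is O(1e-10)
        hf = np.where(np.abs(hf) < 1e-10, np.copysign(1e-10, hf), hf)
        kf = np.where(np.abs(kf) < 1e-10, np.copysign(1e-10, kf), kf)
        den = np.sqrt(1.0 - rf ** 2)
        ah = (kf - rf * hf) / (hf * den)
        ak = (hf - rf * kf) / (kf * den)
        beta = np.where(hf * kf < 0.0, 0.5, 0.0)
        val = (0.5 * (_norm.cdf(hf) + _norm.cdf(kf))
               - owens_t(hf, ah) - owens_t(kf, ak) - beta)
        out[finite] = val
    return np.clip(out, 0.0, 1.0)


def bvn_rectangle(lo1, hi1, lo2, hi2, rho):
    """P(lo1 < Z1 < hi1, lo2 < Z2 < hi2), standard bivariate normal.

    Limits may be +/-inf; |rho| must be < 1.  Absolute error <= 1e-7.
    """
    lo1, hi1 = np.asarray(lo1, float), np.asarray(hi1, float)
    lo2, hi2 = np.asarray(lo2, float), np.asarray(hi2, float)
    if np.any(lo1 >= hi1) or np.any(lo2 >= hi2):
        raise ValueError("lower limit must be below upper limit")
    p = (bvn_cdf(hi1, hi2, rho) - bvn_cdf(lo1, hi2, rho)
         - bvn_cdf(hi1, lo2, rho) + bvn_cdf(lo1, lo2, rho))
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def prevalence_to_threshold(prevalence: float) -> float:
    """Threshold t with P(Z > t) = prevalence on the liability scale."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    return float(_norm.isf(prevalence))


# ---------------------------------------------------------------------------
# Tetrachoric correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TetrachoricEstimate:
    """Latent-normal correlation of a dichotomized bivariate normal."""

    rho: float
    ci95: tuple[float, float]
    n_pairs: int
    zygosity: str = ""
    thresholds: tuple[float, float] = (0.0, 0.0)


def _table_probs(t1: float, t2: float, rho: float) -> np.ndarray:
    """Cell probabilities [[p00, p01], [p10, p11]] (1 = above threshold)."""
    F = float(bvn_cdf(t1, t2, rho))
    p1, p2 = _norm.cdf(t1), _norm.cdf(t2)
    return np.array([[F, p1 - F], [p2 - F, 1.0 - p1 - p2 + F]])


def _table_loglik(table: np.ndarray, t1: float, t2: float,
                  rho: float) -> float:
    p = np.clip(_table_probs(t1, t2, rho), 1e-300, 1.0)
    return float(np.sum(table * np.log(p)))


def tetrachoric(contingency, zygosity: str = "",
                level: float = 0.95) -> TetrachoricEstimate:
    """ML tetrachoric correlation from a 2x2 concordance table.

    ``contingency[i][j]`` counts pairs with member-1 status i and member-2
    status j (0 = below threshold / control, 1 = case).  The three-parameter
    model (rho and two thresholds) is just-identified, so the multinomial
    MLE reproduces the margins exactly: the thresholds are the inverse
    normal of the marginal proportions and rho solves
    Phi2(t1, t2, rho) = n00/n.  The CI is a profile-likelihood interval.
    """
    table = np.asarray(contingency, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("contingency must be a nonnegative 2x2 table")
    n = table.sum()
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(
            "empty margin: tetrachoric undefined; collapse or use exact "
            "boundary handling")
    p1 = table[0].sum() / n      # P(member 1 below threshold)
    p2 = table[:, 0].sum() / n
    t1, t2 = float(_norm.ppf(p1)), float(_norm.ppf(p2))
    target = table[0, 0] / n

    def g(r):
        return float(bvn_cdf(t1, t2, r)) - target

    lo, hi = -1 + 1e-10, 1 - 1e-10
    if g(lo) * g(hi) > 0:          # degenerate table, rho at boundary
        rho = lo if abs(g(lo)) < abs(g(hi)) else hi
    else:
        rho = optimize.brentq(g, lo, hi, xtol=1e-12)

    ll_max = _table_loglik(table, t1, t2, rho)
    q = stats.chi2.ppf(level, 1)

    def profile_dev(r):
        res = optimize.minimize(
            lambda t: -_table_loglik(table, t[0], t[1], r),
            np.array([t1, t2]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10})
        return 2.0 * (ll_max + res.fun) - q

    try:
        lo_ci = (-1 + 1e-6 if profile_dev(-1 + 1e-6) < 0
                 else optimize.brentq(profile_dev, -1 + 1e-6, rho, xtol=1e-5))
    except ValueError:
        lo_ci = -1.0
    try:
        hi_ci = (1 - 1e-6 if profile_dev(1 - 1e-6) < 0
                 else optimize.brentq(profile_dev, rho, 1 - 1e-6, xtol=1e-5))
    except ValueError:
        hi_ci = 1.0
    return TetrachoricEstimate(float(rho), (float(lo_ci), float(hi_ci)),
                               int(n), zygosity, (t1, t2))


def concordance_table(pairs: PairData) -> np.ndarray:
    """2x2 case-concordance counts of binary pair data (0/1 trait)."""
    y = pairs.y.astype(int)
    table = np.zeros((2, 2))
    for i, j in y:
        table[i, j] += 1
    return table


# ---------------------------------------------------------------------------
# Liability-threshold model fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdModel:
    """Probit-scale covariate effects on the case threshold.

    The subject-specific threshold is
    ``t_i = -(gamma0 + gamma_sex*sex + gamma_age*age + gamma_height*height)``
    so that positive coefficients increase the case probability.
    """

    gamma0: float = 0.0
    gamma_sex: float = 0.0
    gamma_age: float = 0.0
    gamma_height: float = 0.0

    def thresholds(self, x: np.ndarray,
                   covariates: Sequence[str] = ("sex", "age", "height")
                   ) -> np.ndarray:
        gammas = {"sex": self.gamma_sex, "age": self.gamma_age,
                  "height": self.gamma_height}
        g = np.array([gammas[c] for c in covariates])
        return -(self.gamma0 + x @ g)


# fraction parameterization: a2 = sin^2(u), second = (1-a2) sin^2(v)
def _fracs_from_angles(model: str, angles: np.ndarray) -> dict[str, float]:
    names = {"ACE": ("a", "c"), "ADE": ("a", "d"),
             "AE": ("a",), "CE": ("c",)}[model]
    fr: dict[str, float] = {}
    rem = 1.0
    for nm, u in zip(names, angles):
        f = rem * math.sin(u) ** 2
        fr[nm] = f
        rem -= f
    fr["e"] = rem
    return fr


def _liability_r(model: str, angles: np.ndarray) -> tuple[float, float]:
    fr = _fracs_from_angles(model, angles)
    va, vd, vc = fr.get("a", 0.0), fr.get("d", 0.0), fr.get("c", 0.0)
    return va + vd + vc, 0.5 * va + 0.25 * vd + vc


_N_STRUCT = {"ACE": 2, "ADE": 2, "AE": 1, "CE": 1}


def _pair_cell_loglik(y: np.ndarray, t: np.ndarray, rho: np.ndarray
                      ) -> float:
    """Sum of log concordance-cell probabilities.

    ``y`` (n,2) in {0,1}; ``t`` (n,2) member thresholds; ``rho`` (n,)
    liability correlations.
    """
    rho = np.clip(rho, -1 + 1e-9, 1 - 1e-9)
    F = bvn_cdf(t[:, 0], t[:, 1], rho)
    p1 = _norm.cdf(t[:, 0])
    p2 = _norm.cdf(t[:, 1])
    y1, y2 = y[:, 0], y[:, 1]
    p = np.where(
        (y1 == 0) & (y2 == 0), F,
        np.where((y1 == 0) & (y2 == 1), p1 - F,
                 np.where((y1 == 1) & (y2 == 0), p2 - F,
                          1.0 - p1 - p2 + F)))
    return float(np.sum(np.log(np.clip(p, 1e-300, 1.0))))


def fit_liability(pairs: PairData,
                  model_label: str = "AE",
                  covariates: Sequence[str] | None = None,
                  include_opposite_sex_dz: bool = False,
                  n_restarts: int = 5,
                  seed: int = 0,
                  ci_method: str | None = "delta",
                  trait: str = "") -> TwinModelFit:
    """Maximum-likelihood liability-threshold twin model for a binary trait.

    Each complete pair contributes the bivariate-normal probability of its
    observed concordance cell, with member-specific thresholds from the
    probit covariate model and liability correlation implied by the A/D/C/E
    fractions for the pair's zygosity (SAT frees rho_MZ and rho_DZ).
    Opposite-sex DZ pairs are excluded by default, matching the reporting
    of same-sex twin correlations; ``include_opposite_sex_dz`` overrides.
    The total liability variance is fixed at 1 for identification, so the
    heritability is the fitted a2 directly.
    """
    if model_label not in MODEL_LABELS or model_label == "E":
        raise ValueError(f"unsupported liability model {model_label!r}")
    if covariates is None:
        covariates = pairs.covariate_names
    if not include_opposite_sex_dz:
        pairs = pairs.subset(pairs.zygosity != "DZ_opposite_sex")
    y = pairs.y.astype(int)
    if len(y) == 0:
        raise ValueError("no complete pairs to fit")
    prev = float(y.mean())
    if prev <= 0.0 or prev >= 1.0:
        raise ValueError(f"trait prevalence is {prev:.0%}; liability model "
                         "requires both cases and controls")
    mz = pairs.is_mz
    p = len(covariates)
    # covariates are centered/scaled internally for conditioning
    xi = [pairs.covariate_names.index(c) for c in covariates]
    x_raw = pairs.x[:, :, xi]
    m, s = _standardizer(x_raw.reshape(2 * len(y), p))
    xs = (x_raw - m) / s

    groups_present = (bool(mz.any()), bool((~mz).any()))
    k_struct = (sum(groups_present) if model_label == "SAT"
                else _N_STRUCT[model_label])

    def negll(theta: np.ndarray) -> float:
        g0 = theta[0]
        gam = theta[1:1 + p]
        struct = theta[1 + p:]
        t = -(g0 + xs @ gam)
        if model_label == "SAT":
            r = np.empty(len(y))
            k = 0
            for g, present in enumerate(groups_present):
                if present:
                    r[mz if g == 0 else ~mz] = math.tanh(struct[k])
                    k += 1
        else:
            r_mz, r_dz = _liability_r(model_label, struct)
            r = np.where(mz, min(r_mz, 1 - 1e-9), r_dz)
        ll = _pair_cell_loglik(y, t, r)
        return -ll if np.isfinite(ll) else 1e10

    # moment-flavoured start: threshold from prevalence, mid-range fractions
    g0_0 = float(_norm.ppf(prev))
    x0 = np.concatenate([[g0_0], np.zeros(p),
                         np.full(k_struct, 0.25 if model_label == "SAT"
                                 else math.asin(math.sqrt(0.5)))])
    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for r_i in range(max(1, n_restarts)):
        start = x0.copy()
        if r_i > 0:
            start += 0.3 * rng.standard_normal(len(start))
        res = optimize.minimize(negll, start, method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        converged = converged or bool(res.success)
    theta = np.asarray(best.x, dtype=float)
    loglik = -float(best.fun)
    n_params = len(theta)

    fit = TwinModelFit(
        model_label=model_label, components=None, mean=None,
        loglik=loglik, n_params=n_params, aic=2.0 * n_params - 2.0 * loglik,
        implied_r_mz=float("nan"), implied_r_dz=float("nan"),
        converged=converged, n_pairs_mz=int(mz.sum()),
        n_pairs_dz=int((~mz).sum()), trait=trait,
    )
    fit._negll = negll
    fit._theta = theta
    fit._data = pairs

    # thresholds back on the original covariate scale
    gam_std = theta[1:1 + p]
    gam = gam_std / s
    g0 = float(theta[0]) - float(np.sum(gam_std * m / s))
    kw = {"gamma0": g0}
    names = {"sex": "gamma_sex", "age": "gamma_age", "height": "gamma_height"}
    for c, gv in zip(covariates, gam):
        kw[names[c]] = float(gv)
    fit.threshold = ThresholdModel(**kw)

    off = 1 + p
    if model_label == "SAT":
        struct = theta[off:]
        rhos, k = [], 0
        for present in groups_present:
            rhos.append(math.tanh(struct[k]) if present else float("nan"))
            if present:
                k += 1
        fit.implied_r_mz, fit.implied_r_dz = rhos
        idx, k = {}, 0
        for g, present in enumerate(groups_present):
            if present:
                idx["r_mz" if g == 0 else "r_dz"] = off + k
                k += 1
        fit._frac_funcs = {key: (lambda th, i=i: math.tanh(th[i]))
                           for key, i in idx.items()}
    else:
        fr = _fracs_from_angles(model_label, theta[off:])
        comp = VarianceComponents(
            a2=fr.get("a", 0.0), d2=fr.get("d", 0.0), c2=fr.get("c", 0.0),
            e2=fr["e"], total_sd=1.0)
        fit.components = comp
        fit.implied_r_mz, fit.implied_r_dz = implied_correlations(comp)
        fit._frac_funcs = _liability_fraction_functions(model_label, off)
        fit._profile = _make_liability_profile(model_label, off, negll)

    if ci_method:
        fit.ci95 = _liability_ci(fit, method=ci_method)
    return fit


def _liability_fraction_functions(model: str, off: int) -> dict:
    names = {"ACE": ("a", "c"), "ADE": ("a", "d"),
             "AE": ("a",), "CE": ("c",)}[model]

    funcs = {}
    for nm in names + ("e",):
        funcs[f"{nm}2"] = (lambda th, nm=nm:
                           _fracs_from_angles(model, np.asarray(th[off:]))[nm])
    funcs["r_mz"] = lambda th: _liability_r(model, np.asarray(th[off:]))[0]
    funcs["r_dz"] = lambda th: _liability_r(model, np.asarray(th[off:]))[1]
    return funcs


def _make_liability_profile(model: str, off: int, negll):
    names = {"ACE": ("a", "c"), "ADE": ("a", "d"),
             "AE": ("a",), "CE": ("c",)}[model]

    def profile(comp: str, f: float, theta_hat: np.ndarray) -> float:
        nm = comp.rstrip("2")
        f = float(np.clip(f, 0.0, 1.0 - 1e-9))
        if nm == "e":          # e2 fixed <=> constrain via complement of rest
            raise ValueError("profile over e2 not supported; use 1 - others")
        j = names.index(nm)

        def constrained(th_red):
            angles = list(th_red[off:])
            # reconstruct the fixed fraction's angle given preceding ones
            fr_before = 1.0
            full_angles = []
            it = iter(angles)
            for jj, _nm in enumerate(names):
                if jj == j:
                    share = f / fr_before if fr_before > 1e-12 else 1.0
                    share = min(max(share, 0.0), 1.0)
                    u = math.asin(math.sqrt(share))
                else:
                    u = next(it)
                full_angles.append(u)
                fr_before -= fr_before * math.sin(u) ** 2
            return negll(np.concatenate([th_red[:off], full_angles]))

        th0 = np.delete(theta_hat, off + j)
        res = optimize.minimize(constrained, th0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        return float(res.fun)

    return profile


def _liability_ci(fit: TwinModelFit, method: str = "delta",
                  level: float = 0.95) -> dict[str, tuple[float, float]]:
    funcs = fit._frac_funcs or {}
    theta = fit._theta
    out: dict[str, tuple[float, float]] = {}
    if method == "delta":
        H = fd_hessian(fit._negll, theta)
        cov = np.linalg.pinv(H)
        z = _norm.ppf(0.5 + level / 2.0)
        for name, g in funcs.items():
            est = g(theta)
            grad = _fd_grad(g, theta)
            se = math.sqrt(max(float(grad @ cov @ grad), 0.0))
            lo, hi = est - z * se, est + z * se
            lim = (0.0, 1.0) if name.endswith("2") else (-1.0, 1.0)
            lo, hi = max(lo, lim[0]), min(hi, lim[1])
            if name.endswith("2") and est < 1e-6:
                lo = 0.0
            out[name] = (float(lo), float(hi))
        return out
    if method == "profile":
        if fit._profile is None:
            raise ValueError("profile intervals unavailable for SAT")
        q = stats.chi2.ppf(level, 1)
        f_min = float(fit._negll(theta))
        for name in [k for k in funcs
                     if k.endswith("2") and not k.startswith("e")]:
            est = funcs[name](theta)

            def dev(f):
                return 2.0 * (fit._profile(name, f, theta) - f_min) - q

            lo = 0.0 if est < 1e-4 or dev(1e-6) < 0 else \
                optimize.brentq(dev, 1e-6, est, xtol=1e-5)
            hi = 1.0 - 1e-6 if dev(1.0 - 1e-6) < 0 else \
                optimize.brentq(dev, est, 1.0 - 1e-6, xtol=1e-5)
            out[name] = (float(lo), float(hi))
        return out
    raise ValueError(f"unknown CI method {method!r}")
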