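"""Biometric variance-component models for continuous twin traits.

The classical twin design decomposes the phenotypic variance into additive
genetic (A), non-additive/dominance genetic (D), shared environmental (C)
and unique environmental (E) sources:

    V_Total = V_A + V_D + V_C + V_E

MZ co-twins share all of A and D and all of C; DZ co-twins share on average
half of A and a quarter of D, so the model-implied twin covariances are

    Cov_MZ = V_A + V_D + V_C
    Cov_DZ = 0.5 V_A + 0.25 V_D + V_C

C and D are not jointly identifiable from twins alone, hence the fitted
families are ACE, ADE and their nested AE / CE / E reductions, compared
against a saturated model with free zygosity-specific moments.  Trait means
carry linear sex/age/height effects.  Fitting is full-information maximum
likelihood on pairs (optionally plus univariate singleton terms), with the
variance structure parameterized by unconstrained path coefficients whose
squares are the variance contributions — nonnegativity is automatic and
boundary solutions (a component estimated at zero) are reachable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .cohort import PairData

MODEL_LABELS = ("SAT", "ACE", "ADE", "AE", "CE", "E")
#: path coefficients estimated per structured model, in order
MODEL_PATHS: dict[str, tuple[str, ...]] = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}


@dataclass(frozen=True)
class VarianceComponents:
    """Standardized variance fractions of a trait or liability.

    ``a2 + d2 + c2 + e2 = 1``; ``total_sd`` is the scale (sigma) in trait
    units, 1.0 for a liability.  At most one of d2/c2 may be nonzero in a
    fitted model (C and D are confounded in twin data).
    """

    a2: float = 0.0
    d2: float = 0.0
    c2: float = 0.0
    e2: float = 1.0
    total_sd: float = 1.0

    def __post_init__(self) -> None:
        fr = (self.a2, self.d2, self.c2, self.e2)
        if any(f < -1e-9 for f in fr):
            raise ValueError(f"negative variance fraction in {fr}")
        if abs(sum(fr) - 1.0) > 1e-8:
            raise ValueError(f"fractions sum to {sum(fr)}, expected 1")
        if self.d2 > 1e-8 and self.c2 > 1e-8:
            raise ValueError("d2 and c2 cannot both be estimated")
        if not self.total_sd > 0:
            raise ValueError("total_sd must be positive")


@dataclass(frozen=True)
class MeanModel:
    """Linear covariate effects on the trait mean, original units."""

    intercept: float = 0.0
    beta_sex: float = 0.0      # male - female
    beta_age: float = 0.0      # per year
    beta_height: float = 0.0   # per cm

    def predict(self, x: np.ndarray,
                covariates: Sequence[str] = ("sex", "age", "height")
                ) -> np.ndarray:
        """Mean for covariate rows ``x`` (last axis in ``covariates`` order)."""
        betas = {"sex": self.beta_sex, "age": self.beta_age,
                 "height": self.beta_height}
        b = np.array([betas[c] for c in covariates])
        return self.intercept + x @ b


def implied_correlations(components: VarianceComponents
                         ) -> tuple[float, float]:
    """Model-implied MZ and DZ twin correlations.

    r_MZ = a2 + d2 + c2 and r_DZ = 0.5 a2 + 0.25 d2 + c2, i.e. the expected
    twin covariances divided by the total variance.
    """
    r_mz = components.a2 + components.d2 + components.c2
    r_dz = 0.5 * components.a2 + 0.25 * components.d2 + components.c2
    return float(r_mz), float(r_dz)


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------

_LOG2PI = math.log(2.0 * math.pi)


def pair_loglik(y, mu, sigma: float, rho) -> np.ndarray | float:
    """Log-density of twin pairs under a symmetric bivariate normal.

    Both members share variance ``sigma**2``; the within-pair correlation
    ``rho`` is the model-implied correlation for the pair's zygosity.
    ``y`` and ``mu`` have trailing dimension 2; symmetric under member
    swap.  ``sigma`` must be positive.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("|rho| must be < 1")
    r = (y - mu) / sigma
    r1, r2 = r[..., 0], r[..., 1]
    omr2 = 1.0 - rho ** 2
    quad = (r1 ** 2 + r2 ** 2 - 2.0 * rho * r1 * r2) / omr2
    ll = -_LOG2PI - 2.0 * math.log(sigma) - 0.5 * np.log(omr2) - 0.5 * quad
    return ll if ll.ndim else float(ll)


def singleton_loglik(y, mu, sigma: float) -> np.ndarray | float:
    """Univariate normal log-density for unpaired subjects."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    r = (np.asarray(y, dtype=float) - mu) / sigma
    ll = -0.5 * _LOG2PI - math.log(sigma) - 0.5 * r ** 2
    return ll if np.ndim(ll) else float(ll)


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class TwinModelFit:
    """A fitted twin model: components, mean model and fit statistics."""

    model_label: str
    components: VarianceComponents | None
    mean: MeanModel | None
    loglik: float
    n_params: int
    aic: float
    implied_r_mz: float
    implied_r_dz: float
    converged: bool
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_pairs_mz: int = 0
    n_pairs_dz: int = 0
    n_singletons: int = 0
    trait: str = ""
    threshold: object = None            # ThresholdModel for liability fits
    # --- private handles used by component_ci / profile refits ---
    _negll: Callable | None = field(default=None, repr=False, compare=False)
    _theta: np.ndarray | None = field(default=None, repr=False, compare=False)
    _frac_funcs: dict | None = field(default=None, repr=False, compare=False)
    _refit: Callable | None = field(default=None, repr=False, compare=False)
    _profile: Callable | None = field(default=None, repr=False, compare=False)
    _data: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        d = {
            "model": self.model_label,
            "trait": self.trait,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "r_mz": self.implied_r_mz,
            "r_dz": self.implied_r_dz,
            "converged": self.converged,
            "n_pairs_mz": self.n_pairs_mz,
            "n_pairs_dz": self.n_pairs_dz,
            "n_singletons": self.n_singletons,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
        }
        if self.components is not None:
            d["components"] = {
                "a2": self.components.a2, "d2": self.components.d2,
                "c2": self.components.c2, "e2": self.components.e2,
                "total_sd": self.components.total_sd,
            }
        if self.mean is not None:
            d["mean"] = {
                "intercept": self.mean.intercept,
                "beta_sex": self.mean.beta_sex,
                "beta_age": self.mean.beta_age,
                "beta_height": self.mean.beta_height,
            }
        if self.threshold is not None:
            t = self.threshold
            d["threshold"] = {
                "gamma0": t.gamma0, "gamma_sex": t.gamma_sex,
                "gamma_age": t.gamma_age, "gamma_height": t.gamma_height,
            }
        return d


# ---------------------------------------------------------------------------
# Numerical helpers
# ---------------------------------------------------------------------------

def fd_hessian(fun: Callable, x: np.ndarray, rel_step: float = 1e-4
               ) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _fd_grad(fun: Callable, x: np.ndarray, rel_step: float = 1e-6
             ) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty(len(x))
    h = rel_step * (1.0 + np.abs(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = h[i]
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h[i])
    return g


def _standardizer(x_all: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs used to condition the design matrix."""
    if x_all.shape[0] == 0 or x_all.shape[1] == 0:
        return (np.zeros(x_all.shape[1]), np.ones(x_all.shape[1]))
    m = x_all.mean(axis=0)
    s = x_all.std(axis=0)
    s[s < 1e-12] = 1.0
    return m, s


def _group_masks(zygosity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mz = zygosity == "MZ"
    return mz, ~mz


# ---------------------------------------------------------------------------
# Continuous model fitting
# ---------------------------------------------------------------------------

def _structured_negll(theta: np.ndarray, model: str, y: np.ndarray,
                      xs: np.ndarray, mz: np.ndarray,
                      ys: np.ndarray | None, xss: np.ndarray | None
                      ) -> float:
    p = xs.shape[2]
    b0 = theta[0]
    beta = theta[1:1 + p]
    paths = theta[1 + p:]
    V = float(np.sum(paths ** 2))
    if not np.isfinite(V) or V < 1e-12:
        return 1e10
    parts = dict(zip(MODEL_PATHS[model], paths ** 2))
    va = parts.get("a", 0.0); vd = parts.get("d", 0.0); vc = parts.get("c", 0.0)
    r_mz = (va + vd + vc) / V
    r_dz = (0.5 * va + 0.25 * vd + vc) / V
    r_mz = min(r_mz, 1.0 - 1e-10)
    rho = np.where(mz, r_mz, r_dz)
    sigma = math.sqrt(V)
    mu = b0 + xs @ beta
    ll = float(np.sum(pair_loglik(y, mu, sigma, rho)))
    if ys is not None and len(ys):
        ll += float(np.sum(singleton_loglik(ys, b0 + xss @ beta, sigma)))
    return -ll if np.isfinite(ll) else 1e10


def _sat_negll(theta: np.ndarray, y: np.ndarray, xs: np.ndarray,
               mz: np.ndarray, groups_present: tuple[bool, bool],
               ys: np.ndarray | None, xss: np.ndarray | None) -> float:
    p = xs.shape[2]
    beta = theta[:p]
    rest = theta[p:]
    ll = 0.0
    k = 0
    for g, present in enumerate(groups_present):      # 0 = MZ, 1 = DZ
        if not present:
            continue
        mu_g, logv_g, w_g = rest[3 * k:3 * k + 3]
        k += 1
        mask = mz if g == 0 else ~mz
        v = math.exp(logv_g)
        rho = math.tanh(w_g)
        mu = mu_g + xs[mask] @ beta
        ll += float(np.sum(pair_loglik(y[mask], mu, math.sqrt(v), rho)))
    if ys is not None and len(ys):
        # singletons share the first present group's mean/variance intercepts
        mu_g, logv_g = rest[0], rest[1]
        ll += float(np.sum(singleton_loglik(
            ys, mu_g + xss @ beta, math.sqrt(math.exp(logv_g)))))
    return -ll if np.isfinite(ll) else 1e10


def _moment_init(y: np.ndarray, xs: np.ndarray, mz: np.ndarray
                 ) -> tuple[np.ndarray, float, float, float, float]:
    """OLS betas, residual variance and raw MZ/DZ residual correlations."""
    n, _, p = xs.shape
    Y = y.reshape(-1)
    X = np.column_stack([np.ones(2 * n), xs.reshape(2 * n, p)])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ coef).reshape(n, 2)
    v0 = max(float(resid.var()), 1e-8)

    def _corr(mask):
        if mask.sum() < 3:
            return 0.3
        r = resid[mask]
        c = np.corrcoef(r[:, 0], r[:, 1])[0, 1]
        return float(np.clip(c, -0.95, 0.98)) if np.isfinite(c) else 0.3

    return coef[1:], float(coef[0]), v0, _corr(mz), _corr(~mz)


def _init_paths(model: str, v0: float, rmz: float, rdz: float) -> np.ndarray:
    rmz = max(rmz, 0.02)
    rdz = max(rdz, 0.01)
    if model == "AE":
        fr = {"a": np.clip(rmz, 0.05, 0.95)}
    elif model == "CE":
        fr = {"c": np.clip((rmz + rdz) / 2, 0.05, 0.95)}
    elif model == "ACE":
        a2 = np.clip(2 * (rmz - rdz), 0.05, 0.9)
        c2 = np.clip(2 * rdz - rmz, 0.02, 0.9 - a2 if a2 < 0.9 else 0.02)
        fr = {"a": a2, "c": max(c2, 0.02)}
    elif model == "ADE":
        a2 = np.clip(4 * rdz - rmz, 0.05, 0.9)
        d2 = np.clip(2 * rmz - 4 * rdz, 0.02, 0.9)
        fr = {"a": a2, "d": max(d2, 0.02)}
    else:  # E
        fr = {}
    used = sum(fr.values())
    fr["e"] = max(1.0 - used, 0.05)
    tot = sum(fr.values())
    return np.array([math.sqrt(fr.get(name, 0.0) / tot * v0)
                     for name in MODEL_PATHS[model]])


def fit_continuous(pairs: PairData,
                   singletons: tuple[np.ndarray, np.ndarray] | None = None,
                   model_label: str = "AE",
                   include_singletons: bool = False,
                   n_restarts: int = 5,
                   seed: int = 0,
                   ci_method: str | None = "delta",
                   trait: str = "") -> TwinModelFit:
    """Maximum-likelihood fit of a twin variance-component model.

    Parameters
    ----------
    pairs : PairData
        Complete twin pairs (trait values, covariates, zygosity).
    singletons : (values, covariates) or None
        Unpaired subjects; contribute univariate normal terms only when
        ``include_singletons`` is set.
    model_label : {"SAT", "ACE", "ADE", "AE", "CE", "E"}
        SAT frees zygosity-specific means, variances and correlations;
        the structured models share a single mean model and scale and
        constrain the correlations through the variance fractions.
    ci_method : {"delta", "profile", "bootstrap", None}
        95% intervals attached to the fit; None skips them.

    Non-convergence after all restarts is flagged (``converged=False``),
    never silent.
    """
    if model_label not in MODEL_LABELS:
        raise ValueError(f"unknown model {model_label!r}")
    y, xs_raw = pairs.y, pairs.x
    n, _, p = xs_raw.shape
    if n == 0:
        raise ValueError("no complete pairs to fit")
    mz, dz = _group_masks(pairs.zygosity)

    x_stack = xs_raw.reshape(2 * n, p)
    ys = xss = None
    if include_singletons and singletons is not None and len(singletons[0]):
        ys, xss_raw = singletons
        x_stack = np.vstack([x_stack, xss_raw])
    m, s = _standardizer(x_stack)
    xs = (xs_raw - m) / s
    if ys is not None:
        xss = (singletons[1] - m) / s

    beta0, b00, v0, rmz0, rdz0 = _moment_init(y, xs, mz)
    rng = np.random.default_rng(seed)

    if model_label == "SAT":
        groups_present = (bool(mz.any()), bool(dz.any()))
        def negll(th): return _sat_negll(th, y, xs, mz, groups_present, ys, xss)
        base = [beta0]
        for g, present in enumerate(groups_present):
            if present:
                r0 = rmz0 if g == 0 else rdz0
                base.append([b00, math.log(v0), math.atanh(np.clip(r0, -0.9, 0.95))])
        x0 = np.concatenate([np.atleast_1d(np.asarray(b, dtype=float))
                             for b in base])
    else:
        def negll(th): return _structured_negll(th, model_label, y, xs, mz, ys, xss)
        x0 = np.concatenate([[b00], beta0,
                             _init_paths(model_label, v0, rmz0, rdz0)])

    best = None
    converged = False
    for r in range(max(1, n_restarts)):
        start = x0.copy()
        if r > 0:
            start = start * (1 + 0.2 * rng.standard_normal(len(start)))
            start += 0.05 * math.sqrt(v0) * rng.standard_normal(len(start))
        res = optimize.minimize(negll, start, method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        converged = converged or bool(res.success)
    theta = np.asarray(best.x, dtype=float)
    loglik = -float(best.fun)
    n_params = len(theta)
    aic = 2.0 * n_params - 2.0 * loglik

    n_singles = int(len(ys)) if ys is not None else 0
    fit = TwinModelFit(
        model_label=model_label, components=None, mean=None,
        loglik=loglik, n_params=n_params, aic=aic,
        implied_r_mz=0.0, implied_r_dz=0.0, converged=converged,
        n_pairs_mz=int(mz.sum()), n_pairs_dz=int(dz.sum()),
        n_singletons=n_singles, trait=trait,
    )
    fit._negll = negll
    fit._theta = theta
    fit._data = pairs

    if model_label == "SAT":
        groups_present = (bool(mz.any()), bool(dz.any()))
        rest = theta[p:]
        rhos = []
        k = 0
        for present in groups_present:
            rhos.append(math.tanh(rest[3 * k + 2]) if present else float("nan"))
            if present:
                k += 1
        fit.implied_r_mz, fit.implied_r_dz = rhos[0], rhos[1]
        beta = theta[:p] / s
        fit.mean = _mean_model(float(rest[0]) - float(np.sum(theta[:p] * m / s)),
                               beta, pairs.covariate_names)
        idx = {}
        k = 0
        for g, present in enumerate(groups_present):
            if present:
                idx["r_mz" if g == 0 else "r_dz"] = p + 3 * k + 2
                k += 1
        fit._frac_funcs = {
            key: (lambda th, i=i: math.tanh(th[i])) for key, i in idx.items()
        }
    else:
        paths = theta[1 + p:]
        V = float(np.sum(paths ** 2))
        parts = dict(zip(MODEL_PATHS[model_label], paths ** 2))
        comp = VarianceComponents(
            a2=parts.get("a", 0.0) / V, d2=parts.get("d", 0.0) / V,
            c2=parts.get("c", 0.0) / V, e2=parts.get("e", 0.0) / V,
            total_sd=math.sqrt(V))
        fit.components = comp
        fit.implied_r_mz, fit.implied_r_dz = implied_correlations(comp)
        beta = theta[1:1 + p] / s
        fit.mean = _mean_model(float(theta[0]) - float(np.sum(theta[1:1 + p] * m / s)),
                               beta, pairs.covariate_names)
        fit._frac_funcs = _fraction_functions(model_label, 1 + p)
        fit._profile = _make_profile(model_label, 1 + p, negll)
        fit._refit = _make_refit(negll, theta)

    if ci_method:
        fit.ci95 = component_ci(fit, method=ci_method, seed=seed)
    return fit


def _mean_model(intercept: float, beta: np.ndarray,
                covariates: Sequence[str]) -> MeanModel:
    kw = {"intercept": intercept}
    names = {"sex": "beta_sex", "age": "beta_age", "height": "beta_height"}
    for c, b in zip(covariates, beta):
        kw[names[c]] = float(b)
    return MeanModel(**kw)


def _fraction_functions(model: str, off: int) -> dict[str, Callable]:
    """Map component name -> function of theta giving its fraction."""
    names = MODEL_PATHS[model]

    def frac(th, j):
        paths = np.asarray(th[off:], dtype=float)
        return float(paths[j] ** 2 / np.sum(paths ** 2))

    funcs = {}
    for j, nm in enumerate(names):
        funcs[f"{nm}2"] = (lambda th, j=j: frac(th, j))

    def _r(th, which):
        paths = np.asarray(th[off:], dtype=float)
        V = float(np.sum(paths ** 2))
        parts = dict(zip(names, paths ** 2))
        va, vd, vc = (parts.get(k, 0.0) for k in ("a", "d", "c"))
        if which == "mz":
            return (va + vd + vc) / V
        return (0.5 * va + 0.25 * vd + vc) / V

    funcs["r_mz"] = lambda th: _r(th, "mz")
    funcs["r_dz"] = lambda th: _r(th, "dz")
    return funcs


def _make_profile(model: str, off: int, negll: Callable) -> Callable:
    """Constrained optimizer: minimum negll with one fraction fixed."""
    names = MODEL_PATHS[model]

    def profile(comp: str, f: float, theta_hat: np.ndarray) -> float:
        j = names.index(comp.rstrip("2"))
        f = float(np.clip(f, 0.0, 1.0 - 1e-9))

        def constrained(th_red):
            others = np.asarray(th_red[off:], dtype=float)
            V_others = float(np.sum(others ** 2))
            if V_others < 1e-12:
                return 1e10
            pj = math.sqrt(f / (1.0 - f) * V_others)
            paths = np.insert(others, j, pj)
            return negll(np.concatenate([th_red[:off], paths]))

        th0 = np.delete(theta_hat, off + j)
        res = optimize.minimize(constrained, th0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        return float(res.fun)

    return profile


def _make_refit(negll: Callable, theta_hat: np.ndarray) -> Callable:
    def refit(new_negll: Callable) -> tuple[np.ndarray, float]:
        res = optimize.minimize(new_negll, theta_hat, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        return np.asarray(res.x), float(res.fun)
    return refit


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def component_ci(fit: TwinModelFit, method: str = "delta",
                 level: float = 0.95, n_boot: int = 200,
                 seed: int = 0) -> dict[str, tuple[float, float]]:
    """95% (by default) intervals for variance fractions and implied
    correlations of a fitted model.

    delta
        Normal-theory intervals from the inverse observed information,
        truncated to [0, 1]; at a boundary estimate (fraction 0) the
        interval is one-sided from 0.
    profile
        Inverts the likelihood-ratio statistic at the chi-square(1)
        quantile, searching each side of the estimate.
    bootstrap
        Percentile intervals from resampling pairs within zygosity.
    """
    if fit._negll is None or fit._theta is None:
        raise ValueError("fit carries no likelihood handle")
    funcs = fit._frac_funcs or {}
    theta = fit._theta
    z = stats.norm.ppf(0.5 + level / 2.0)
    out: dict[str, tuple[float, float]] = {}

    if method == "delta":
        H = fd_hessian(fit._negll, theta)
        cov = np.linalg.pinv(H)
        for name, g in funcs.items():
            est = g(theta)
            grad = _fd_grad(g, theta)
            var = float(grad @ cov @ grad)
            se = math.sqrt(max(var, 0.0))
            lo, hi = est - z * se, est + z * se
            if name.endswith("2"):
                lo, hi = max(lo, 0.0), min(hi, 1.0)
                if est < 1e-6:
                    lo = 0.0
            else:
                lo, hi = max(lo, -1.0), min(hi, 1.0)
            out[name] = (float(lo), float(hi))
        return out

    if method == "profile":
        if fit._profile is None:
            raise ValueError("profile intervals unavailable for this model")
        q = stats.chi2.ppf(level, 1)
        f_min = float(fit._negll(theta))
        for name in [k for k in funcs if k.endswith("2")]:
            est = funcs[name](theta)

            def dev(f):
                return 2.0 * (fit._profile(name, f, theta) - f_min) - q

            lo = 0.0 if est < 1e-4 or dev(max(est * 0.05, 1e-6)) < 0 \
                else optimize.brentq(dev, max(est * 0.05, 1e-6), est, xtol=1e-5)
            hi_bound = 1.0 - 1e-6
            hi = hi_bound if dev(hi_bound) < 0 \
                else optimize.brentq(dev, est, hi_bound, xtol=1e-5)
            out[name] = (float(lo), float(min(hi, 1.0)))
        return out

    if method == "bootstrap":
        pairs = fit._data
        if pairs is None:
            raise ValueError("bootstrap requires the fitting data")
        rng = np.random.default_rng(seed)
        mz_idx = np.flatnonzero(pairs.is_mz)
        dz_idx = np.flatnonzero(~pairs.is_mz)
        samples: dict[str, list[float]] = {k: [] for k in funcs}
        for _ in range(n_boot):
            take = np.concatenate([
                rng.choice(mz_idx, size=len(mz_idx), replace=True)
                if len(mz_idx) else np.array([], dtype=int),
                rng.choice(dz_idx, size=len(dz_idx), replace=True)
                if len(dz_idx) else np.array([], dtype=int)])
            sub = pairs.subset(take)
            try:
                bfit = fit_continuous(sub, model_label=fit.model_label,
                                      n_restarts=1, seed=seed, ci_method=None)
            except (ValueError, np.linalg.LinAlgError):
                continue
            for k, g in (bfit._frac_funcs or {}).items():
                if k in samples:
                    samples[k].append(g(bfit._theta))
        alpha = (1.0 - level) / 2.0
        for k, vals in samples.items():
            if vals:
                out[k] = (float(np.quantile(vals, alpha)),
                          float(np.quantile(vals, 1 - alpha)))
        return out

    raise ValueError(f"unknown CI method {method!r}")
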