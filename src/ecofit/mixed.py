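"""Mixed-model machinery.

:class:`BinomialMixedModel` fits a Bernoulli GLMM with independent
random intercepts for one or more (possibly crossed) grouping factors by
Laplace-approximated maximum likelihood:

* inner loop — penalized IRLS jointly over the fixed effects beta and the
  spherical random effects u (b_k = sd_k * u_k), maximising
  ``sum_i [y_i eta_i - log(1 + exp eta_i)] - ||u||^2 / 2``;
* Laplace log-likelihood at the conditional mode,
  ``f(beta_hat, u_hat) - 0.5 * logdet(L' W L + I)`` with ``L = Z Lambda``;
* outer loop — bounded Nelder-Mead over the random-effect SDs.

Wald standard errors for beta come from the beta block of the inverse
penalized Fisher information at the mode (the same conditional-on-theta
covariance lme4 reports). Setting an SD to zero exactly reproduces a plain
binomial GLM, which is both the degenerate-variance behaviour and a tested
limit identity.

``satterthwaite_df`` supplies approximate denominator degrees of freedom
for gaussian linear mixed models (REML), via a Woodbury-based restricted
likelihood and finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

_MAX_ABS_COEF = 50.0  # beyond this on the logit scale: flag likely separation


def _expand_groups(labels) -> tuple[np.ndarray, list]:
    levels, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes, list(levels)


@dataclass
class MixedFit:
    """Result of a binomial GLMM fit."""

    params: np.ndarray
    se: np.ndarray
    xnames: list
    sd_estimates: dict
    loglik: float
    n_obs: int
    n_groups: dict
    converged: bool
    note: str = ""
    random_modes: dict = field(default_factory=dict)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        h = norm.ppf(1 - alpha / 2) * self.se
        return np.column_stack([self.params - h, self.params + h])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.xnames,
            "estimate": self.params,
            "se": self.se,
            "statistic": self.zvalues,
            "p_value": self.pvalues,
        })


class BinomialMixedModel:
    """Bernoulli GLMM with random intercepts per grouping factor.

    Parameters
    ----------
    y : array of 0/1 responses
    X : (n, p) fixed-effects design (include the intercept column)
    groups : mapping factor name -> length-n label array
    xnames : names for the columns of X
    """

    def __init__(self, y, X, groups: dict, xnames=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one row per response")
        if not np.isin(self.y, [0.0, 1.0]).all():
            raise ValueError("binomial responses must be 0/1")
        sd = self.X.std(axis=0)
        const_like = (sd == 0) & (self.X[0] != 1.0)
        nontrivial = (sd == 0).sum() > 1 or const_like.any()
        if nontrivial:
            raise ValueError("constant predictor column in X (only an "
                             "intercept column may be constant)")
        self.xnames = list(xnames) if xnames is not None else [
            f"x{i}" for i in range(self.X.shape[1])]
        self.group_names = list(groups)
        self.codes, self.levels = {}, {}
        for name, labels in groups.items():
            codes, levels = _expand_groups(labels)
            if len(labels) != self.y.size:
                raise ValueError(f"group {name!r} has wrong length")
            self.codes[name] = codes
            self.levels[name] = levels
        self.p = self.X.shape[1]
        self.q_sizes = [len(self.levels[g]) for g in self.group_names]
        self.q = int(sum(self.q_sizes))
        # sparse-free Z: n x q block indicator matrix
        n = self.y.size
        Z = np.zeros((n, self.q))
        off = 0
        for g, qk in zip(self.group_names, self.q_sizes):
            Z[np.arange(n), off + self.codes[g]] = 1.0
            off += qk
        self.Z = Z

    # ---------------------------------------------------------- internals

    def _pirls(self, sds, beta, u, maxiter=100, tol=1e-10):
        """Penalized IRLS over (beta, u) for fixed random-effect SDs."""
        lam = np.concatenate([
            np.full(qk, s) for s, qk in zip(sds, self.q_sizes)
        ]) if self.q else np.zeros(0)
        L = self.Z * lam  # Z Lambda
        A = np.hstack([self.X, L])
        pen = np.concatenate([np.zeros(self.p), np.ones(self.q)])
        theta = np.concatenate([beta, u])
        obj_prev = -np.inf
        ok = False
        for _ in range(maxiter):
            eta = A @ theta
            mu = expit(eta)
            obj = float(self.y @ eta - np.logaddexp(0.0, eta).sum()
                        - 0.5 * theta[self.p:] @ theta[self.p:])
            if abs(obj - obj_prev) < tol * (1 + abs(obj)):
                ok = True
                break
            obj_prev = obj
            w = np.clip(mu * (1 - mu), 1e-10, None)
            M = (A * w[:, None]).T @ A + np.diag(pen)
            g = A.T @ (self.y - mu) - pen * theta
            try:
                step = np.linalg.solve(M, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(M, g, rcond=None)[0]
            # halving line search on the penalized objective
            for _ in range(30):
                cand = theta + step
                eta_c = A @ cand
                obj_c = float(self.y @ eta_c - np.logaddexp(0.0, eta_c).sum()
                              - 0.5 * cand[self.p:] @ cand[self.p:])
                if obj_c >= obj - 1e-12:
                    break
                step *= 0.5
            theta = theta + step
        eta = A @ theta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        obj = float(self.y @ eta - np.logaddexp(0.0, eta).sum()
                    - 0.5 * theta[self.p:] @ theta[self.p:])
        S = (L * w[:, None]).T @ L + np.eye(self.q)
        sign, logdet = np.linalg.slogdet(S)
        ll = obj - 0.5 * logdet
        return theta[:self.p], theta[self.p:], ll, ok, (A, w, pen)

    def _laplace_ll(self, sds, state):
        beta, u, ll, ok, _ = self._pirls(sds, state["beta"], state["u"])
        state["beta"], state["u"] = beta, u
        return ll

    # ---------------------------------------------------------------- fit

    def fit(self, fix_sd: dict | None = None, start_sd: float = 0.5,
            sd_bound: float = 10.0) -> MixedFit:
        """Maximise the Laplace likelihood.

        ``fix_sd`` maps factor names to fixed SD values (e.g. 0.0 to force
        the plain-GLM limit); the remaining SDs are optimised.
        """
        fix_sd = dict(fix_sd or {})
        unknown = set(fix_sd) - set(self.group_names)
        if unknown:
            raise ValueError(f"fix_sd names not among groups: {sorted(unknown)}")
        free_idx = [i for i, g in enumerate(self.group_names) if g not in fix_sd]
        sds = np.array([fix_sd.get(g, start_sd) for g in self.group_names])

        # start beta at the GLM solution (sd=0)
        state = {"beta": np.zeros(self.p), "u": np.zeros(self.q)}
        beta0, _, _, _, _ = self._pirls(np.zeros(len(sds)), state["beta"],
                                        state["u"])
        state["beta"] = beta0

        outer_ok = True
        if free_idx:
            def negll(free_sds):
                s = sds.copy()
                s[free_idx] = free_sds
                return -self._laplace_ll(s, state)

            res = optimize.minimize(
                negll, x0=sds[free_idx], method="Nelder-Mead",
                bounds=[(0.0, sd_bound)] * len(free_idx),
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
            sds[free_idx] = res.x
            outer_ok = bool(res.success)

        beta, u, ll, inner_ok, (A, w, pen) = self._pirls(
            sds, state["beta"], state["u"])
        M = (A * w[:, None]).T @ A + np.diag(pen)
        try:
            C = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            C = np.linalg.pinv(M)
        se = np.sqrt(np.clip(np.diag(C)[:self.p], 0, None))

        note = ""
        converged = inner_ok and outer_ok
        if np.max(np.abs(beta)) > _MAX_ABS_COEF:
            converged = False
            note = "possible separation: |estimate| very large"
        if not converged and not note:
            note = "optimizer did not report convergence"

        modes, off = {}, 0
        for g, qk, s in zip(self.group_names, self.q_sizes, sds):
            modes[g] = dict(zip(self.levels[g], s * u[off:off + qk]))
            off += qk
        return MixedFit(
            params=beta, se=se, xnames=self.xnames,
            sd_estimates=dict(zip(self.group_names, sds.tolist())),
            loglik=ll, n_obs=self.y.size,
            n_groups={g: len(self.levels[g]) for g in self.group_names},
            converged=converged, note=note, random_modes=modes)


# ------------------------------------------------------------ gaussian df

def _reml_pieces(y, X, Z_list, var_comps, var_resid):
    """Woodbury-based REML quantities for V = s2 I + sum vk Zk Zk'."""
    n, p = X.shape
    active = [(Z, v) for Z, v in zip(Z_list, var_comps) if v > 0]
    s2 = float(var_resid)
    if not active:
        Vi_X = X / s2
        Vi_y = y / s2
        logdetV = n * np.log(s2)
    else:
        Z = np.hstack([Z for Z, _ in active])
        d = np.concatenate([np.full(Z_.shape[1], v) for Z_, v in active])
        K = Z.T @ Z
        inner = np.diag(s2 / d) + K
        inner_inv = np.linalg.inv(inner)
        def Vi(M):
            return (M - Z @ (inner_inv @ (Z.T @ M))) / s2
        Vi_X = Vi(X)
        Vi_y = Vi(y)
        sign, ld = np.linalg.slogdet(np.eye(len(d)) + (K * d[None, :]) / s2)
        logdetV = n * np.log(s2) + ld
    XtViX = X.T @ Vi_X
    C = np.linalg.inv(XtViX)
    beta = C @ (X.T @ Vi_y)
    r = y - X @ beta
    if not active:
        Vi_r = r / s2
    else:
        Vi_r = (r - Z @ (inner_inv @ (Z.T @ r))) / s2
    sign2, ld2 = np.linalg.slogdet(XtViX)
    reml = -0.5 * (logdetV + ld2 + float(r @ Vi_r))
    return C, beta, reml


def reml_refine(y, X, Z_list, var_comps, var_resid):
    """Polish a gaussian-LMM variance estimate on the restricted likelihood.

    Nelder-Mead on the Woodbury REML evaluator, started from the supplied
    variances (typically a statsmodels MixedLM fit, whose default optimizer
    can stall short of the optimum on crossed variance-component
    structures). Returns ``(var_comps, var_resid, beta, se, reml)`` at the
    refined optimum; beta and its SEs are the GLS solution there.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    theta0 = np.array(list(var_comps) + [var_resid], dtype=float)

    def negreml(th):
        if th[-1] <= 0 or np.any(th[:-1] < 0):
            return np.inf
        return -_reml_pieces(y, X, Z_list, th[:-1], th[-1])[2]

    res = optimize.minimize(negreml, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10,
                                     "maxiter": 2000})
    theta = res.x if res.fun <= negreml(theta0) else theta0
    C, beta, reml = _reml_pieces(y, X, Z_list, theta[:-1], theta[-1])
    se = np.sqrt(np.diag(C))
    return theta[:-1], theta[-1], beta, se, reml


def satterthwaite_df(y, X, Z_list, var_comps, var_resid):
    """Satterthwaite denominator df for each fixed-effect coefficient.

    ``Z_list`` holds one 0/1 indicator matrix per random-intercept factor;
    ``var_comps`` are their variances and ``var_resid`` the residual
    variance, all on the variance (not SD) scale, typically taken from a
    fitted REML model. Returns an array of df (NaN where the approximation
    is unusable, e.g. variance estimates on the boundary).
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    theta = np.array(list(var_comps) + [var_resid], dtype=float)
    p = X.shape[1]
    m = len(theta)

    def var_beta(th):
        C, _, _ = _reml_pieces(y, X, Z_list, th[:-1], th[-1])
        return np.diag(C)

    def reml(th):
        if th[-1] <= 0 or np.any(th[:-1] < 0):
            return -np.inf
        return _reml_pieces(y, X, Z_list, th[:-1], th[-1])[2]

    steps = np.maximum(np.abs(theta) * 1e-3, 1e-8)
    # gradient of Var(beta_j) wrt theta (forward differences keep theta >= 0)
    G = np.zeros((p, m))
    v0 = var_beta(theta)
    for k in range(m):
        e = np.zeros(m)
        e[k] = steps[k]
        G[:, k] = (var_beta(theta + e) - v0) / steps[k]
    # covariance of theta_hat: inverse negative Hessian of the REML loglik
    H = np.zeros((m, m))
    hsteps = np.maximum(np.abs(theta) * 1e-2, 1e-6)
    f0 = reml(theta)
    for k in range(m):
        for l in range(k, m):
            ek = np.zeros(m); ek[k] = hsteps[k]
            el = np.zeros(m); el[l] = hsteps[l]
            fpp = reml(theta + ek + el)
            fpm = reml(theta + ek)
            fmp = reml(theta + el)
            H[k, l] = H[l, k] = (fpp - fpm - fmp + f0) / (hsteps[k] * hsteps[l])
    out = np.full(p, np.nan)
    try:
        Acov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return out
    if not np.all(np.isfinite(Acov)):
        return out
    for j in range(p):
        denom = float(G[j] @ Acov @ G[j])
        if denom > 0:
            df = 2.0 * v0[j] ** 2 / denom
            if np.isfinite(df) and df > 0:
                out[j] = df
    return out


def indicator_matrix(labels) -> np.ndarray:
    """Dense 0/1 random-intercept design for one grouping factor."""
    codes, levels = _expand_groups(labels)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z
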