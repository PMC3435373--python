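"""Binomial random-intercept GLMMs and AIC multimodel inference.

The mixed model is a logistic regression with one Gaussian random
intercept per individual,

    logit P(y_ij = 1) = x_ij' beta + sigma * u_i,    u_i ~ N(0, 1),

fitted by maximum likelihood.  The marginal likelihood integrates the
random effect out per group; the integral is approximated either by the
Laplace method (default) or by adaptive Gauss-Hermite quadrature (>= 10
nodes, the high-accuracy mode).  Estimation is ML throughout because AIC
comparisons span models with different fixed effects.

AIC counts the random-intercept variance as one parameter:
k = (fixed effects incl. intercept) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "ModelFit",
    "BinomialRandomInterceptGLMM",
    "GLMMConvergenceError",
    "fit_binomial_glmm",
    "aic_table",
    "model_average",
    "forward_select",
    "correlogram",
    "predict_probability",
]

INTERCEPT = "(intercept)"


class GLMMConvergenceError(RuntimeError):
    """Optimizer failed; carries the scipy iteration trace message."""


@dataclass
class ModelFit:
    """One fitted binomial GLMM: terms, estimates, fit statistics."""

    terms: list  # incl. "(intercept)" first
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    sigma: float  # random-intercept SD
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    method: str
    converged: bool = True
    separation_flags: list = field(default_factory=list)

    @property
    def spec(self) -> str:
        fixed = [t for t in self.terms if t != INTERCEPT]
        return "+".join(fixed) if fixed else "null"

    @property
    def random_intercept_variance(self) -> float:
        return self.sigma**2

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "beta": self.beta, "se": self.se, "p_value": self.p_values}
        )


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes, len(uniques)


class BinomialRandomInterceptGLMM(BaseEstimator):
    """Sklearn-style estimator for the random-intercept logistic model.

    Parameters
    ----------
    method : {"laplace", "agq"}
        Integral approximation; "agq" is adaptive Gauss-Hermite quadrature
        centered and scaled at the per-group posterior mode.
    n_quad : int
        Quadrature nodes for ``method="agq"`` (>= 10 recommended).

    After ``fit(X, y, groups)``:

    - ``coef_`` fixed-effect slopes, ``intercept_`` the intercept,
    - ``sigma_`` random-intercept SD, ``loglik_``, ``aic_``,
    - ``se_`` Wald standard errors for (intercept, slopes).
    """

    def __init__(
        self,
        method: str = "laplace",
        n_quad: int = 15,
        max_iter: int = 200,
        fix_sigma: float | None = None,
    ):
        self.method = method
        self.n_quad = n_quad
        self.max_iter = max_iter
        self.fix_sigma = fix_sigma

    # -- marginal log-likelihood -------------------------------------------

    def _posterior_modes(self, eta0, y, codes, n_groups, sigma):
        """Newton mode-finding for all group effects simultaneously."""
        u = np.zeros(n_groups)
        for _ in range(50):
            eta = eta0 + sigma * u[codes]
            p = expit(eta)
            grad = sigma * np.bincount(codes, weights=y - p, minlength=n_groups) - u
            w = np.bincount(codes, weights=p * (1 - p), minlength=n_groups)
            hess = sigma**2 * w + 1.0
            step = grad / hess
            u = u + step
            if np.max(np.abs(grad)) < 1e-10:
                break
        eta = eta0 + sigma * u[codes]
        p = expit(eta)
        w = np.bincount(codes, weights=p * (1 - p), minlength=n_groups)
        h = sigma**2 * w + 1.0
        return u, h

    def _loglik(self, beta, sigma, X, y, codes, n_groups):
        eta0 = X @ beta
        if sigma < 1e-10:
            return float(np.sum(y * log_expit(eta0) + (1 - y) * log_expit(-eta0)))
        u, h = self._posterior_modes(eta0, y, codes, n_groups, sigma)

        def data_ll_by_group(uvec):
            eta = eta0 + sigma * uvec[codes]
            ll = y * log_expit(eta) + (1 - y) * log_expit(-eta)
            return np.bincount(codes, weights=ll, minlength=n_groups)

        if self.method == "laplace":
            ll_g = data_ll_by_group(u) - 0.5 * u**2 - 0.5 * np.log(h)
            return float(ll_g.sum())
        if self.method == "agq":
            nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)
            tau = 1.0 / np.sqrt(h)
            terms = np.empty((self.n_quad, n_groups))
            for j, (xj, wj) in enumerate(zip(nodes, weights)):
                uj = u + np.sqrt(2.0) * tau * xj
                terms[j] = (
                    np.log(wj)
                    + xj**2
                    + data_ll_by_group(uj)
                    - 0.5 * uj**2
                    - 0.5 * np.log(2 * np.pi)
                )
            ll_g = np.log(np.sqrt(2.0) * tau) + logsumexp(terms, axis=0)
            return float(ll_g.sum())
        raise ValueError(f"unknown method {self.method!r}")

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("response must be binary 0/1")
        codes, n_groups = _group_codes(groups)
        if n_groups < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        n, p = X.shape
        if p and np.any(X.std(axis=0) == 0):
            raise ValueError("a fixed-effect term has zero variance")
        # standardize columns for optimizer conditioning; back-transform after
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = np.column_stack([np.ones(n), (X - mu) / sd])

        def nll(theta):
            return -self._loglik(theta[:-1], theta[-1], Xs, y, codes, n_groups)

        theta0 = np.zeros(p + 2)
        theta0[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
        theta0[-1] = 0.5 if self.fix_sigma is None else self.fix_sigma
        sigma_bound = (0.0, None) if self.fix_sigma is None else (self.fix_sigma,) * 2
        bounds = [(None, None)] * (p + 1) + [sigma_bound]
        res = minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if not res.success and "ABNORMAL" in str(res.message):
            # line-search breakdown: restart from another point, then fall
            # back to a derivative-free pass before giving up
            alt = theta0.copy()
            alt[-1] = 0.1 if self.fix_sigma is None else self.fix_sigma
            retry = minimize(
                nll, alt, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": 1e-9, "gtol": 1e-6},
            )
            if retry.fun <= res.fun:
                res = retry
            if not res.success and "ABNORMAL" in str(res.message):
                powell = minimize(
                    nll, res.x, method="Powell", bounds=bounds,
                    options={"maxiter": 10_000, "xtol": 1e-8, "ftol": 1e-10},
                )
                if powell.fun <= res.fun + 1e-9:
                    res = powell
            if not res.success:
                raise GLMMConvergenceError(
                    f"GLMM did not converge: {res.message} (nit={res.nit})"
                )
        theta = res.x
        ll = -res.fun

        # covariance of (intercept, slopes, sigma) on the standardized scale
        cov_s = self._wald_cov(nll, theta, drop_last=self.fix_sigma is not None)
        # back-transform: beta_j = beta_sj / sd_j ; beta_0 = beta_s0 - sum beta_sj mu_j/sd_j
        J = np.zeros((p + 1, p + 1))
        J[0, 0] = 1.0
        for j in range(p):
            J[0, j + 1] = -mu[j] / sd[j]
            J[j + 1, j + 1] = 1.0 / sd[j]
        beta_s = theta[: p + 1]
        beta = np.empty(p + 1)
        beta[1:] = beta_s[1:] / sd
        beta[0] = beta_s[0] - np.sum(beta_s[1:] * mu / sd)
        cov = J @ cov_s[: p + 1, : p + 1] @ J.T if cov_s is not None else None
        if cov is not None:
            d = np.diag(cov)
            se = np.where(d > 0, np.sqrt(np.where(d > 0, d, 1.0)), np.nan)
        else:
            se = np.full(p + 1, np.nan)

        self.intercept_ = beta[0]
        self.coef_ = beta[1:]
        self.beta_ = beta
        self.se_ = se
        self.sigma_ = float(theta[-1])
        self.loglik_ = ll
        # fixed effects incl. intercept + the variance when estimated
        self.n_params_ = p + 1 + (1 if self.fix_sigma is None else 0)
        self.aic_ = -2 * ll + 2 * self.n_params_
        self.n_obs_ = n
        self.n_groups_ = n_groups
        self.converged_ = bool(res.success)
        return self

    @staticmethod
    def _wald_cov(nll, theta, h: float = 1e-4, drop_last: bool = False):
        """Observed-information covariance by central finite differences."""
        k = len(theta)
        H = np.empty((k, k))
        hs = h * np.maximum(1.0, np.abs(theta))
        f0 = nll(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = hs[i]
                ej[j] = hs[j]
                if i == j:
                    lo = theta - ei
                    lo[-1] = max(lo[-1], 0.0)
                    H[i, i] = (nll(theta + ei) - 2 * f0 + nll(lo)) / (hs[i] ** 2)
                else:
                    tpp = theta + ei + ej
                    tpm = theta + ei - ej
                    tmp = theta - ei + ej
                    tmm = theta - ei - ej
                    for t in (tpm, tmp, tmm):
                        t[-1] = max(t[-1], 0.0)
                    H[i, j] = H[j, i] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (
                        4 * hs[i] * hs[j]
                    )
        try:
            if drop_last or theta[-1] < 1e-6:
                # sigma fixed or at the boundary: drop its row/col before inverting
                cov = np.full((k, k), np.nan)
                cov[:-1, :-1] = np.linalg.inv(H[:-1, :-1])
                return cov
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None

    def predict_proba_fixed(self, X):
        """P(y=1) at random effect 0."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return expit(self.intercept_ + X @ self.coef_)


# ---------------------------------------------------------------------------
# ModelFit-level interface
# ---------------------------------------------------------------------------


def fit_binomial_glmm(
    design_table: pd.DataFrame,
    fixed_terms: list,
    response: str = "response",
    group: str = "individual",
    method: str = "laplace",
    n_quad: int = 15,
    fix_sigma: float | None = None,
) -> ModelFit:
    """Fit a binomial random-intercept GLMM on named design-table columns.

    ``fixed_terms=[]`` fits the null model (intercept + random intercept);
    ``fix_sigma=0.0`` pins the random-intercept SD, collapsing the model to
    plain logistic regression.
    """
    fixed_terms = list(fixed_terms)
    missing = [t for t in fixed_terms if t not in design_table.columns]
    if missing:
        raise KeyError(f"terms not in design table: {missing}")
    X = design_table[fixed_terms].to_numpy(dtype=float) if fixed_terms else np.empty(
        (len(design_table), 0)
    )
    y = design_table[response].to_numpy(dtype=float)
    est = BinomialRandomInterceptGLMM(
        method=method, n_quad=n_quad, fix_sigma=fix_sigma
    ).fit(X, y, design_table[group].to_numpy())
    z = est.beta_ / est.se_
    p_values = 2 * norm.sf(np.abs(z))
    separation = [
        t for t, b in zip(fixed_terms, est.coef_) if abs(b) > 15.0
    ]
    return ModelFit(
        terms=[INTERCEPT] + fixed_terms,
        beta=est.beta_,
        se=est.se_,
        p_values=p_values,
        sigma=est.sigma_,
        loglik=est.loglik_,
        aic=est.aic_,
        n_obs=est.n_obs_,
        n_groups=est.n_groups_,
        method=method,
        converged=est.converged_,
        separation_flags=separation,
    )


def aic_table(fits: list) -> pd.DataFrame:
    """Rank fitted models by AIC with Akaike weights.

    ``delta_aic_i = aic_i - min(aic)``;
    ``weight_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)``.
    Accepts ModelFit objects or (spec, aic) pairs.
    """
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        if isinstance(f, ModelFit):
            rows.append((f.spec, f.aic))
        else:
            rows.append((str(f[0]), float(f[1])))
    tab = pd.DataFrame(rows, columns=["model", "aic"])
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    w = np.exp(-tab["delta_aic"] / 2.0)
    tab["weight"] = w / w.sum()
    return tab.sort_values("aic", kind="stable").reset_index(drop=True)


def model_average(fits: list, delta_max: float = 2.0) -> pd.DataFrame:
    """Akaike-weight average of the supported model set (delta AIC <= delta_max).

    Weights are renormalized over the supported set; a term absent from a
    model contributes 0 there (zero-substitution averaging).  The averaged
    SE uses the unconditional-variance estimator
    ``se_avg = sum_i w_i * sqrt(se_i^2 + (beta_i - beta_avg)^2)``.
    """
    fits = [f for f in fits if isinstance(f, ModelFit)]
    if not fits:
        raise ValueError("need at least one ModelFit")
    aics = np.array([f.aic for f in fits])
    keep = aics - aics.min() <= delta_max
    sel = [f for f, k in zip(fits, keep) if k]
    w = np.exp(-(aics[keep] - aics.min()) / 2.0)
    w = w / w.sum()
    terms: list = []
    for f in sel:
        for t in f.terms:
            if t not in terms:
                terms.append(t)
    beta_avg, se_avg = [], []
    for t in terms:
        b = np.array([f.beta[f.terms.index(t)] if t in f.terms else 0.0 for f in sel])
        s = np.array([f.se[f.terms.index(t)] if t in f.terms else 0.0 for f in sel])
        bb = float(np.sum(w * b))
        beta_avg.append(bb)
        se_avg.append(float(np.sum(w * np.sqrt(s**2 + (b - bb) ** 2))))
    return pd.DataFrame({"term": terms, "beta": beta_avg, "se": se_avg})


def forward_select(
    design: pd.DataFrame,
    candidate_vars: list,
    response: str = "response",
    group: str = "individual",
    corr_threshold: float = 0.5,
    method: str = "laplace",
):
    """Forward AIC selection with a pairwise-correlation screen.

    Starting from the null model, at each step the variable giving the
    lowest AIC enters if it improves on the current AIC.  Two variables
    with |Pearson r| > ``corr_threshold`` never share a model: when a
    candidate collides with an included variable, whichever of the pair
    correlates more strongly with the response is kept and the other is
    dropped/skipped.

    Returns (path, best_fit); the path is a list of (terms, aic) visited.
    """
    missing = [v for v in candidate_vars if v not in design.columns]
    if missing:
        raise KeyError(f"candidates not in design: {missing}")
    yv = design[response].to_numpy(dtype=float)

    def r_with_response(v):
        x = design[v].to_numpy(dtype=float)
        if x.std() == 0 or yv.std() == 0:
            return 0.0
        return abs(np.corrcoef(x, yv)[0, 1])

    def r_between(a, b):
        x, z = design[a].to_numpy(float), design[b].to_numpy(float)
        if x.std() == 0 or z.std() == 0:
            return 0.0
        return abs(np.corrcoef(x, z)[0, 1])

    current: list = []
    best = fit_binomial_glmm(design, current, response, group, method)
    path = [(list(current), best.aic)]
    remaining = list(candidate_vars)
    while remaining:
        trials = []
        for v in remaining:
            collide = [u for u in current if r_between(u, v) > corr_threshold]
            if collide:
                u = max(collide, key=r_with_response)
                if r_with_response(v) <= r_with_response(u):
                    continue  # v loses the screen, ineligible
                terms = [t for t in current if t not in collide] + [v]
            else:
                terms = current + [v]
            try:
                f = fit_binomial_glmm(design, terms, response, group, method)
            except (GLMMConvergenceError, ValueError):
                continue
            trials.append((v, terms, f))
        if not trials:
            break
        v, terms, f = min(trials, key=lambda t: t[2].aic)
        if f.aic < best.aic:
            current, best = terms, f
            remaining.remove(v)
            path.append((list(current), best.aic))
        else:
            break
    return path, best


def correlogram(
    residuals,
    coords,
    n_bins: int = 10,
    n_perm: int = 199,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Distance-binned Moran autocorrelation with a permutation envelope.

    A binned stand-in for a spline correlogram: pairwise products of
    centered residuals are averaged within distance bins and scaled by the
    residual variance; the null envelope comes from ``n_perm`` random
    relabelings of residuals over locations.  The envelope is simultaneous
    across bins (studentized max-deviation over the permutation ensemble),
    so under the null the whole observed curve stays inside with
    probability ~``1 - alpha``.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    if len(z) < 30:
        raise ValueError("need at least 30 residuals")
    if z.std() == 0:
        raise ValueError("residuals are constant; autocorrelation undefined")
    from scipy.spatial.distance import pdist

    d = pdist(xy)
    iu = np.triu_indices(len(z), k=1)
    zc = z - z.mean()
    edges = np.linspace(0, d.max() / 2.0, n_bins + 1)
    which = np.digitize(d, edges) - 1
    valid = (which >= 0) & (which < n_bins)

    def moran_by_bin(zz):
        prod = zz[iu[0]] * zz[iu[1]]
        num = np.bincount(which[valid], weights=prod[valid], minlength=n_bins)
        cnt = np.bincount(which[valid], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, num / cnt, np.nan) / zz.var()

    obs = moran_by_bin(zc)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_bins))
    for b in range(n_perm):
        null[b] = moran_by_bin(rng.permutation(zc))
    mu = np.nanmean(null, axis=0)
    sd = np.nanstd(null, axis=0)
    sd[sd == 0] = np.inf
    dev = np.nanmax(np.abs(null - mu) / sd, axis=1)  # per-permutation sup-t
    c = np.nanpercentile(dev, 100 * (1 - alpha))
    lo = mu - c * sd
    hi = mu + c * sd
    mids = 0.5 * (edges[:-1] + edges[1:])
    cnt = np.bincount(which[valid], minlength=n_bins)
    return pd.DataFrame(
        {"distance": mids, "moran": obs, "lower": lo, "upper": hi, "n_pairs": cnt}
    )


def predict_probability(fit: ModelFit, covariate_row: dict) -> float:
    """Inverse-logit of the linear predictor at random effect 0."""
    eta = fit.beta[0]
    for t, b in zip(fit.terms[1:], fit.beta[1:]):
        if t not in covariate_row:
            raise ValueError(f"missing covariate {t!r}")
        eta += b * float(covariate_row[t])
    return float(expit(eta))
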