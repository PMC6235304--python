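"""Mixed binary logistic models with crossed random intercepts.

The detection rate (DR) and level of certainty (LC) of an aerial count are
modelled on the logit scale as

    logit(R) = a + b*height + c*wind + d*cloud + e*sun + f*experience
               + alpha_flight + beta_photo + gamma_observer

with Gaussian random intercepts for flight, photo and observer.  The three
grouping factors are *crossed* (every observer reviews every photo of every
flight), so the marginal likelihood does not factorize over groups and is
maximized here by a Laplace approximation: for candidate parameters the
joint mode of all random effects is found by penalized IRLS (the inner
problem is strictly concave), and the marginal log-likelihood is the joint
log-density at the mode corrected by the log-determinant of its curvature.
For small latent dimensions an adaptive (mode-centered, curvature-scaled)
product Gauss-Hermite rule is available, which is effectively exact and is
the reference for validating the Laplace path.

Covariate encoding — shared with the synthetic-data generator so that
simulation truth and recovered estimates live on the same scale:

* height and wind: standardized (sample mean / SD over units),
* cloud and sun: 3-level ordinal regrouped to a binary indicator
  (response-specific, see :func:`regroup`),
* experience: raw 0/1 dummy (0 = experienced, 1 = novice).

Responses are binomial: DR uses the per-flight school estimate as the
denominator; LC uses the observer's own total count, excluding zero-count
units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ConvergenceError",
    "standardize",
    "regroup",
    "encode_covariates",
    "CrossedMixedLogit",
    "fit_glmm",
    "backward_select",
]

FIXED_NAMES = ("height", "wind", "cloud", "sun", "experience")
RANDOM_NAMES = ("flight", "photo", "observer")

_SIGMA_FLOOR_LOG = -6.0  # log-SD lower bound; below -5 reported as boundary 0
_SIGMA_CEIL_LOG = 3.0


class ConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimization fails."""


def standardize(values) -> np.ndarray:
    """Center and scale to unit sample SD (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1-D vector")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def regroup(values, factor: str, response: str) -> np.ndarray:
    """Collapse a 3-level ordinal covariate to the binary coding of one model.

    Cloud (both models): scattered clouds count as clear sky — {0, 1} -> 0,
    heavy cover {2} -> 1.  Sun reflection differs by response: minor
    reflection is negligible for detection (DR: {0, 1} -> 0, {2} -> 1) but
    already erodes certainty (LC: {0} -> 0, {1, 2} -> 1).
    """
    x = np.asarray(values, dtype=int)
    if np.any((x < 0) | (x > 2)):
        raise ValueError(f"{factor} classes must be in {{0, 1, 2}}")
    if factor == "cloud":
        return (x == 2).astype(float)
    if factor == "sun":
        if response == "dr":
            return (x == 2).astype(float)
        if response == "lc":
            return (x >= 1).astype(float)
        raise ValueError(f"unknown response {response!r}")
    raise ValueError(f"unknown regroupable factor {factor!r}")


def encode_covariates(units: pd.DataFrame, response: str,
                      fixed=FIXED_NAMES) -> tuple[np.ndarray, list]:
    """Design matrix (with intercept) for the requested fixed effects.

    Returns ``(X, names)`` with ``names[0] == "intercept"``.
    """
    cols = [np.ones(len(units))]
    names = ["intercept"]
    for name in fixed:
        if name == "height":
            cols.append(standardize(units["height_m"]))
        elif name == "wind":
            cols.append(standardize(units["wind_ms"]))
        elif name == "cloud":
            cols.append(regroup(units["cloud_class"], "cloud", response))
        elif name == "sun":
            cols.append(regroup(units["sun_class"], "sun", response))
        elif name == "experience":
            cols.append(units["experienced"].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown fixed effect {name!r}")
        names.append(name)
    return np.column_stack(cols), names


@dataclass(frozen=True)
class ModelSpec:
    """Which response, fixed effects and random intercepts to fit."""

    response: str = "dr"
    fixed: tuple = FIXED_NAMES
    random: tuple = RANDOM_NAMES

    def __post_init__(self):
        if self.response not in ("dr", "lc"):
            raise ValueError("response must be 'dr' or 'lc'")
        for f in self.fixed:
            if f not in FIXED_NAMES:
                raise ValueError(f"unknown fixed effect {f!r}")
        for r in self.random:
            if r not in RANDOM_NAMES:
                raise ValueError(f"unknown random factor {r!r}")

    def drop_fixed(self, name: str) -> "ModelSpec":
        return ModelSpec(self.response,
                         tuple(f for f in self.fixed if f != name),
                         self.random)

    def drop_random(self, name: str) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed,
                         tuple(r for r in self.random if r != name))


@dataclass
class ModelFit:
    """Result of one mixed-logit fit."""

    spec: ModelSpec
    coefficients: dict
    se: dict
    pvalues: dict
    random_sd: dict
    loglik: float
    aic: float
    n_units: int
    converged: bool
    boundary: list = field(default_factory=list)
    method: str = "laplace"

    @property
    def n_params(self) -> int:
        return len(self.coefficients) + len(self.random_sd)

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "fixed": list(self.spec.fixed),
            "random": list(self.spec.random),
            "coefficients": self.coefficients,
            "se": self.se,
            "pvalues": self.pvalues,
            "random_sd": self.random_sd,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_units": self.n_units,
            "converged": self.converged,
            "boundary": self.boundary,
            "method": self.method,
        }


def _response_arrays(units: pd.DataFrame, spec: ModelSpec):
    """Successes, trials and the unit subset used for the given response."""
    tot = (units["n_definite"] + units["n_possible"]).to_numpy()
    if spec.response == "dr":
        n = units["est_pop"].to_numpy()
        if np.any(n <= 0):
            raise ValueError("est_pop must be > 0 for the DR model")
        # real data can over-count (DR > 1); a binomial response cannot
        # exceed its denominator, so successes are capped for fitting
        y = np.minimum(tot, n)
        keep = np.ones(len(units), dtype=bool)
    else:
        keep = tot > 0
        y = units.loc[keep, "n_definite"].to_numpy()
        n = tot[keep]
    return y.astype(float), n.astype(float), units.loc[keep]


class CrossedMixedLogit:
    """Binomial-logit likelihood machinery for crossed Gaussian intercepts.

    Holds the encoded design and exposes marginal log-likelihood evaluation
    (Laplace or adaptive Gauss-Hermite) and maximum-likelihood fitting.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, n: np.ndarray,
                 factors: list[tuple[str, np.ndarray]],
                 fixed_names: list[str], spec: ModelSpec):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.n = np.asarray(n, float)
        self.spec = spec
        self.fixed_names = list(fixed_names)
        self.factor_names = [name for name, _ in factors]
        self.codes = []
        self.block_sizes = []
        for _, levels in factors:
            codes, uniq = pd.factorize(levels)
            if len(uniq) < 2:
                raise ValueError("each random factor needs >= 2 levels")
            self.codes.append(codes)
            self.block_sizes.append(len(uniq))
        self.q = int(sum(self.block_sizes))
        self.k = self.X.shape[1]
        m = len(self.y)
        if self.q:
            rows = np.tile(np.arange(m), len(self.codes))
            cols = np.concatenate(
                [c + off for c, off in zip(self.codes, self._offsets())]
            )
            self.Z = sp.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(m, self.q)
            )
        else:
            self.Z = sp.csr_matrix((m, 0))
        self._logC = float(np.sum(gammaln(self.n + 1) - gammaln(self.y + 1)
                                  - gammaln(self.n - self.y + 1)))
        self._u_warm = np.zeros(self.q)

    @classmethod
    def from_units(cls, units: pd.DataFrame, spec: ModelSpec) -> "CrossedMixedLogit":
        y, n, sub = _response_arrays(units, spec)
        X, names = encode_covariates(sub, spec.response, spec.fixed)
        factors = [(r, sub[f"{r}_id"].to_numpy()) for r in spec.random]
        return cls(X, y, n, factors, names, spec)

    # -- internals -------------------------------------------------------
    def _offsets(self):
        return np.concatenate([[0], np.cumsum(self.block_sizes)[:-1]]).astype(int)

    def _dinv(self, sigma: np.ndarray) -> np.ndarray:
        return np.repeat(1.0 / sigma**2, self.block_sizes)

    def _joint(self, beta, u, dinv):
        """Penalized binomial log-likelihood (no determinant terms)."""
        eta = self.X @ beta + self.Z @ u
        # n*log(1+e^eta), stably
        soft = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
        return float(self.y @ eta - self.n @ soft - 0.5 * np.sum(dinv * u * u))

    def _mode(self, beta, sigma, maxiter=50):
        """Newton (penalized IRLS) solve for the joint random-effect mode.

        The gradient tolerance scales with the total number of Bernoulli
        trials: beyond that the objective is flat to machine precision.
        """
        dinv = self._dinv(sigma)
        tol_g = 1e-10 * max(1.0, float(self.n.sum()))
        u = self._u_warm.copy()
        f = self._joint(beta, u, dinv)
        H_chol = None
        for _ in range(maxiter):
            eta = self.X @ beta + self.Z @ u
            p = expit(eta)
            w = self.n * p * (1 - p)
            g = self.Z.T @ (self.y - self.n * p) - dinv * u
            H = (self.Z.multiply(w[:, None]).T @ self.Z).toarray()
            H[np.diag_indices_from(H)] += dinv
            H_chol = cho_factor(H, lower=True)
            if np.max(np.abs(g)) < tol_g:
                break
            du = cho_solve(H_chol, g)
            step, improved = 1.0, False
            f_floor = f - 1e-9 * max(1.0, abs(f))
            for _ in range(12):
                f_new = self._joint(beta, u + step * du, dinv)
                if f_new >= f_floor:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break  # at the numerical noise floor of the objective
            u = u + step * du
            f = f_new
        self._u_warm = u
        return u, H_chol, f

    def loglik(self, beta, sigma, method="laplace", nodes=9):
        """Marginal log-likelihood at the given parameters.

        ``method='laplace'`` is the default used for fitting;
        ``method='agq'`` runs a mode-centered product Gauss-Hermite rule
        (requires total latent dimension <= 6).
        """
        beta = np.asarray(beta, float)
        sigma = np.asarray(sigma, float)
        if self.q == 0:
            eta = self.X @ beta
            soft = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
            return float(self.y @ eta - self.n @ soft) + self._logC
        u, H_chol, f = self._mode(beta, sigma)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(H_chol[0]))))
        logdet_S = 2.0 * float(np.sum(np.repeat(np.log(sigma), self.block_sizes)))
        if method == "laplace":
            return f + self._logC - 0.5 * (logdet_S + logdet_H)
        if method != "agq":
            raise ValueError(f"unknown method {method!r}")
        if self.q > 6:
            raise ValueError("agq is limited to total latent dimension <= 6")
        if nodes**self.q * len(self.y) > 5e7:
            raise ValueError("agq grid too large for this data size")
        # u = u_hat + sqrt(2) * L^{-T} z, H = L L^T
        z1, w1 = np.polynomial.hermite.hermgauss(nodes)
        grids = np.meshgrid(*([z1] * self.q), indexing="ij")
        Zn = np.column_stack([g.ravel() for g in grids])  # (nodes^q, q)
        wgrids = np.meshgrid(*([np.log(w1)] * self.q), indexing="ij")
        logw = np.sum([g.ravel() for g in wgrids], axis=0)
        L = np.tril(H_chol[0])
        U = u[None, :] + np.sqrt(2.0) * solve_triangular(L.T, Zn.T, lower=False).T
        eta = (self.X @ beta)[None, :] + U @ self.Z.toarray().T  # (npts, m)
        soft = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
        dinv = self._dinv(sigma)
        g = (eta @ self.y - soft @ self.n
             - 0.5 * np.sum(U * U * dinv[None, :], axis=1)
             - 0.5 * logdet_S - 0.5 * self.q * np.log(2 * np.pi))
        # integral = (sqrt 2)^q |H|^{-1/2} sum w_j exp(g_j + |z_j|^2)
        lse = logsumexp(logw + g + np.sum(Zn * Zn, axis=1))
        return float(0.5 * self.q * np.log(2.0) - 0.5 * logdet_H + lse
                     + self._logC)

    # -- fitting ---------------------------------------------------------
    def _start_beta(self) -> np.ndarray:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    np.column_stack([self.y, self.n - self.y]),
                    self.X,
                    family=sm.families.Binomial(),
                ).fit()
            beta = np.asarray(res.params, float)
            if np.all(np.isfinite(beta)):
                return np.clip(beta, -10, 10)
        except Exception:
            pass
        return np.zeros(self.k)

    def fit(self, method="laplace", nodes=9, start=None,
            compute_se=True) -> ModelFit:
        from scipy.optimize import minimize

        if start is None:
            theta0 = np.concatenate([self._start_beta(),
                                     np.full(len(self.block_sizes),
                                             np.log(0.3))])
        else:
            theta0 = np.asarray(start, float)
        nb = self.k

        def negll(theta):
            val = self.loglik(theta[:nb], np.exp(theta[nb:]),
                              method=method, nodes=nodes)
            return -val if np.isfinite(val) else 1e12

        bounds = [(None, None)] * nb + [
            (_SIGMA_FLOOR_LOG, _SIGMA_CEIL_LOG)
        ] * len(self.block_sizes)
        res = minimize(
            negll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-5, "eps": 3e-6},
        )
        if not res.success and "ROUND" not in str(res.message).upper():
            # one restart from a perturbed point before giving up
            res2 = minimize(
                negll, theta0 * 0.5, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-5,
                         "eps": 3e-6},
            )
            if res2.fun < res.fun:
                res = res2
        theta = res.x
        beta = theta[:nb]
        sigma = np.exp(theta[nb:])
        boundary = [
            name for name, s in zip(self.factor_names, sigma)
            if np.log(s) < _SIGMA_FLOOR_LOG + 1.0
        ]
        sigma_out = {
            name: (0.0 if name in boundary else float(s))
            for name, s in zip(self.factor_names, sigma)
        }
        ll = -res.fun
        k_par = nb + len(self.block_sizes)
        se = dict.fromkeys(self.fixed_names, float("nan"))
        pvals = dict.fromkeys(self.fixed_names, float("nan"))
        if compute_se:
            cov = self._theta_cov(negll, theta)
            if cov is not None:
                for j, name in enumerate(self.fixed_names):
                    if cov[j, j] > 0:
                        se[name] = float(np.sqrt(cov[j, j]))
                        z = beta[j] / se[name]
                        pvals[name] = float(2 * norm.sf(abs(z)))
        return ModelFit(
            spec=self.spec,
            coefficients={n: float(b) for n, b in zip(self.fixed_names, beta)},
            se=se,
            pvalues=pvals,
            random_sd=sigma_out,
            loglik=float(ll),
            aic=float(2 * k_par - 2 * ll),
            n_units=len(self.y),
            converged=bool(res.success),
            boundary=boundary,
            method=method,
        )

    def _theta_cov(self, negll, theta, step=1e-4):
        """Covariance from a central-difference Hessian of -loglik."""
        p = len(theta)
        H = np.empty((p, p))
        h = step * np.maximum(1.0, np.abs(theta))
        f0 = negll(theta)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                if i == j:
                    val = (negll(theta + ei) - 2 * f0 + negll(theta - ei)) / h[i] ** 2
                else:
                    val = (
                        negll(theta + ei + ej) - negll(theta + ei - ej)
                        - negll(theta - ei + ej) + negll(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None


def fit_glmm(units: pd.DataFrame, spec: ModelSpec | None = None,
             method: str = "laplace", nodes: int = 9,
             compute_se: bool = True) -> ModelFit:
    """Fit one mixed binary logistic model to the unit table.

    ``units`` needs columns photo_id, flight_id, observer_id, height_m,
    wind_ms, cloud_class, sun_class, experienced, n_definite, n_possible,
    est_pop.  See :class:`ModelSpec` for the response and term selection.
    """
    spec = spec or ModelSpec()
    model = CrossedMixedLogit.from_units(units, spec)
    fit = model.fit(method=method, nodes=nodes, compute_se=compute_se)
    if not fit.converged and not np.isfinite(fit.loglik):
        raise ConvergenceError(
            f"mixed-logit fit for response {spec.response!r} failed"
        )
    return fit


def backward_select(units: pd.DataFrame, spec: ModelSpec | None = None,
                    test_random: bool = True,
                    method: str = "laplace") -> tuple[ModelFit, list]:
    """AIC backward elimination from the full model.

    Random intercepts are tested first by likelihood-ratio comparison of
    nested fits and kept whenever they improve AIC; fixed effects are then
    removed greedily (largest AIC drop first) until no removal lowers AIC.
    Returns the final fit and an ordered trace of the decisions.
    """
    spec = spec or ModelSpec()
    trace: list[dict] = []
    current = fit_glmm(units, spec, method=method, compute_se=False)

    def try_drop(kind: str):
        nonlocal current, spec
        while True:
            terms = spec.random if kind == "random" else spec.fixed
            candidates = {}
            for term in terms:
                cand_spec = (spec.drop_random(term) if kind == "random"
                             else spec.drop_fixed(term))
                try:
                    cand = fit_glmm(units, cand_spec, method=method,
                                    compute_se=False)
                except (ValueError, ConvergenceError):
                    continue
                candidates[term] = cand
            if not candidates:
                return
            best = min(candidates, key=lambda t: candidates[t].aic)
            entry = {
                "kind": kind,
                "candidate_aic": {t: candidates[t].aic for t in candidates},
                "aic_before": current.aic,
            }
            if candidates[best].aic < current.aic:
                lr = 2 * (current.loglik - candidates[best].loglik)
                entry.update(removed=best, aic_after=candidates[best].aic,
                             lr_statistic=float(lr))
                trace.append(entry)
                spec = (spec.drop_random(best) if kind == "random"
                        else spec.drop_fixed(best))
                current = candidates[best]
            else:
                entry.update(removed=None)
                trace.append(entry)
                return

    if test_random and spec.random:
        try_drop("random")
    if spec.fixed:
        try_drop("fixed")
    # refit with standard errors for the final model
    final = fit_glmm(units, spec, method=method, compute_se=True)
    return final, trace
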