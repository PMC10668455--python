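"""Linear mixed model for BI-RADS breast density on age and BMI.

The density reading y (an integer 1-4 treated as continuous) of woman i
at screen j is modelled as

    y_ij = x_ij' beta + z_ij' b_i + e_ij,
    b_i ~ N(0, G),  e_ij ~ N(0, sigma^2),

where x = (1, a, a^2, a^3, a^4, bmi, a*bmi) with a = age/5 - c (age in
5-year units, centred at a configurable constant c), z = (1, a) gives
each woman a random intercept and random age slope with unstructured
2x2 covariance G, and the model is fitted by maximum likelihood with
beta profiled out by generalized least squares and G parameterised
through its Cholesky factor. Cluster-robust (sandwich) standard errors
are available from the fitted results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

FIXED_NAMES = ["intercept", "age5", "age5^2", "age5^3", "age5^4", "bmi", "age5:bmi"]
N_FIXED = 7


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the best fit so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def build_design(age, bmi, centering: float = 10.0):
    """Fixed- and random-effects design rows for given age(s) and BMI(s).

    Returns (X, Z) with X of shape (n, 7) = (1, a, a², a³, a⁴, bmi, a·bmi)
    and Z of shape (n, 2) = (1, a), where a = age/5 − centering.
    Scalars in give 1-row matrices out.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    bmi = np.atleast_1d(np.asarray(bmi, dtype=float))
    a = age / 5.0 - centering
    X = np.column_stack([np.ones_like(a), a, a**2, a**3, a**4, bmi, a * bmi])
    Z = np.column_stack([np.ones_like(a), a])
    return X, Z


@dataclass
class LmmParams:
    """Parameters of the density mixed model.

    beta : fixed effects, length 7 (density units).
    G : 2x2 PSD random-effects covariance (intercept, age slope per 5 yr).
    sigma2 : residual variance.
    centering : age centering constant c (age/5 units; 10 = age 50).
    """

    beta: np.ndarray
    G: np.ndarray
    sigma2: float
    centering: float = 10.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.G = np.asarray(self.G, dtype=float).reshape(2, 2)
        if self.beta.shape != (N_FIXED,):
            raise ValueError("beta must have length 7")
        if not np.allclose(self.G, self.G.T):
            raise ValueError("G must be symmetric")
        if np.linalg.eigvalsh(self.G).min() < -1e-10:
            raise ValueError("G must be positive semidefinite")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta": self.beta.tolist(),
                    "G": self.G.tolist(),
                    "sigma2": float(self.sigma2),
                    "centering": float(self.centering),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "LmmParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            beta=np.array(d["beta"]),
            G=np.array(d["G"]),
            sigma2=d["sigma2"],
            centering=d.get("centering", 10.0),
        )


# ---------------------------------------------------------------------
# grouped data layout: women batched by number of screens so the
# per-woman multivariate-normal algebra runs as stacked linalg
# ---------------------------------------------------------------------


class _GroupedData:
    def __init__(self, woman_ids, y, X, Z):
        """woman_ids: per-row labels (rows sorted by woman, time)."""
        self.groups = []  # list of (ids, Ys(m,n), Xs(m,n,7), Zs(m,n,2))
        ids, counts = np.unique(woman_ids, return_counts=True)
        order = {}
        start = 0
        # rows are contiguous per woman in sorted order
        labels = np.asarray(woman_ids)
        splits = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        blocks = np.split(np.arange(len(labels)), splits)
        by_n: dict[int, list] = {}
        for blk in blocks:
            by_n.setdefault(len(blk), []).append(blk)
        for n, blks in sorted(by_n.items()):
            rows = np.array(blks)  # (m, n)
            self.groups.append(
                (
                    labels[rows[:, 0]],
                    y[rows],
                    X[rows],
                    Z[rows],
                )
            )
        self.n_obs = len(y)
        self.n_women = sum(g[0].shape[0] for g in self.groups)
        self.max_n = max(g[1].shape[1] for g in self.groups)

    @classmethod
    def from_cohort(cls, cohort, centering):
        s = cohort.screens
        if s["birads"].isna().any() or s["bmi"].isna().any():
            raise ValueError("cohort must be preprocessed (no missing bmi/birads)")
        X, Z = build_design(s["age"].to_numpy(), s["bmi"].to_numpy(), centering)
        return cls(s["woman_id"].to_numpy(), s["birads"].to_numpy(float), X, Z)


def _group_loglik_terms(Ys, Xs, Zs, beta, G, sigma2):
    """Per-woman logdet(V) and quadratic form for one size group."""
    m, n = Ys.shape
    V = Zs @ G @ np.swapaxes(Zs, 1, 2) + sigma2 * np.eye(n)[None, :, :]
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    r = Ys - Xs @ beta
    w = np.linalg.solve(V, r[..., None])[..., 0]
    quad = (r * w).sum(axis=1)
    return logdet, quad


def marginal_loglik(params: LmmParams, cohort, per_woman: bool = False):
    """Marginal Gaussian log-likelihood of a cohort under ``params``.

    Sum over women of the multivariate-normal log-density of her reading
    vector with mean X_i beta and covariance Z_i G Z_i' + sigma^2 I.
    With ``per_woman=True`` returns (ids, per-woman logliks).
    """
    gd = _GroupedData.from_cohort(cohort, params.centering)
    return _marginal_loglik_grouped(gd, params.beta, params.G, params.sigma2,
                                    per_woman=per_woman)


def _marginal_loglik_grouped(gd, beta, G, sigma2, per_woman=False):
    ids_all, ll_all = [], []
    total = 0.0
    for ids, Ys, Xs, Zs in gd.groups:
        n = Ys.shape[1]
        logdet, quad = _group_loglik_terms(Ys, Xs, Zs, beta, G, sigma2)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        total += ll.sum()
        if per_woman:
            ids_all.append(ids)
            ll_all.append(ll)
    if per_woman:
        return np.concatenate(ids_all), np.concatenate(ll_all)
    return float(total)


def _profiled_beta(gd, G, sigma2):
    """GLS beta at the given variance components."""
    A = np.zeros((N_FIXED, N_FIXED))
    b = np.zeros(N_FIXED)
    for _, Ys, Xs, Zs in gd.groups:
        n = Ys.shape[1]
        V = Zs @ G @ np.swapaxes(Zs, 1, 2) + sigma2 * np.eye(n)[None, :, :]
        VinvX = np.linalg.solve(V, Xs)
        A += np.einsum("mnp,mnq->pq", Xs, VinvX)
        b += np.einsum("mnp,mn->p", VinvX, Ys)
    return np.linalg.solve(A, b), A


def _theta_to_varcomp(theta):
    l11, l21, l22, log_sig = theta
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T, float(np.exp(2.0 * log_sig))


class DensityMixedModel:
    """Mixed model for longitudinal BI-RADS density, statsmodels-style.

    Parameters
    ----------
    cohort : CohortTable with no missing BMI or BI-RADS.
    centering : age centering constant c in 5-year units (default 10,
        i.e. age 50); fitted values are invariant to it.

    Examples
    --------
    >>> model = DensityMixedModel(cohort)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, cohort, centering: float = 10.0):
        self.cohort = cohort
        self.centering = float(centering)
        self._gd = _GroupedData.from_cohort(cohort, centering)
        self.g_identified = self._gd.max_n > 1

    @classmethod
    def from_dataframe(cls, screens, centering: float = 10.0):
        """Build directly from a screens-format DataFrame (no outcomes)."""
        from .cohort import CohortTable

        outcomes = (
            screens.groupby("woman_id")["exam_time"]
            .max()
            .add(1.0)
            .rename("exit_time")
            .reset_index()
        )
        outcomes["event"] = 0
        outcomes["censor_reason"] = "admin_end"
        return cls(CohortTable(screens, outcomes), centering)

    def loglik(self, params: LmmParams) -> float:
        return _marginal_loglik_grouped(
            self._gd, params.beta, params.G, params.sigma2
        )

    def _neg_loglik_theta(self, theta, reml: bool = False):
        G, sigma2 = _theta_to_varcomp(theta)
        if sigma2 < 1e-10 or not np.isfinite(sigma2):
            return 1e12
        try:
            beta, A = _profiled_beta(self._gd, G, sigma2)
            ll = _marginal_loglik_grouped(self._gd, beta, G, sigma2)
            if reml:
                sign, logdet = np.linalg.slogdet(A)
                if sign <= 0:
                    return 1e12
                ll -= 0.5 * logdet
            return -ll
        except np.linalg.LinAlgError:
            return 1e12

    def fit(self, maxiter: int = 500, tol: float = 1e-10,
            start=None, reml: bool = False) -> "DensityMixedModelResults":
        """Maximum-likelihood fit (REML behind a flag, for sensitivity).

        beta is profiled out by GLS at each variance-component candidate;
        G is parameterised through its Cholesky factor so positive
        semidefiniteness holds by construction.
        """
        # moment-based starting values from pooled OLS
        y = np.concatenate([g[1].ravel() for g in self._gd.groups])
        Xall = np.concatenate([g[2].reshape(-1, N_FIXED) for g in self._gd.groups])
        beta0, *_ = np.linalg.lstsq(Xall, y, rcond=None)
        resid_var = max(float(np.var(y - Xall @ beta0)), 1e-4)
        if start is None:
            start = np.array(
                [np.sqrt(resid_var / 2), 0.0, 0.05, 0.5 * np.log(resid_var / 2)]
            )
        res = optimize.minimize(
            self._neg_loglik_theta,
            start,
            args=(reml,),
            method="Nelder-Mead",
            options={"maxiter": maxiter * 4, "xatol": 1e-7, "fatol": tol * 10},
        )
        res = optimize.minimize(
            self._neg_loglik_theta,
            res.x,
            args=(reml,),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9},
        )
        G, sigma2 = _theta_to_varcomp(res.x)
        beta, _ = _profiled_beta(self._gd, G, sigma2)
        params = LmmParams(beta=beta, G=G, sigma2=sigma2, centering=self.centering)
        loglik = _marginal_loglik_grouped(self._gd, beta, G, sigma2)
        objective = -self._neg_loglik_theta(res.x, reml)
        converged = bool(res.success) or abs(res.fun + objective) < 1e-6
        if not converged and not np.isfinite(loglik):
            raise ConvergenceError("mixed-model fit failed to converge", best=params)
        return DensityMixedModelResults(
            model=self,
            params=params,
            loglik=loglik,
            converged=converged,
            n_women=self._gd.n_women,
            n_obs=self._gd.n_obs,
            g_identified=self.g_identified,
        )


@dataclass
class DensityMixedModelResults:
    """Fitted density mixed model: estimates, likelihood, robust SEs."""

    model: DensityMixedModel
    params: LmmParams
    loglik: float
    converged: bool
    n_women: int
    n_obs: int
    g_identified: bool
    _robust_cov: np.ndarray | None = field(default=None, repr=False)

    # full parameter vector ordering used for the sandwich matrix
    PARAM_NAMES = FIXED_NAMES + ["G[0,0]", "G[1,0]", "G[1,1]", "sigma2"]

    def _full_theta(self):
        p = self.params
        return np.concatenate(
            [p.beta, [p.G[0, 0], p.G[1, 0], p.G[1, 1], p.sigma2]]
        )

    def _per_woman_loglik(self, theta):
        beta = theta[:N_FIXED]
        G = np.array(
            [[theta[N_FIXED], theta[N_FIXED + 1]],
             [theta[N_FIXED + 1], theta[N_FIXED + 2]]]
        )
        sigma2 = theta[N_FIXED + 3]
        out = []
        for _, Ys, Xs, Zs in self.model._gd.groups:
            n = Ys.shape[1]
            logdet, quad = _group_loglik_terms(Ys, Xs, Zs, beta, G, sigma2)
            out.append(-0.5 * (n * np.log(2 * np.pi) + logdet + quad))
        return np.concatenate(out)

    def robust_covariance(self, beta_only: bool = True) -> np.ndarray:
        """Cluster-robust sandwich covariance A^-1 B A^-1.

        A is the observed information of the marginal log-likelihood and
        B the sum over women (clusters) of outer products of per-woman
        score vectors, both at the estimates. Scores and information are
        computed by central finite differences over the full parameter
        vector (beta, vech G, sigma2); the beta block is returned by
        default.
        """
        if self._robust_cov is None:
            theta = self._full_theta()
            k = len(theta)
            h = 1e-5 * np.maximum(np.abs(theta), 1.0)
            # per-woman scores
            scores = np.zeros((self.n_women, k))
            for j in range(k):
                tp, tm = theta.copy(), theta.copy()
                tp[j] += h[j]
                tm[j] -= h[j]
                scores[:, j] = (
                    self._per_woman_loglik(tp) - self._per_woman_loglik(tm)
                ) / (2 * h[j])
            B = scores.T @ scores
            # observed information: negative Hessian of the total loglik
            def total(t):
                return self._per_woman_loglik(t).sum()

            A = np.zeros((k, k))
            f0 = total(theta)
            for i in range(k):
                for j in range(i, k):
                    if i == j:
                        tpp = theta.copy(); tpp[i] += h[i]
                        tmm = theta.copy(); tmm[i] -= h[i]
                        A[i, i] = -(total(tpp) - 2 * f0 + total(tmm)) / h[i] ** 2
                    else:
                        tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                        tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                        tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                        tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                        A[i, j] = A[j, i] = -(
                            total(tpp) - total(tpm) - total(tmp) + total(tmm)
                        ) / (4 * h[i] * h[j])
            Ainv = np.linalg.pinv(A)
            cov = Ainv @ B @ Ainv
            cov = 0.5 * (cov + cov.T)
            self._robust_cov = cov
        if beta_only:
            return self._robust_cov[:N_FIXED, :N_FIXED]
        return self._robust_cov

    def model_based_covariance(self) -> np.ndarray:
        """Inverse GLS information for beta (non-robust)."""
        _, A = _profiled_beta(self.model._gd, self.params.G, self.params.sigma2)
        return np.linalg.inv(A)

    def predict_fixed(self, age, bmi) -> np.ndarray:
        """Population-mean density surface x(age, bmi)' beta."""
        X, _ = build_design(age, bmi, self.params.centering)
        return X @ self.params.beta

    def sequential_estimates(self, cohort=None, cuts=None, inclusive=True):
        """Per-woman per-screen empirical-Bayes density estimates."""
        from .empirical_bayes import sequential_estimates

        return sequential_estimates(
            cohort if cohort is not None else self.model.cohort,
            self.params,
            cuts=cuts,
            inclusive=inclusive,
        )

    def summary(self) -> str:
        p = self.params
        se = np.sqrt(np.diag(self.robust_covariance(beta_only=True)))
        lines = [
            "Density mixed model (ML)",
            f"  women: {self.n_women}   observations: {self.n_obs}",
            f"  log-likelihood: {self.loglik:.3f}   converged: {self.converged}",
            f"  age centering c = {p.centering} (5-yr units)",
            "",
            f"  {'term':>10} {'coef':>12} {'robust se':>12}",
        ]
        for name, b, s in zip(FIXED_NAMES, p.beta, se):
            lines.append(f"  {name:>10} {b:>12.5f} {s:>12.5f}")
        lines += [
            "",
            f"  G (random intercept/slope cov): "
            f"[[{p.G[0,0]:.5f}, {p.G[0,1]:.5f}], [{p.G[1,0]:.5f}, {p.G[1,1]:.5f}]]",
            f"  sigma2 (residual): {p.sigma2:.5f}",
        ]
        if not self.g_identified:
            lines.append("  note: all women single-screen; G not identified")
        return "\n".join(lines)
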