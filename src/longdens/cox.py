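"""Time-varying-covariate Cox proportional-hazards fitting.

Risk intervals in counting-process form (start, stop] with
piecewise-constant covariates are fitted by Newton-Raphson on the
partial likelihood, with Efron (default) or Breslow handling of tied
event times. The module also provides the three density model
specifications used to quantify the predictive information of breast
density — BI-RADS as a four-level factor, continuous longitudinal
density with linear and quadratic terms, and the eight-category
longitudinal measure — each adjusted for baseline age and time-varying
BMI, together with the likelihood-ratio information gain over the
age+BMI-only model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, RiskIntervalTable, build_risk_intervals


class CoxError(RuntimeError):
    pass


@dataclass(frozen=True)
class Covariate:
    """One model term: continuous, factor (with reference level), or
    continuous plus quadratic."""

    name: str
    kind: str = "continuous"  # continuous | factor | continuous+quadratic
    ref: object = None        # reference level for factor coding

    def __post_init__(self):
        if self.kind not in ("continuous", "factor", "continuous+quadratic"):
            raise ValueError(f"unknown coding {self.kind!r}")
        if self.kind == "factor" and self.ref is None:
            raise ValueError("factor coding requires a reference level")


@dataclass(frozen=True)
class CoxSpec:
    covariates: tuple
    ties_method: str = "efron"

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.ties_method not in ("efron", "breslow"):
            raise ValueError("ties_method must be 'efron' or 'breslow'")


def _design(intervals: RiskIntervalTable, spec: CoxSpec):
    """Expand a spec into a numeric design matrix with column names."""
    d = intervals.data
    cols, names = [], []
    for cv in spec.covariates:
        if cv.name not in d.columns:
            raise CoxError(f"covariate {cv.name!r} missing from intervals")
        x = d[cv.name].to_numpy()
        if cv.kind == "continuous":
            cols.append(x.astype(float)); names.append(cv.name)
        elif cv.kind == "continuous+quadratic":
            xf = x.astype(float)
            cols += [xf, xf**2]
            names += [cv.name, f"{cv.name}^2"]
        else:
            levels = [lv for lv in np.unique(x) if lv != cv.ref]
            if cv.ref not in set(np.unique(x)):
                raise CoxError(
                    f"reference level {cv.ref!r} of {cv.name!r} not observed"
                )
            for lv in levels:
                cols.append((x == lv).astype(float))
                lab = f"{lv:g}" if isinstance(lv, (int, float, np.integer,
                                                   np.floating)) else str(lv)
                names.append(f"{cv.name}={lab}")
    X = np.column_stack(cols) if cols else np.empty((len(d), 0))
    return X, names


class _PartialLik:
    """Efron/Breslow partial likelihood with suffix-sum risk sets.

    The risk set at event time t is {rows: start < t <= stop}; its sums
    are computed as (suffix over stop >= t) - (suffix over start >= t),
    which makes each Newton iteration O(rows * p^2).
    """

    def __init__(self, start, stop, event, X, ties="efron"):
        self.X = X
        self.ties = ties
        self.n, self.p = X.shape
        ev_times = np.unique(stop[event == 1])
        self.event_times = ev_times
        self.tied_rows = [
            np.flatnonzero((event == 1) & (stop == t)) for t in ev_times
        ]
        self.o_stop = np.argsort(stop, kind="mergesort")
        self.sorted_stop = stop[self.o_stop]
        self.o_start = np.argsort(start, kind="mergesort")
        self.sorted_start = start[self.o_start]
        # suffix positions per event time
        self.i_stop = np.searchsorted(self.sorted_stop, ev_times, side="left")
        self.i_start = np.searchsorted(self.sorted_start, ev_times, side="left")

    def _suffix(self, arr, order):
        """Suffix sums of arr (n, ...) in the given sort order."""
        s = np.zeros((self.n + 1,) + arr.shape[1:])
        s[:-1] = np.cumsum(arr[order][::-1], axis=0)[::-1]
        return s

    def loglik_grad_hess(self, beta, want_derivs=True):
        X = self.X
        eta = X @ beta
        eta = eta - eta.max()  # overflow guard; cancels in ratios
        w = np.exp(eta)
        wx = w[:, None] * X
        wxx = wx[:, :, None] * X[:, None, :]
        suf0_stop = self._suffix(w[:, None], self.o_stop)[:, 0]
        suf0_start = self._suffix(w[:, None], self.o_start)[:, 0]
        suf1_stop = self._suffix(wx, self.o_stop)
        suf1_start = self._suffix(wx, self.o_start)
        if want_derivs:
            suf2_stop = self._suffix(wxx, self.o_stop)
            suf2_start = self._suffix(wxx, self.o_start)
        ll = 0.0
        grad = np.zeros(self.p)
        hess = np.zeros((self.p, self.p))
        for e, t in enumerate(self.event_times):
            D = self.tied_rows[e]
            d = len(D)
            S0 = suf0_stop[self.i_stop[e]] - suf0_start[self.i_start[e]]
            S1 = suf1_stop[self.i_stop[e]] - suf1_start[self.i_start[e]]
            if want_derivs:
                S2 = suf2_stop[self.i_stop[e]] - suf2_start[self.i_start[e]]
            S0D = w[D].sum(); S1D = wx[D].sum(axis=0)
            if want_derivs:
                S2D = wxx[D].sum(axis=0)
            ll += eta[D].sum()
            if want_derivs:
                grad += X[D].sum(axis=0)
            frac = (np.arange(d) / d) if self.ties == "efron" else np.zeros(d)
            for f in frac:
                phi = S0 - f * S0D
                if phi <= 0:
                    raise CoxError("empty risk set at an event time")
                ll -= np.log(phi)
                if want_derivs:
                    s1 = (S1 - f * S1D) / phi
                    grad -= s1
                    hess -= (S2 - f * S2D) / phi - np.outer(s1, s1)
        return ll, grad, hess

    def loglik(self, beta):
        return self.loglik_grad_hess(beta, want_derivs=False)[0]


@dataclass
class TimeVaryingCoxResults:
    """Fitted Cox model: coefficients, covariance, likelihoods."""

    spec: CoxSpec
    names: list
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    n_intervals: int
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names)

    def linear_predictor(self, intervals: RiskIntervalTable) -> np.ndarray:
        X, names = _design(intervals, self.spec)
        if names != self.names:
            raise CoxError("interval table incompatible with fitted spec")
        return X @ self.coef

    def summary(self) -> str:
        tab = hazard_ratio_table(self)
        lines = [
            "Time-varying Cox model "
            f"({self.spec.ties_method} ties, {self.n_events} events, "
            f"{self.n_intervals} intervals)",
            f"  log-likelihood: {self.loglik:.3f} (null {self.loglik_null:.3f})",
            f"  {'term':>22} {'coef':>9} {'HR':>7} {'95% lo':>7} {'95% hi':>7}",
        ]
        for (_, r), b in zip(tab.iterrows(), self.coef):
            lines.append(
                f"  {r['name']:>22} {b:>9.4f} {r['HR']:>7.3f} "
                f"{r['lo']:>7.3f} {r['hi']:>7.3f}"
            )
        return "\n".join(lines)


class TimeVaryingCoxModel:
    """Counting-process Cox model, statsmodels-style.

    Parameters
    ----------
    intervals : RiskIntervalTable of (start, stop] rows.
    spec : CoxSpec naming covariates and their coding.
    """

    def __init__(self, intervals: RiskIntervalTable, spec: CoxSpec):
        self.intervals = intervals
        self.spec = spec
        d = intervals.data
        if d["event"].sum() < 1:
            raise CoxError("at least one event required")
        self.X, self.names = _design(intervals, spec)
        self._pl = _PartialLik(
            d["start"].to_numpy(float),
            d["stop"].to_numpy(float),
            d["event"].to_numpy(int),
            self.X,
            ties=spec.ties_method,
        )

    def loglik(self, beta) -> float:
        return self._pl.loglik(np.asarray(beta, dtype=float))

    def fit(self, maxiter: int = 100, tol: float = 1e-9,
            coef_limit: float = 20.0) -> TimeVaryingCoxResults:
        """Newton-Raphson with step-halving on the partial likelihood.

        Convergence is declared when the score vanishes (max |component|
        < ``tol``) or the log-likelihood stops changing. A coefficient
        exceeding ``coef_limit`` in magnitude raises a separation error
        naming the covariate; pass ``coef_limit=inf`` to tolerate
        boundary estimates (e.g. a factor level with no events, whose
        partial likelihood is monotone but converges to its supremum).
        """
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll0, _, _ = self._pl.loglik_grad_hess(beta)
        ll = ll0
        it = 0
        ll_prev = -np.inf
        if p > 0:
            for it in range(1, maxiter + 1):
                cur, grad, hess = self._pl.loglik_grad_hess(beta)
                if np.abs(grad).max() < tol or abs(cur - ll_prev) < 1e-11:
                    ll = cur
                    break
                ll_prev = cur
                try:
                    step = np.linalg.solve(-hess, grad)
                except np.linalg.LinAlgError:
                    # degenerate directions (e.g. a constant covariate)
                    # get a zero step via the pseudo-inverse
                    step = np.linalg.pinv(-hess) @ grad
                scale = 1.0
                for _ in range(30):
                    cand = beta + scale * step
                    new = self._pl.loglik(cand)
                    if new >= cur - 1e-12:
                        break
                    scale /= 2
                beta = beta + scale * step
                ll = self._pl.loglik(beta)
                if np.abs(beta).max() > coef_limit:
                    worst = self.names[int(np.argmax(np.abs(beta)))]
                    raise CoxError(
                        f"divergent coefficient for {worst!r} "
                        "(possible complete separation)"
                    )
            else:
                raise CoxError(
                    f"Newton-Raphson did not converge in {maxiter} iterations "
                    f"(last loglik {ll:.6f})"
                )
        _, _, hess = self._pl.loglik_grad_hess(beta)
        if p:
            try:
                cov = np.linalg.inv(-hess)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(-hess)
        else:
            cov = np.empty((0, 0))
        d = self.intervals.data
        return TimeVaryingCoxResults(
            spec=self.spec,
            names=self.names,
            coef=beta,
            cov=0.5 * (cov + cov.T),
            loglik=float(ll),
            loglik_null=float(ll0),
            n_events=int(d["event"].sum()),
            n_intervals=len(d),
            n_iter=it,
        )


def fit_cox(intervals: RiskIntervalTable, spec: CoxSpec,
            **kwargs) -> TimeVaryingCoxResults:
    """Convenience wrapper: build and fit a TimeVaryingCoxModel."""
    return TimeVaryingCoxModel(intervals, spec).fit(**kwargs)


def lr_statistic(full: TimeVaryingCoxResults, reduced: TimeVaryingCoxResults):
    """Likelihood-ratio information gain of ``full`` over nested ``reduced``.

    Returns (delta_lr, df) with delta_lr = 2 (ll_full - ll_reduced).
    """
    if not set(reduced.names) <= set(full.names):
        raise ValueError("models are not nested (reduced terms not in full)")
    if full.n_intervals != reduced.n_intervals or full.n_events != reduced.n_events:
        raise ValueError("models were fitted on different interval tables")
    return 2.0 * (full.loglik - reduced.loglik), len(full.names) - len(reduced.names)


def hazard_ratio_table(fit: TimeVaryingCoxResults, level: float = 0.95) -> pd.DataFrame:
    """Wald hazard ratios and confidence intervals per coefficient."""
    z = stats.norm.ppf(0.5 + level / 2)
    se = fit.se
    with np.errstate(over="ignore"):  # boundary coefs give inf bounds
        return pd.DataFrame(
            {
                "name": fit.names,
                "HR": np.exp(fit.coef),
                "lo": np.exp(fit.coef - z * se),
                "hi": np.exp(fit.coef + z * se),
            }
        )


# ---------------------------------------------------------------------
# the three density models + reduced (age + BMI) model
# ---------------------------------------------------------------------


@dataclass
class DensityModelSet:
    """The three density Cox models and the age+BMI reduced model."""

    intervals: RiskIntervalTable
    reduced: TimeVaryingCoxResults
    birads: TimeVaryingCoxResults          # model 1: 4-level factor, ref 2
    continuous: TimeVaryingCoxResults      # model 2: linear + quadratic
    categorical8: TimeVaryingCoxResults    # model 3: 8-level factor, ref 3

    def lr_table(self) -> pd.DataFrame:
        rows = []
        for label, fit in (
            ("birads", self.birads),
            ("continuous", self.continuous),
            ("categorical8", self.categorical8),
        ):
            dlr, df = lr_statistic(fit, self.reduced)
            rows.append({"model": label, "delta_lr": dlr, "df": df})
        return pd.DataFrame(rows)


def density_models(
    cohort: CohortTable,
    estimates: pd.DataFrame,
    mode: str = "time_varying",
    start_at_screen: int = 1,
    entry_lag: float = 0.5,
    ties_method: str = "efron",
    center_density: bool = False,
) -> DensityModelSet:
    """Fit the three density models plus the age+BMI-only reduced model.

    Covariates are updated at each screening examination
    (``mode='time_varying'``) or held at the ``start_at_screen``-th
    screen's values through follow-up (``mode='frozen_at_screen_k'``).
    With ``start_at_screen`` > 1, follow-up starts at that screen (women
    with fewer screens are excluded) and the baseline-age covariate is
    the age at that screen.

    Density enters the continuous model uncentred by default so hazard
    ratios read per unit; ``center_density`` subtracts the interval-rows
    mean first, which changes the coefficients' interpretation but not
    the fitted likelihood (the linear spans coincide up to constants
    that cancel in the partial likelihood).
    """
    if mode not in ("time_varying", "frozen_at_screen_k"):
        raise ValueError(f"unknown mode {mode!r}")
    s = cohort.screens.reset_index(drop=True)
    # keys rounded to 1e-9 yr: exam times that round-trip through CSV can
    # drift by one ulp, which would break an exact-equality merge
    left = s[["woman_id", "exam_time"]].assign(_t=s["exam_time"].round(9))
    right = estimates[["woman_id", "exam_time", "value", "category8"]].assign(
        _t=estimates["exam_time"].round(9)
    )
    est = left.merge(
        right.drop(columns="exam_time"),
        on=["woman_id", "_t"],
        how="left",
        validate="one_to_one",
    )
    if est["value"].isna().any():
        raise ValueError("estimates must cover every (woman, screen)")

    cov = pd.DataFrame(
        {
            "age_entry": s["age"],
            "bmi": s["bmi"],
            "birads": s["birads"].astype(int),
            "dens": est["value"],
            "cat8": est["category8"].astype(int),
        }
    )
    grp = s.groupby("woman_id", sort=False)
    k = start_at_screen
    # baseline-age covariate: age at the entry screen, constant per woman
    age_k = grp["age"].transform(lambda a: a.iloc[k - 1] if len(a) >= k else np.nan)
    cov["age_entry"] = age_k
    if mode == "frozen_at_screen_k":
        for c in ("bmi", "birads", "dens", "cat8"):
            cov[c] = cov.groupby(s["woman_id"], sort=False)[c].transform(
                lambda v: v.iloc[k - 1] if len(v) >= k else np.nan
            )
    intervals = build_risk_intervals(
        cohort, cov, entry_lag=entry_lag, baseline_screen=k
    )
    adj = (
        Covariate("age_entry", "continuous"),
        Covariate("bmi", "continuous"),
    )
    specs = {
        "reduced": CoxSpec(adj, ties_method),
        "birads": CoxSpec(adj + (Covariate("birads", "factor", ref=2),), ties_method),
        "continuous": CoxSpec(
            adj + (Covariate("dens", "continuous+quadratic"),), ties_method
        ),
        "categorical8": CoxSpec(
            adj + (Covariate("cat8", "factor", ref=3),), ties_method
        ),
    }
    # factor models tolerate boundary coefficients: at simulation scale a
    # low-risk category can have zero events, making its dummy's partial
    # likelihood monotone; the likelihood still converges so ΔLR is valid
    limits = {"reduced": 20.0, "birads": np.inf, "continuous": 20.0,
              "categorical8": np.inf}
    tables = dict.fromkeys(specs, intervals)
    if center_density:
        centred = intervals.data.copy()
        centred["dens"] = centred["dens"] - centred["dens"].mean()
        tables["continuous"] = RiskIntervalTable(centred)
    fits = {
        lbl: fit_cox(tables[lbl], sp, coef_limit=limits[lbl])
        for lbl, sp in specs.items()
    }
    return DensityModelSet(intervals=intervals, reduced=fits["reduced"],
                           birads=fits["birads"], continuous=fits["continuous"],
                           categorical8=fits["categorical8"])
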