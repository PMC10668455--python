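"""Sequential empirical-Bayes prediction of longitudinal breast density.

Given fitted mixed-model parameters, a woman's random intercept and
slope are predicted from her reading history by the posterior mean
(BLUP)

    b_hat = G Z' V^-1 (y - X beta),   V = Z G Z' + sigma^2 I,

and her continuous longitudinal density at a screen is the model
prediction x' beta + z' b_hat using the data observed to that point.
The estimate borrows strength from other women of the same age and BMI:
with no history it is the population mean surface, and with a long
history it shrinks toward her own readings. An eight-category measure
is derived by quantile-matching the baseline estimates to the baseline
BI-RADS distribution (equal split within each BI-RADS category).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import LmmParams, build_design

#: published cut points for the eight-category measure; valid only
#: together with a compatible parameter file — re-derive after refits
PAPER_DEFAULT_CUTS = (1.5, 2.0, 2.2, 2.6, 2.9, 3.2, 3.6)

ESTIMATE_COLUMNS = [
    "woman_id", "exam_time", "value", "eb_intercept", "eb_slope",
    "n_obs_used", "category8", "category4",
]


@dataclass(frozen=True)
class CutPoints:
    """Seven strictly increasing thresholds defining eight categories."""

    thresholds: tuple
    provenance: str = "derived"

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.shape != (7,) or not np.all(np.diff(t) > 0):
            raise ValueError("need 7 strictly increasing thresholds")
        object.__setattr__(self, "thresholds", tuple(t))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"thresholds": list(self.thresholds), "provenance": self.provenance},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CutPoints":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["thresholds"]), d.get("provenance", "derived"))

    @classmethod
    def paper_default(cls) -> "CutPoints":
        return cls(PAPER_DEFAULT_CUTS, provenance="paper_default")


def eb_posterior(X, Z, y, params: LmmParams):
    """Posterior mean and covariance of a woman's random effects.

    Parameters
    ----------
    X, Z, y : design matrices (n,7), (n,2) and readings (n,) of her
        history; n may be zero, giving the prior (0, G).

    Returns
    -------
    (b_hat, b_cov) : posterior mean (2,) and covariance (2,2)
        b_hat = G Z' V^-1 (y - X beta), b_cov = G - G Z' V^-1 Z G.
    """
    G, sigma2, beta = params.G, params.sigma2, params.beta
    X = np.asarray(X, dtype=float).reshape(-1, 7)
    Z = np.asarray(Z, dtype=float).reshape(-1, 2)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n == 0:
        return np.zeros(2), G.copy()
    V = Z @ G @ Z.T + sigma2 * np.eye(n)
    W = np.linalg.solve(V, np.column_stack([y - X @ beta, Z]))
    b_hat = G @ Z.T @ W[:, 0]
    b_cov = G - G @ Z.T @ W[:, 1:] @ G
    return b_hat, 0.5 * (b_cov + b_cov.T)


def predict_longitudinal_density(history, age_t, bmi_t, params: LmmParams):
    """Continuous longitudinal density at (age_t, bmi_t) given a history.

    ``history`` is a sequence of (age, bmi, birads) triples observed up
    to the prediction time (may be empty). The returned value
    x(age_t, bmi_t)' beta + z(age_t)' b_hat is real-valued and not
    clipped to [1, 4]; the categorical measure absorbs the tails.
    """
    if len(history):
        ages, bmis, ys = (np.asarray(v, dtype=float) for v in zip(*history))
        X, Z = build_design(ages, bmis, params.centering)
    else:
        X = np.empty((0, 7)); Z = np.empty((0, 2)); ys = np.empty(0)
    b_hat, _ = eb_posterior(X, Z, ys, params)
    x, z = build_design(age_t, bmi_t, params.centering)
    return float(x[0] @ params.beta + z[0] @ b_hat)


def categorize(value, cuts: CutPoints):
    """Map continuous density to category 1-8 (left-closed intervals).

    A value exactly on a threshold belongs to the upper category.
    """
    t = np.asarray(cuts.thresholds)
    cat = np.searchsorted(t, np.asarray(value, dtype=float), side="right") + 1
    return int(cat) if np.isscalar(value) else cat.astype(int)


def derive_cutpoints(baseline_values, baseline_birads) -> CutPoints:
    """Quantile-match eight-category cut points to baseline BI-RADS.

    Thresholds are the empirical quantiles (inverse CDF, lower value at
    ties) of the baseline continuous estimates at cumulative
    probabilities (p1/2, p1, p1+p2/2, ..., p1+p2+p3+p4/2) where p1..p4
    are the baseline BI-RADS proportions, so categories 1-2 together
    match BI-RADS A with an equal split inside, and so on.
    """
    v = np.asarray(baseline_values, dtype=float)
    b = np.asarray(baseline_birads)
    if len(v) != len(b):
        raise ValueError("values and birads must have the same length")
    if len(v) < 8:
        raise ValueError("need at least 8 baseline observations")
    p = np.array([(b == k).mean() for k in (1, 2, 3, 4)])
    cum = np.concatenate([[0.0], np.cumsum(p)])
    probs = []
    for k in range(4):
        probs.append(cum[k] + p[k] / 2)
        probs.append(cum[k + 1])
    probs = np.clip(np.array(probs[:-1]), 0.0, 1.0)
    q = np.quantile(v, probs, method="inverted_cdf")
    # degenerate BI-RADS distributions can repeat quantiles; nudge to
    # keep the thresholds strictly increasing (documented degeneracy)
    for i in range(1, 7):
        if q[i] <= q[i - 1]:
            q[i] = np.nextafter(q[i - 1], np.inf)
    return CutPoints(tuple(q), provenance="derived")


def sequential_estimates(cohort, params: LmmParams, cuts: CutPoints | None = None,
                         inclusive: bool = True) -> pd.DataFrame:
    """Empirical-Bayes density estimate at every (woman, screen).

    For each woman, the estimate at her k-th screen uses her screens
    1..k (inclusive of the current reading by default; ``inclusive=False``
    uses screens 1..k-1, a sensitivity variant). No lookahead: appending
    later screens never changes earlier estimates.

    Returns a DataFrame with columns woman_id, exam_time, value,
    eb_intercept, eb_slope, n_obs_used, category8, category4. Categories
    use ``cuts`` (default: the published cut points).
    """
    if cuts is None:
        cuts = CutPoints.paper_default()
    s = cohort.screens
    if s["birads"].isna().any() or s["bmi"].isna().any():
        raise ValueError("cohort must be preprocessed (no missing bmi/birads)")
    X, Z = build_design(s["age"].to_numpy(), s["bmi"].to_numpy(), params.centering)
    y = s["birads"].to_numpy(float)
    labels = s["woman_id"].to_numpy()
    splits = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    blocks = np.split(np.arange(len(labels)), splits)

    G, sigma2, beta = params.G, params.sigma2, params.beta
    n_rows = len(labels)
    value = np.empty(n_rows)
    eb = np.zeros((n_rows, 2))

    # batch across women by history length k
    by_len: dict[int, list] = {}
    for blk in blocks:
        by_len.setdefault(len(blk), []).append(blk)
    max_len = max(by_len) if by_len else 0
    for k in range(1, max_len + 1):
        rows = np.array(
            [blk[:k] for n, blks in by_len.items() if n >= k for blk in blks]
        )  # (m, k) history row indices; last column is the current screen
        cur = rows[:, -1]
        h = rows if inclusive else rows[:, :-1]
        m = rows.shape[0]
        if h.shape[1] == 0:
            b_hat = np.zeros((m, 2))
        else:
            Zh = Z[h]                      # (m, k, 2)
            Xh = X[h]
            rh = y[h] - Xh @ beta
            V = Zh @ G @ np.swapaxes(Zh, 1, 2) + sigma2 * np.eye(h.shape[1])
            w = np.linalg.solve(V, rh[..., None])[..., 0]
            b_hat = np.einsum("ab,mkb,mk->ma", G, Zh, w)
        value[cur] = X[cur] @ beta + (Z[cur] * b_hat).sum(axis=1)
        eb[cur] = b_hat

    n_obs_used = np.concatenate([np.arange(1, len(blk) + 1) for blk in blocks])
    if not inclusive:
        n_obs_used = n_obs_used - 1
    cat8 = categorize(value, cuts)
    out = pd.DataFrame(
        {
            "woman_id": labels,
            "exam_time": s["exam_time"].to_numpy(),
            "value": value,
            "eb_intercept": eb[:, 0],
            "eb_slope": eb[:, 1],
            "n_obs_used": n_obs_used,
            "category8": cat8,
            "category4": np.ceil(cat8 / 2).astype(int),
        }
    )
    return out
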