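"""Yearly at-risk concordance and screen-to-screen risk stability.

Discrimination is summarised by a windowed incident/dynamic concordance
index: within each yearly window starting at 0.5 years of follow-up,
every (event, at-risk) pair is scored by whether the case's current
linear predictor exceeds the at-risk subject's (ties count one half),
and the yearly values are averaged weighted by the number of comparable
pairs. Model comparisons bootstrap whole women (clusters). Stability of
a density measure is the fraction of women whose normalised relative
risk moves outside the 4/5 to 5/4 range between their second and third
mammograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import RiskIntervalTable
from .cox import TimeVaryingCoxResults

STABLE_LO, STABLE_HI = 4.0 / 5.0, 5.0 / 4.0


@dataclass
class ConcordanceCurve:
    """Per-window concordance values and their pair-weighted mean."""

    eval_times: np.ndarray
    yC: np.ndarray          # NaN where the window had no events
    se: np.ndarray
    n_pairs: np.ndarray
    mean_yC: float
    n_dropped_windows: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.eval_times, "yC": self.yC, "se": self.se,
             "n_pairs": self.n_pairs}
        )


def _event_concordance(start, stop, event, lp):
    """Per-event pair counts: (event_time, n_pairs, concordant_weight)."""
    ev_idx = np.flatnonzero(event == 1)
    out = []
    for i in ev_idx:
        s = stop[i]
        at_risk = (start < s) & (stop >= s) & ~((event == 1) & (stop == s))
        m = int(at_risk.sum())
        if m == 0:
            out.append((s, 0, 0.0))
            continue
        others = lp[at_risk]
        conc = float((lp[i] > others).sum()) + 0.5 * float((lp[i] == others).sum())
        out.append((s, m, conc))
    return out


def yearly_concordance(
    intervals: RiskIntervalTable,
    linear_predictor,
    window: float = 1.0,
    first_window_start: float = 0.5,
    weighting: str = "pairs",
) -> ConcordanceCurve:
    """At-risk concordance per yearly window, starting at 0.5 years.

    For each window [t, t + window): over events at time s in the
    window, pairs (event i, subject j at risk at s with no event at s)
    are concordant when i's current linear predictor exceeds j's, tied
    pairs count one half. yC(t) is the concordant-pair fraction; the
    mean is pair-count weighted (``weighting='equal'`` averages windows
    equally instead). Windows without events are dropped from the mean.
    The per-window standard error treats events as independent clusters
    of pairs (U-statistic style).
    """
    if weighting not in ("pairs", "equal"):
        raise ValueError("weighting must be 'pairs' or 'equal'")
    d = intervals.data
    start = d["start"].to_numpy(float)
    stop = d["stop"].to_numpy(float)
    event = d["event"].to_numpy(int)
    lp = np.asarray(linear_predictor, dtype=float)
    if len(lp) != len(d):
        raise ValueError("linear_predictor must have one value per interval row")

    per_event = _event_concordance(start, stop, event, lp)
    t_max = stop.max() if len(stop) else first_window_start
    times = np.arange(first_window_start, t_max + 1e-12, window)
    yC = np.full(len(times), np.nan)
    se = np.full(len(times), np.nan)
    n_pairs = np.zeros(len(times), dtype=int)
    for w, t in enumerate(times):
        ev = [(m, c) for (s, m, c) in per_event if t <= s < t + window and m > 0]
        if not ev:
            continue
        ms = np.array([m for m, _ in ev], dtype=float)
        cs = np.array([c for _, c in ev], dtype=float)
        n_pairs[w] = int(ms.sum())
        yC[w] = cs.sum() / ms.sum()
        frac = cs / ms
        se[w] = np.sqrt(np.sum(ms**2 * (frac - yC[w]) ** 2)) / ms.sum()
    ok = ~np.isnan(yC)
    if not ok.any():
        mean = np.nan
    elif weighting == "pairs":
        mean = float(np.sum(yC[ok] * n_pairs[ok]) / np.sum(n_pairs[ok]))
    else:
        mean = float(np.mean(yC[ok]))
    return ConcordanceCurve(
        eval_times=times, yC=yC, se=se, n_pairs=n_pairs, mean_yC=mean,
        n_dropped_windows=int((~ok).sum()),
    )


def _mean_yc_rows(start, stop, event, lp, window, first_window_start):
    """Pair-weighted mean concordance on raw row arrays (bootstrap core)."""
    per_event = _event_concordance(start, stop, event, lp)
    if not per_event:
        return np.nan
    # pair-weighted mean over windows == pooled over events
    total_m = sum(m for _, m, _ in per_event)
    total_c = sum(c for _, _, c in per_event)
    return total_c / total_m if total_m else np.nan


@dataclass
class ConcordanceComparison:
    diff: float                 # mean_yC(A) - mean_yC(B)
    ci: tuple
    n_boot: int
    warning: str | None = None


def compare_models_concordance(
    intervals: RiskIntervalTable,
    lp_a,
    lp_b,
    n_boot: int = 1000,
    seed: int = 0,
    window: float = 1.0,
    first_window_start: float = 0.5,
) -> ConcordanceComparison:
    """Bootstrap comparison of two models' mean concordance.

    Resamples whole women with replacement (intervals within a woman
    are dependent), recomputes the pair-weighted mean-yC difference on
    each resample, and reports the percentile confidence interval.
    Deterministic under a fixed seed.
    """
    d = intervals.data
    start = d["start"].to_numpy(float)
    stop = d["stop"].to_numpy(float)
    event = d["event"].to_numpy(int)
    a = np.asarray(lp_a, dtype=float)
    b = np.asarray(lp_b, dtype=float)
    warning = None
    if n_boot < 100:
        warning = f"n_boot={n_boot} < 100; interval may be unstable"

    ids = d["woman_id"].to_numpy()
    uniq, inv = np.unique(ids, return_inverse=True)
    row_lists = [np.flatnonzero(inv == k) for k in range(len(uniq))]
    diff_obs = _mean_yc_rows(start, stop, event, a, window, first_window_start) - \
        _mean_yc_rows(start, stop, event, b, window, first_window_start)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for r in range(n_boot):
        take = rng.integers(0, len(uniq), size=len(uniq))
        rows = np.concatenate([row_lists[k] for k in take])
        diffs[r] = _mean_yc_rows(
            start[rows], stop[rows], event[rows], a[rows], window,
            first_window_start,
        ) - _mean_yc_rows(
            start[rows], stop[rows], event[rows], b[rows], window,
            first_window_start,
        )
    lo, hi = np.nanpercentile(diffs, [2.5, 97.5])
    return ConcordanceComparison(
        diff=float(diff_obs), ci=(float(lo), float(hi)), n_boot=n_boot,
        warning=warning,
    )


@dataclass
class StabilityResult:
    """Screen-2-to-screen-3 relative-risk stability of a density measure."""

    woman_ids: np.ndarray
    rr2: np.ndarray            # normalised to mean 1 across women
    rr3: np.ndarray
    rr_ratio: np.ndarray       # rr3 / rr2
    frac_outside: float        # outside [4/5, 5/4]
    cdf_points: np.ndarray     # (ratio, cumulative fraction) pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"woman_id": self.woman_ids, "rr2": self.rr2, "rr3": self.rr3,
             "ratio": self.rr_ratio}
        )


def _density_rr(values, fit: TimeVaryingCoxResults, measure: str):
    coef = fit.coef_series()
    v = np.asarray(values)
    if measure == "birads":
        rr = np.ones(len(v))
        for lv in (1, 2, 3, 4):
            name = f"birads={lv:g}"
            if name in coef.index:
                rr[v.astype(float) == lv] = np.exp(coef[name])
        return rr
    if measure == "longitudinal":
        v = v.astype(float)
        return np.exp(coef["dens"] * v + coef["dens^2"] * v**2)
    raise ValueError("measure must be 'birads' or 'longitudinal'")


def stability_analysis(
    values_screen2: pd.Series,
    values_screen3: pd.Series,
    fit: TimeVaryingCoxResults,
    measure: str,
) -> StabilityResult:
    """Relative-risk stability between the second and third mammogram.

    ``values_screen2/3`` are per-woman density values (BI-RADS readings
    or continuous longitudinal estimates) indexed by woman_id, for the
    subgroup with at least three screens. The fitted Cox model supplies
    the density coefficients; per-woman relative risks at each screen
    are normalised to mean 1 across women, and a woman counts as
    unstable when RR3/RR2 leaves [4/5, 5/4].
    """
    v2 = pd.Series(values_screen2)
    v3 = pd.Series(values_screen3)
    if not v2.index.equals(v3.index):
        v3 = v3.reindex(v2.index)
        if v3.isna().any():
            raise ValueError("every woman needs values at both screens")
    rr2 = _density_rr(v2.to_numpy(), fit, measure)
    rr3 = _density_rr(v3.to_numpy(), fit, measure)
    rr2 = rr2 / rr2.mean()
    rr3 = rr3 / rr3.mean()
    ratio = rr3 / rr2
    frac = float(((ratio < STABLE_LO) | (ratio > STABLE_HI)).mean())
    srt = np.sort(ratio)
    cdf = np.column_stack([srt, np.arange(1, len(srt) + 1) / len(srt)])
    return StabilityResult(
        woman_ids=v2.index.to_numpy(), rr2=rr2, rr3=rr3, rr_ratio=ratio,
        frac_outside=frac, cdf_points=cdf,
    )
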