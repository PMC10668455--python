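"""Screening-cohort data model, CSV I/O, preprocessing and risk intervals.

A cohort is a pair of long-format tables: per-screen observations
(woman id, exam time, age, BMI, BI-RADS density 1-4) and one outcome row
per woman (exit time, invasive-cancer indicator, censoring reason).
Survival analysis consumes the cohort as a counting-process table of
(start, stop] risk intervals with piecewise-constant covariates updated
at each screening examination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCREEN_COLUMNS = ["woman_id", "exam_time", "age", "bmi", "birads"]
OUTCOME_COLUMNS = ["woman_id", "exit_time", "event", "censor_reason"]
CENSOR_REASONS = {"age75", "admin_end", "dcis", "death", "disenrolled", "none"}

#: tolerance (years) for consistency of age gaps with exam-time gaps
AGE_TIME_TOL = 0.1


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


class ImputationError(ValueError):
    """BMI imputation cannot proceed (an occupied age bin has no data)."""


@dataclass
class CohortTable:
    """Validated long-format screening cohort.

    Parameters
    ----------
    screens : DataFrame with columns woman_id, exam_time, age, bmi, birads,
        sorted by (woman_id, exam_time). ``bmi`` and ``birads`` may be NaN.
    outcomes : DataFrame with columns woman_id, exit_time, event,
        censor_reason; exactly one row per woman appearing in ``screens``.
    """

    screens: pd.DataFrame
    outcomes: pd.DataFrame
    #: permit real-valued density readings in the birads column (used by
    #: the simulator's continuous-outcome mode); default is strict 1-4
    allow_continuous: bool = False

    def __post_init__(self) -> None:
        self.screens = (
            self.screens[SCREEN_COLUMNS]
            .sort_values(["woman_id", "exam_time"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.outcomes = (
            self.outcomes[OUTCOME_COLUMNS]
            .sort_values("woman_id", kind="mergesort")
            .reset_index(drop=True)
        )
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        s, o = self.screens, self.outcomes
        if s.duplicated(["woman_id", "exam_time"]).any():
            bad = s.loc[s.duplicated(["woman_id", "exam_time"]), "woman_id"].iloc[0]
            raise CohortValidationError(
                f"duplicate (woman_id, exam_time) for woman {bad!r}"
            )
        br = s["birads"].dropna()
        if len(br) and not self.allow_continuous:
            vals = br.to_numpy(float)
            ok = np.isin(vals, [1.0, 2.0, 3.0, 4.0])
            if not ok.all():
                bad = s.loc[br.index[np.flatnonzero(~ok)[0]], "woman_id"]
                raise CohortValidationError(
                    f"birads outside {{1,2,3,4}} for woman {bad!r}"
                )
        for wid, grp in s.groupby("woman_id", sort=False):
            t = grp["exam_time"].to_numpy(float)
            a = grp["age"].to_numpy(float)
            if len(t) > 1:
                dt, da = np.diff(t), np.diff(a)
                if (dt <= 0).any():
                    raise CohortValidationError(
                        f"exam_time not strictly increasing for woman {wid!r}"
                    )
                if (da <= 0).any():
                    raise CohortValidationError(
                        f"age not strictly increasing for woman {wid!r}"
                    )
                if np.abs(da - dt).max() > AGE_TIME_TOL:
                    raise CohortValidationError(
                        f"age gaps inconsistent with exam-time gaps for woman {wid!r}"
                    )
        women = set(s["woman_id"])
        if o["woman_id"].duplicated().any() or set(o["woman_id"]) != women:
            raise CohortValidationError(
                "outcomes must contain exactly one row per woman with screens"
            )
        bad_reason = ~o["censor_reason"].isin(CENSOR_REASONS)
        if bad_reason.any():
            raise CohortValidationError(
                f"unknown censor_reason {o.loc[bad_reason, 'censor_reason'].iloc[0]!r}"
            )
        if ((o["event"] == 1) & (o["censor_reason"] != "none")).any():
            raise CohortValidationError("event=1 requires censor_reason='none'")
        first = s.groupby("woman_id")["exam_time"].min()
        merged = o.set_index("woman_id")["exit_time"]
        late = merged.loc[first.index] <= first
        if late.any():
            raise CohortValidationError(
                f"exit_time not after first exam for woman {late.index[late][0]!r}"
            )

    # -- convenience ---------------------------------------------------
    @property
    def n_women(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_screens(self) -> int:
        return self.screens.shape[0]

    def baseline(self) -> pd.DataFrame:
        """One row per woman: her earliest screen."""
        return self.screens.groupby("woman_id", sort=True).first().reset_index()

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.screens.copy(), self.outcomes.copy(), self.allow_continuous
        )


def read_cohort(screens_path, outcomes_path,
                allow_continuous: bool = False) -> CohortTable:
    """Read and validate a cohort from two CSV files.

    Empty fields are treated as missing. Raises ``CohortValidationError``
    on malformed content. ``allow_continuous`` admits real-valued
    density readings (simulator continuous-outcome files).
    """
    screens = pd.read_csv(screens_path)
    outcomes = pd.read_csv(outcomes_path)
    for name, df, cols in (
        ("screens", screens, SCREEN_COLUMNS),
        ("outcomes", outcomes, OUTCOME_COLUMNS),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortValidationError(f"{name} file missing columns {missing}")
    # calendar dates are accepted for the time columns and converted to
    # years since the earliest exam date (days / 365.25)
    if screens["exam_time"].dtype == object:
        exam = pd.to_datetime(screens["exam_time"], errors="raise")
        origin = exam.min()
        screens["exam_time"] = (exam - origin).dt.days / 365.25
        if outcomes["exit_time"].dtype == object:
            exit_d = pd.to_datetime(outcomes["exit_time"], errors="raise")
            outcomes["exit_time"] = (exit_d - origin).dt.days / 365.25
    if "censor_reason" in outcomes:
        outcomes["censor_reason"] = outcomes["censor_reason"].fillna("none")
    return CohortTable(screens, outcomes, allow_continuous)


def write_cohort(cohort: CohortTable, screens_path, outcomes_path) -> None:
    cohort.screens.to_csv(screens_path, index=False)
    cohort.outcomes.to_csv(outcomes_path, index=False)


def apply_eligibility(
    cohort: CohortTable,
    min_age: float = 40.0,
    max_age: float = 73.0,
    min_followup: float = 0.5,
) -> CohortTable:
    """Apply the screening-cohort eligibility filters.

    Screens missing a BI-RADS reading are dropped first; each woman's
    baseline is then her earliest remaining screen. Women whose baseline
    age falls outside [min_age, max_age], or whose follow-up from
    baseline is shorter than ``min_followup`` years, are removed
    entirely. Idempotent.
    """
    s = cohort.screens[cohort.screens["birads"].notna()]
    if s.empty:
        empty_s = cohort.screens.iloc[0:0]
        empty_o = cohort.outcomes.iloc[0:0]
        return CohortTable(empty_s, empty_o, cohort.allow_continuous)
    base = s.groupby("woman_id").agg(
        base_age=("age", "first"), base_time=("exam_time", "first")
    )
    exit_t = cohort.outcomes.set_index("woman_id")["exit_time"]
    keep = base.index[
        (base["base_age"] >= min_age)
        & (base["base_age"] <= max_age)
        & (exit_t.loc[base.index] - base["base_time"] >= min_followup)
    ]
    s = s[s["woman_id"].isin(keep)]
    o = cohort.outcomes[cohort.outcomes["woman_id"].isin(keep)]
    return CohortTable(
        s.reset_index(drop=True), o.reset_index(drop=True), cohort.allow_continuous
    )


def winsorize_bmi(bmi, lo: float = 15.0, hi: float = 35.0):
    """Cap BMI at fixed bounds (default 15 and 35 kg/m²).

    Scalar or array; non-positive values raise ``ValueError`` so data
    errors do not silently become the lower bound.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("BMI must be positive")
    out = np.clip(arr, lo, hi)
    return float(out) if np.isscalar(bmi) else out


def impute_bmi(cohort: CohortTable, age_bin_width: float = 5.0,
               min_age: float = 40.0) -> CohortTable:
    """Fill missing BMI: baseline by age-bin mean, follow-up by LOCF.

    Missing baseline BMI is replaced by the mean observed baseline BMI
    among women whose baseline age falls in the same fixed-width age bin
    (bins of ``age_bin_width`` years starting at ``min_age``). Missing
    follow-up BMI is carried forward from the woman's last recorded
    value; women with no BMI ever observed use their baseline bin mean
    at every screen. The result has no missing BMI.
    """
    s = cohort.screens.copy()
    base = s.groupby("woman_id").first()
    bin_idx = np.floor((base["age"] - min_age) / age_bin_width).astype(int)
    bin_means = base.groupby(bin_idx)["bmi"].mean()

    def _baseline_fill(wid):
        b = bin_idx.loc[wid]
        m = bin_means.get(b, np.nan)
        if np.isnan(m):
            raise ImputationError(
                f"no observed baseline BMI in age bin {b} "
                f"[{min_age + b * age_bin_width:.0f}, "
                f"{min_age + (b + 1) * age_bin_width:.0f})"
            )
        return m

    out = []
    for wid, grp in s.groupby("woman_id", sort=False):
        bmi = grp["bmi"].to_numpy(float).copy()
        if np.isnan(bmi[0]):
            bmi[0] = _baseline_fill(wid)
        for k in range(1, len(bmi)):
            if np.isnan(bmi[k]):
                bmi[k] = bmi[k - 1]
        g = grp.copy()
        g["bmi"] = bmi
        out.append(g)
    s = pd.concat(out) if out else s
    return CohortTable(
        s.reset_index(drop=True), cohort.outcomes.copy(), cohort.allow_continuous
    )


@dataclass
class RiskIntervalTable:
    """Counting-process rows (woman_id, start, stop, event, covariates).

    ``data`` holds one row per risk interval; covariate columns are every
    column other than woman_id/start/stop/event. Within a woman the rows
    are contiguous, non-overlapping, and at most the last carries
    event = 1.
    """

    data: pd.DataFrame

    RESERVED = ("woman_id", "start", "stop", "event")

    def __post_init__(self) -> None:
        d = self.data
        if (d["start"] >= d["stop"]).any():
            raise CohortValidationError("risk interval with start >= stop")
        for wid, grp in d.groupby("woman_id", sort=False):
            ev = grp["event"].to_numpy()
            if ev.sum() > 1 or (ev.sum() == 1 and ev[-1] != 1):
                raise CohortValidationError(
                    f"event must be unique and last for woman {wid!r}"
                )
            st = grp["start"].to_numpy()
            sp = grp["stop"].to_numpy()
            if len(grp) > 1 and not np.allclose(st[1:], sp[:-1]):
                raise CohortValidationError(
                    f"non-contiguous intervals for woman {wid!r}"
                )

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def person_time(self) -> float:
        return float((self.data["stop"] - self.data["start"]).sum())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def build_risk_intervals(
    cohort: CohortTable,
    covariate_source: pd.DataFrame,
    entry_lag: float = 0.5,
    baseline_screen: int = 1,
) -> RiskIntervalTable:
    """Expand a cohort into (start, stop] risk intervals.

    The time scale is follow-up since each woman's baseline screen
    (``baseline_screen``-th screen, 1-indexed; women with fewer screens
    are excluded). Each woman enters at ``entry_lag`` years of follow-up.
    Covariates are piecewise constant, taking at time t the values of
    her latest screen at or before t; boundaries fall at screen times
    and at exit. The final interval carries the event indicator. Women
    whose follow-up is <= entry_lag contribute nothing.

    Parameters
    ----------
    covariate_source : DataFrame indexed like the screens table rows
        (same length and order as cohort.screens) whose columns are the
        covariates to attach.
    """
    if len(covariate_source) != len(cohort.screens):
        raise ValueError(
            "covariate_source must supply one row per screen "
            f"({len(covariate_source)} != {len(cohort.screens)})"
        )
    cov = covariate_source.reset_index(drop=True)
    s = cohort.screens.reset_index(drop=True)
    exit_map = cohort.outcomes.set_index("woman_id")[["exit_time", "event"]]

    rows = []
    for wid, grp in s.groupby("woman_id", sort=True):
        if len(grp) < baseline_screen:
            continue
        idx = grp.index.to_numpy()[baseline_screen - 1:]
        t0 = s.loc[idx[0], "exam_time"]
        fu_times = s.loc[idx, "exam_time"].to_numpy(float) - t0
        exit_fu = float(exit_map.loc[wid, "exit_time"]) - t0
        event = int(exit_map.loc[wid, "event"])
        if exit_fu <= entry_lag:
            continue
        # interval boundaries: entry, screen times after entry, exit
        bounds = [entry_lag]
        bounds += [t for t in fu_times if entry_lag < t < exit_fu]
        bounds.append(exit_fu)
        for a, b in zip(bounds[:-1], bounds[1:]):
            # covariates from latest screen at or before interval start
            k = int(np.searchsorted(fu_times, a, side="right") - 1)
            k = max(k, 0)
            row = {"woman_id": wid, "start": a, "stop": b, "event": 0}
            row.update(cov.loc[idx[k]].to_dict())
            rows.append(row)
        if rows and event:
            rows[-1]["event"] = 1
    if not rows:
        empty = pd.DataFrame(
            columns=["woman_id", "start", "stop", "event"]
            + list(cov.columns)
        )
        return RiskIntervalTable(empty)
    return RiskIntervalTable(pd.DataFrame(rows))
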