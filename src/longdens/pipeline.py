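"""High-level pipeline helpers: preprocess, fit, predict, evaluate.

These glue functions run the full study workflow on a cohort —
eligibility filtering, BMI imputation and winsorization, mixed-model
fitting, sequential empirical-Bayes estimation, cut-point derivation,
the three density Cox models, concordance and stability — and are what
the command-line interface and the simulation-study entry points call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, apply_eligibility, impute_bmi, winsorize_bmi
from .concordance import stability_analysis, yearly_concordance
from .cox import DensityModelSet, density_models, lr_statistic
from .empirical_bayes import CutPoints, derive_cutpoints, sequential_estimates
from .lmm import DensityMixedModel, DensityMixedModelResults
from .simulate import SimConfig, simulate_cohort


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds from one base seed.

    Uses numpy's SeedSequence so replicate streams are independent;
    values stay below 2**31.
    """
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def preprocess(
    cohort: CohortTable,
    min_age: float = 40.0,
    max_age: float = 73.0,
    min_followup: float = 0.5,
    age_bin_width: float = 5.0,
    winsor_lo: float = 15.0,
    winsor_hi: float = 35.0,
) -> CohortTable:
    """Eligibility filter, BMI imputation, winsorization — in that order."""
    out = apply_eligibility(cohort, min_age, max_age, min_followup)
    if out.n_women == 0:
        return out
    out = impute_bmi(out, age_bin_width, min_age)
    out.screens["bmi"] = winsorize_bmi(
        out.screens["bmi"].to_numpy(), winsor_lo, winsor_hi
    )
    return out


def fit_and_estimate(cohort: CohortTable, centering: float = 10.0):
    """ML mixed-model fit, derived cut points, sequential EB estimates.

    Returns (results, cuts, estimates).
    """
    res = DensityMixedModel(cohort, centering=centering).fit()
    est = sequential_estimates(cohort, res.params)
    base = est.groupby("woman_id").first()
    base_birads = cohort.screens.groupby("woman_id")["birads"].first()
    if cohort.allow_continuous:
        # continuous-outcome cohorts have no BI-RADS distribution to
        # match; categorise against rounded baseline readings instead
        bb = np.clip(np.round(base_birads.loc[base.index].to_numpy()), 1, 4)
    else:
        bb = base_birads.loc[base.index].to_numpy()
    cuts = derive_cutpoints(base["value"].to_numpy(), bb)
    est = sequential_estimates(cohort, res.params, cuts=cuts)
    return res, cuts, est


def screen_values(cohort: CohortTable, estimates: pd.DataFrame, screen_no: int,
                  min_screens: int = 3):
    """Per-woman values at a given screen for the >=min_screens subgroup.

    Returns (birads, longitudinal) as Series indexed by woman_id.
    """
    s = cohort.screens
    counts = s.groupby("woman_id")["exam_time"].transform("size")
    order = s.groupby("woman_id").cumcount()
    sel = s[(counts >= min_screens) & (order == screen_no - 1)]
    ei = estimates.set_index(
        ["woman_id", estimates["exam_time"].round(9)]
    )
    vals = ei.loc[
        list(zip(sel["woman_id"], sel["exam_time"].round(9))), "value"
    ].to_numpy()
    idx = sel["woman_id"].to_numpy()
    return (
        pd.Series(sel["birads"].to_numpy(), index=idx),
        pd.Series(vals, index=idx),
    )


@dataclass
class ReplicateResult:
    """Summary quantities of one simulated-cohort evaluation."""

    n_women: int
    n_events: int
    delta_lr_birads: float
    delta_lr_continuous: float
    delta_lr_categorical8: float
    df_birads: int
    df_continuous: int
    df_categorical8: int
    mean_yc_birads: float
    mean_yc_continuous: float
    frac_outside_birads: float
    frac_outside_longitudinal: float
    models: DensityModelSet
    lmm: DensityMixedModelResults
    cuts: CutPoints
    estimates: pd.DataFrame
    cohort: CohortTable


def evaluate_cohort(cohort: CohortTable, centering: float = 10.0,
                    entry_lag: float = 0.5,
                    start_at_screen: int = 1,
                    mode: str = "time_varying") -> ReplicateResult:
    """Fit, predict, and evaluate the three density models on a cohort."""
    res, cuts, est = fit_and_estimate(cohort, centering)
    mset = density_models(
        cohort, est, mode=mode, start_at_screen=start_at_screen,
        entry_lag=entry_lag,
    )
    dlr_b, df_b = lr_statistic(mset.birads, mset.reduced)
    dlr_c, df_c = lr_statistic(mset.continuous, mset.reduced)
    dlr_8, df_8 = lr_statistic(mset.categorical8, mset.reduced)
    lp_b = mset.birads.linear_predictor(mset.intervals)
    lp_c = mset.continuous.linear_predictor(mset.intervals)
    yc_b = yearly_concordance(mset.intervals, lp_b).mean_yC
    yc_c = yearly_concordance(mset.intervals, lp_c).mean_yC
    b2, l2 = screen_values(cohort, est, 2)
    b3, l3 = screen_values(cohort, est, 3)
    if len(b2):
        fo_b = stability_analysis(b2, b3, mset.birads, "birads").frac_outside
        fo_l = stability_analysis(
            l2, l3, mset.continuous, "longitudinal"
        ).frac_outside
    else:
        fo_b = fo_l = np.nan
    return ReplicateResult(
        n_women=cohort.n_women,
        n_events=mset.reduced.n_events,
        delta_lr_birads=dlr_b,
        delta_lr_continuous=dlr_c,
        delta_lr_categorical8=dlr_8,
        df_birads=df_b,
        df_continuous=df_c,
        df_categorical8=df_8,
        mean_yc_birads=yc_b,
        mean_yc_continuous=yc_c,
        frac_outside_birads=fo_b,
        frac_outside_longitudinal=fo_l,
        models=mset,
        lmm=res,
        cuts=cuts,
        estimates=est,
        cohort=cohort,
    )


def simulate_and_evaluate(n_women: int, seed: int,
                          **sim_overrides) -> ReplicateResult:
    """One full simulation-study replicate: generate, preprocess, evaluate."""
    cfg = SimConfig(n_women=n_women, seed=seed, **sim_overrides)
    cohort, _ = simulate_cohort(cfg)
    cohort = preprocess(cohort)
    return evaluate_cohort(cohort)
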