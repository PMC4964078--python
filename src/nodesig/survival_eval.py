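"""Prognostic value of a score against DMFS: Cox PH, Harrell's C, KM, log-rank.

Scores are standardized to unit SD before the Cox fit so hazard ratios are
per-SD and comparable across signatures. Scores enter in their native
orientation (the fit records it); concordance is computed on the
risk orientation, so C > 0.5 always means "prognostic in the claimed
direction". Ties in event times are handled with the Efron correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

from .cohort_data import CohortTable
from .errors import (
    ConvergenceError,
    DegenerateSplitError,
    InvalidInputError,
    UndefinedStatisticError,
)
from .signature_scoring import ScoreVector


@dataclass
class SurvivalFit:
    """Univariate Cox fit of a (unit-SD) score against DMFS."""

    signature: str
    stratum: str
    n: int
    n_events: int
    beta: float  # log hazard per SD of score, native orientation
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    concordance: float
    orientation: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class KmCurve:
    """Median-split product-limit curves with the two-group log-rank test."""

    times: dict  # group -> event-time grid
    survival: dict  # group -> survival estimates
    at_risk: dict  # group -> at-risk counts at each grid time
    group_sizes: dict
    chi2: float
    p: float
    cutpoint: float


def _align(score: ScoreVector, cohort: CohortTable):
    ids = [s for s in cohort.sample_ids if s in score.scores.index]
    if len(ids) == 0:
        raise InvalidInputError("score and cohort share no samples")
    sub = cohort.subset(ids)
    return score.scores.loc[ids].astype(float), sub.durations(), sub.events()


def concordance_index(score: ScoreVector, cohort: CohortTable) -> float:
    """Harrell's concordance between a risk-oriented score and censored DMFS.

    Over comparable pairs (the earlier time carries an event), counts the
    fraction where the higher-risk score belongs to the earlier event; score
    ties count 0.5. Orientation is applied so C > 0.5 means prognostic in the
    claimed direction.
    """
    s, t, e = _align(score, cohort)
    risk = s if score.orientation == "higher_is_worse" else -s
    if e.sum() == 0:
        raise UndefinedStatisticError("no events: no comparable pairs")
    try:
        # lifelines' C treats higher predicted values as longer survival
        return float(_lifelines_cindex(t.to_numpy(), -risk.to_numpy(), e.to_numpy()))
    except ZeroDivisionError as exc:
        raise UndefinedStatisticError("no comparable pairs") from exc


def cox_fit(
    score: ScoreVector,
    cohort: CohortTable,
    stratum: str = "combined",
) -> SurvivalFit:
    """Single-covariate Cox proportional-hazards fit (Efron ties).

    The score is standardized to unit sample SD; beta is therefore the log
    hazard per SD in the score's native orientation. Wald 95% CI and p-value;
    Harrell's C attached (risk-oriented).
    """
    s, t, e = _align(score, cohort)
    if int(e.sum()) < 2:
        raise InvalidInputError(f"need >= 2 events, got {int(e.sum())}")
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise InvalidInputError("score is constant; no hazard association estimable")
    z = (s - s.mean()) / sd
    df = pd.DataFrame({"time": t.to_numpy(), "event": e.to_numpy(), "score": z.to_numpy()})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event", show_progress=False)
    except Exception as exc:  # lifelines raises ConvergenceError/ValueError
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    return SurvivalFit(
        signature=score.name,
        stratum=stratum,
        n=int(len(df)),
        n_events=int(e.sum()),
        beta=beta,
        hr=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - 1.959963984540054 * se)),
        ci_upper=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(cph.summary.loc["score", "p"]),
        concordance=concordance_index(score, cohort.subset(list(s.index))),
        orientation=score.orientation,
    )


def km_median_split(score: ScoreVector, cohort: CohortTable) -> KmCurve:
    """Kaplan-Meier curves for score >= median vs < median, with log-rank.

    Median ties go to the high-score group, deterministically. Raises if the
    split leaves a group empty or if no events occur (log-rank undefined).
    """
    s, t, e = _align(score, cohort)
    cut = float(np.median(s))
    high = s >= cut
    if high.all() or (~high).all():
        raise DegenerateSplitError("median split left one group empty (ties at median)")
    if e.sum() == 0:
        raise UndefinedStatisticError("all samples censored; log-rank undefined")
    times, surv, at_risk, sizes = {}, {}, {}, {}
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        grid = kmf.survival_function_.index.to_numpy(dtype=float)
        times[name] = grid
        surv[name] = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        tt = np.sort(t[mask].to_numpy())
        at_risk[name] = np.array([(tt >= u).sum() for u in grid])
        sizes[name] = int(mask.sum())
    lr = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    return KmCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        group_sizes=sizes,
        chi2=float(lr.test_statistic),
        p=float(lr.p_value),
        cutpoint=cut,
    )


def fits_to_table(fits: list[SurvivalFit]) -> pd.DataFrame:
    """Signature x stratum results table (p, C, HR, CI)."""
    return pd.DataFrame([f.to_dict() for f in fits])
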