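"""Mortality modelling by trajectory cluster and risk reclassification.

Covers the third analysis stage: a ladder of Cox proportional-hazards
models for all-cause mortality with trajectory-cluster indicators
(Model 1 unadjusted; Model 2 adds surgical risk score, valve size,
calcium score and device type; Model 3 adds BMI and pacemaker status),
discrimination by Harrell's C-index, categorical net reclassification
improvement (NRI) of base risk-score models augmented with cluster
membership, subject-level bootstrap confidence intervals, and
calibration tables of predicted vs. observed mortality.

Cox fits use lifelines (Efron tie handling); absolute risks come from
the Breslow baseline survival.  The NRI handles censoring before the
horizon by Kaplan-Meier estimation of event probabilities within
reclassification groups, which reduces exactly to the count-based NRI
under full follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from astraj.errors import (
    DegenerateModelError,
    InvalidInputError,
    UndefinedMetricError,
)

CLUSTER_REFERENCE = "StableLow"
MODEL_COVARIATES = {
    1: [],
    2: ["sts_score", "valve_size", "agatston", "valve_type_self_expanding"],
    3: ["sts_score", "valve_size", "agatston", "valve_type_self_expanding",
        "bmi", "pacemaker"],
}
DEFAULT_RISK_CUTOFFS = (0.05, 0.075, 0.10)


# ---------------------------------------------------------------------------
# Cox ladder
# ---------------------------------------------------------------------------

def _design_frame(records: pd.DataFrame, covariates: list[str],
                  cluster_col: str = "cluster_label") -> pd.DataFrame:
    df = records.copy()
    if "valve_type_self_expanding" in covariates:
        df["valve_type_self_expanding"] = (
            df["valve_type"] == "self_expanding").astype(int)
    labels = [l for l in df[cluster_col].unique() if l != CLUSTER_REFERENCE]
    cluster_cols = []
    for lab in sorted(map(str, labels)):
        col = f"cluster_{lab}"
        df[col] = (df[cluster_col].astype(str) == lab).astype(int)
        cluster_cols.append(col)
    keep = cluster_cols + covariates + ["survival_time_years", "event"]
    return df[keep], cluster_cols


def fit_cox_ladder(records: pd.DataFrame, model_id: int):
    """Fit one rung of the mortality model ladder.

    ``model_id`` 1 = cluster indicators only; 2 adds surgical risk
    score, valve size, calcium score and device type; 3 additionally
    BMI and pacemaker.  The reference cluster is StableLow.

    Returns ``(fitted CoxPHFitter, hazard-ratio table)`` where the
    table has one row per term with HR, 95% CI and p-value.
    """
    if model_id not in MODEL_COVARIATES:
        raise InvalidInputError("model_id must be 1, 2 or 3")
    if records["cluster_label"].nunique() < 2:
        raise InvalidInputError("need at least two clusters present")
    if records["event"].sum() < 10:
        raise DegenerateModelError("need at least 10 events to fit the ladder")
    df, cluster_cols = _design_frame(records, MODEL_COVARIATES[model_id])
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="survival_time_years", event_col="event")
    except Exception as exc:  # convergence/separation
        raise DegenerateModelError(
            f"Cox model {model_id} failed to fit: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame({
        "term": summ.index,
        "hr": np.exp(summ["coef"]).to_numpy(),
        "ci_low": np.exp(summ["coef lower 95%"]).to_numpy(),
        "ci_high": np.exp(summ["coef upper 95%"]).to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    table.attrs["cluster_terms"] = cluster_cols
    return cph, table


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def harrell_c(times, events, risk_scores) -> float:
    """Harrell's concordance index for right-censored survival data.

    A pair is comparable when the earlier time is an event; the pair is
    concordant when the higher risk score belongs to the earlier
    failure, with risk ties counted half.  Tied event times are not
    comparable; a censored subject tied with an event time counts as
    surviving longer.
    """
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    r = np.asarray(risk_scores, float)
    if t.shape != e.shape or t.shape != r.shape:
        raise InvalidInputError("times, events and risk_scores must align")
    # comparable: i is an event and (t_i < t_j, or t_i == t_j and j censored)
    ti = t[:, None]
    tj = t[None, :]
    comparable = e[:, None] & ((ti < tj) | ((ti == tj) & ~e[None, :]))
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs")
    ri = r[:, None]
    rj = r[None, :]
    concordant = (comparable & (ri > rj)).sum()
    tied = (comparable & (ri == rj)).sum()
    return float((concordant + 0.5 * tied) / n_comp)


# ---------------------------------------------------------------------------
# absolute risk
# ---------------------------------------------------------------------------

def predicted_mortality(cph: CoxPHFitter, records: pd.DataFrame,
                        horizon: float) -> np.ndarray:
    """Per-subject probability of death by ``horizon`` years.

    ``1 - S0(h)^exp(lp)`` with the Breslow baseline survival of the
    fitted model.  A horizon beyond the last observed time warns and
    extrapolates flatly from the last time.
    """
    tmax = float(cph.durations.max())
    h = horizon
    if horizon > tmax:
        warnings.warn(f"horizon {horizon} beyond last observed time {tmax:.3g}; "
                      "using the last-time survival", stacklevel=2)
        h = tmax
    surv = cph.predict_survival_function(records, times=[h])
    return 1.0 - surv.iloc[0].to_numpy()


# ---------------------------------------------------------------------------
# categorical NRI
# ---------------------------------------------------------------------------

@dataclass
class ReclassificationResult:
    horizon: float
    nri_events: float
    nri_nonevents: float
    nri_overall: float
    nri_events_ci: tuple | None = None
    nri_nonevents_ci: tuple | None = None
    nri_overall_ci: tuple | None = None
    c_base: float | None = None
    c_augmented: float | None = None
    c_difference: float | None = None
    c_base_ci: tuple | None = None
    c_augmented_ci: tuple | None = None
    c_difference_ci: tuple | None = None
    n_boot: int = 0

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = list(v) if isinstance(v, tuple) else v
        return out


def _km_event_prob(times, events, horizon) -> float:
    """P(event by horizon) by Kaplan-Meier; exact count under full follow-up."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    censored_early = (~events) & (times < horizon)
    if not censored_early.any():
        return float(np.mean(events & (times <= horizon)))
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(1.0 - kmf.predict(horizon))


def categorical_nri(base_probs, augmented_probs, times, events,
                    horizon: float, categories=DEFAULT_RISK_CUTOFFS,
                    censoring: str = "km") -> ReclassificationResult:
    """Categorical net reclassification improvement at a horizon.

    Subjects are binned by predicted mortality under both models using
    the ordered ``categories`` cutoffs (default <5%, 5-7.5%, 7.5-10%,
    >10%).  With ``censoring="km"``, event status by the horizon is
    estimated by Kaplan-Meier within the up-/down-/un-moved groups
    (reduces to plain counting under full follow-up);
    ``censoring="complete_case"`` drops subjects censored before the
    horizon.

    ``nri_events = P(up|event) - P(down|event)``;
    ``nri_nonevents = P(down|non-event) - P(up|non-event)``;
    overall is their sum.
    """
    base = np.asarray(base_probs, float)
    aug = np.asarray(augmented_probs, float)
    t = np.asarray(times, float)
    e = np.asarray(events).astype(int)
    if not (base.shape == aug.shape == t.shape == e.shape):
        raise InvalidInputError("probability and outcome vectors must align")
    cuts = np.asarray(categories, float)
    if np.any(np.diff(cuts) <= 0) or cuts.min() <= 0 or cuts.max() >= 1:
        raise InvalidInputError("categories must be strictly increasing in (0,1)")

    if censoring == "complete_case":
        keep = (e == 1) & (t <= horizon) | (t >= horizon)
        base, aug, t, e = base[keep], aug[keep], t[keep], e[keep]

    bin_base = np.searchsorted(cuts, base, side="right")
    bin_aug = np.searchsorted(cuts, aug, side="right")
    move = np.sign(bin_aug - bin_base)           # +1 up, -1 down, 0 same

    p_event_all = _km_event_prob(t, e, horizon)
    if p_event_all <= 0:
        raise UndefinedMetricError("no events by the horizon")

    n = base.size
    parts = {}
    for name, mask in (("up", move > 0), ("down", move < 0)):
        frac = mask.mean()
        pe = _km_event_prob(t[mask], e[mask], horizon) if mask.any() else 0.0
        parts[name] = (frac, pe)
    (f_up, pe_up), (f_down, pe_down) = parts["up"], parts["down"]

    nri_ev = (pe_up * f_up - pe_down * f_down) / p_event_all
    nri_ne = (((1 - pe_down) * f_down - (1 - pe_up) * f_up)
              / (1 - p_event_all))
    return ReclassificationResult(
        horizon=horizon, nri_events=float(nri_ev),
        nri_nonevents=float(nri_ne), nri_overall=float(nri_ev + nri_ne))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(statistic, records: pd.DataFrame, n_boot: int = 1000,
                 seed: int = 0, alpha: float = 0.05):
    """Subject-level bootstrap percentile CI for an arbitrary statistic.

    ``statistic`` maps a resampled records frame to a float or a 1-d
    vector.  Resamples rows with replacement; deterministic given
    ``seed``.  Raises if the statistic fails on more than 10% of
    resamples.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            draws.append(np.atleast_1d(np.asarray(
                statistic(records.iloc[idx].reset_index(drop=True)), float)))
        except Exception:
            failures += 1
    if failures > 0.1 * n_boot:
        raise DegenerateModelError(
            f"statistic failed on {failures}/{n_boot} bootstrap resamples")
    arr = np.vstack(draws)
    lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                           axis=0)
    if arr.shape[1] == 1:
        return (float(lo[0]), float(hi[0]))
    return list(zip(lo.tolist(), hi.tolist()))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_table(predicted_probs, times, events, horizon: float,
                      n_bins: int = 10) -> pd.DataFrame:
    """Predicted vs. observed mortality by predicted-probability decile.

    Bins subjects by quantiles of the predicted probability (empty or
    duplicate bins are collapsed with a warning) and contrasts the mean
    prediction with 1 - KM(horizon) in each bin.
    """
    p = np.asarray(predicted_probs, float)
    t = np.asarray(times, float)
    e = np.asarray(events).astype(int)
    ser = pd.Series(p)
    try:
        bins = pd.qcut(ser, n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(np.zeros(p.size, dtype=int))
    if bins.isna().any():   # constant predictions collapse every edge
        bins = pd.Series(np.zeros(p.size, dtype=int))
    n_eff = bins.nunique()
    if n_eff < n_bins:
        warnings.warn(f"collapsed to {n_eff} calibration bins "
                      "(ties in predictions)", stacklevel=2)
    rows = []
    for b in sorted(bins.unique()):
        mask = (bins == b).to_numpy()
        rows.append({
            "bin": int(b), "n": int(mask.sum()),
            "predicted_mean": float(p[mask].mean()),
            "observed_km": _km_event_prob(t[mask], e[mask], horizon)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end reclassification analysis
# ---------------------------------------------------------------------------

def _risk_model_probs(records: pd.DataFrame, score_col: str,
                      cluster: bool, horizon: float,
                      mode: str = "refit") -> np.ndarray:
    """Horizon-specific death probabilities from a base risk score.

    ``mode="refit"`` refits a Cox model on the score (plus cluster
    indicators when ``cluster``) and converts to absolute risk via the
    Breslow baseline, re-anchoring the probability scale to the cohort.
    ``mode="face_value"`` keeps the risk score's own probability scale
    (percentage / 100) — the scale the risk-category cutoffs were
    designed for; the augmented model then tilts the base survival
    probability by the mean-centered cluster component of a Cox fit on
    score + cluster: ``p_aug = 1 - (1 - p_base)^exp(g)``.
    """
    df = records[[score_col, "survival_time_years", "event",
                  "cluster_label"]].copy()
    covs = [score_col]
    cluster_cols = []
    if cluster:
        for lab in sorted(df["cluster_label"].astype(str).unique()):
            if lab != CLUSTER_REFERENCE:
                col = f"cluster_{lab}"
                df[col] = (df["cluster_label"].astype(str) == lab).astype(int)
                cluster_cols.append(col)
    if mode == "face_value":
        base = np.clip(records[score_col].to_numpy() / 100.0, 1e-12, 1.0)
        if not cluster:
            return base
        cph = CoxPHFitter()
        cph.fit(df[covs + cluster_cols + ["survival_time_years", "event"]],
                duration_col="survival_time_years", event_col="event")
        g = np.zeros(len(df))
        for col in cluster_cols:
            g += cph.params_[col] * df[col].to_numpy()
        g -= g.mean()
        return 1.0 - (1.0 - base) ** np.exp(g)
    if mode != "refit":
        raise InvalidInputError(f"unknown probability mode {mode!r}")
    cph = CoxPHFitter()
    cph.fit(df[covs + cluster_cols + ["survival_time_years", "event"]],
            duration_col="survival_time_years", event_col="event")
    return predicted_mortality(cph, df[covs + cluster_cols], horizon)


def reclassification_analysis(records: pd.DataFrame, score_col: str,
                              horizon: float,
                              categories=DEFAULT_RISK_CUTOFFS,
                              n_boot: int = 1000, seed: int = 0,
                              mode: str = "refit") -> ReclassificationResult:
    """C-index and NRI for a base risk score vs. base + trajectory cluster.

    Fits the base model on ``score_col`` and an augmented model adding
    cluster indicators, converts both to predicted mortality at the
    horizon, and reports Harrell's C for both along with the
    categorical NRI, all with subject-level bootstrap percentile CIs.
    """
    def compute(df: pd.DataFrame) -> np.ndarray:
        base = _risk_model_probs(df, score_col, cluster=False,
                                 horizon=horizon, mode=mode)
        aug = _risk_model_probs(df, score_col, cluster=True,
                                horizon=horizon, mode=mode)
        t = df["survival_time_years"].to_numpy()
        e = df["event"].to_numpy()
        nri = categorical_nri(base, aug, t, e, horizon, categories)
        cb = harrell_c(t, e, base)
        ca = harrell_c(t, e, aug)
        return np.array([nri.nri_events, nri.nri_nonevents, nri.nri_overall,
                         cb, ca, ca - cb])

    point = compute(records)
    cis = [None] * 6
    if n_boot > 0:
        cis = bootstrap_ci(compute, records, n_boot=n_boot, seed=seed)
    return ReclassificationResult(
        horizon=horizon,
        nri_events=float(point[0]), nri_nonevents=float(point[1]),
        nri_overall=float(point[2]),
        nri_events_ci=cis[0], nri_nonevents_ci=cis[1], nri_overall_ci=cis[2],
        c_base=float(point[3]), c_augmented=float(point[4]),
        c_difference=float(point[5]),
        c_base_ci=cis[3], c_augmented_ci=cis[4], c_difference_ci=cis[5],
        n_boot=n_boot)
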