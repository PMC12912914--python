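"""Community screening validation metrics.

Implements the diagnostic-performance side of the analysis: AUROC with
a stratified bootstrap CI, the Youden-optimal cutpoint with a full
confusion summary (Wilson intervals), Bayes prevalence-adjusted
projections of PPV/NPV and the positive screen rate, screen
classification (TP/FP/TN/FN with moderate/severe AS as the case
definition), and the prognosis of false-positive screens relative to
true negatives via proportional-hazards models.

Conventions: the classification rule is ``score >= cutpoint ->
positive``; mild AS is grouped with normal as a non-case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.stats import norm, rankdata

from astraj.errors import DegenerateModelError, InvalidInputError, UndefinedMetricError

CASE_CLASS = "moderate_severe"


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise InvalidInputError("labels must be 0/1")
    if labels.min() == labels.max():
        raise UndefinedMetricError("both classes must be present")
    return labels


def wilson_interval(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = norm.ppf(1 - alpha / 2)
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(centre - half, 0.0), min(centre + half, 1.0))


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

@dataclass
class AurocResult:
    value: float
    ci_low: float
    ci_high: float
    n_boot: int


def _auroc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney probability of correct ordering, ties counted 1/2
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auroc(scores, labels, n_boot: int = 2000, seed: int = 0) -> AurocResult:
    """Area under the ROC curve with a case/control-stratified bootstrap CI.

    Equals the rank-based (Mann-Whitney) probability that a random case
    scores above a random non-case, ties counted half.  The percentile
    CI resamples cases and controls separately (2000 resamples by
    default).
    """
    scores = np.asarray(scores, float)
    labels = _check_binary(labels)
    value = _auroc_point(scores, labels)
    rng = np.random.default_rng(seed)
    pos, neg = scores[labels == 1], scores[labels == 0]
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        stats_[b] = _auroc_point(np.concatenate([ps, ns]),
                                 np.concatenate([np.ones(ps.size, int),
                                                 np.zeros(ns.size, int)]))
    lo, hi = np.percentile(stats_, [2.5, 97.5])
    return AurocResult(value=value, ci_low=float(lo), ci_high=float(hi),
                       n_boot=n_boot)


# ---------------------------------------------------------------------------
# cutpoint and confusion
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    cutpoint: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    ppv_ci: tuple
    npv_ci: tuple

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("cutpoint", "tp", "fp", "tn", "fn",
              "sensitivity", "specificity", "ppv", "npv")}
        for k in ("sensitivity_ci", "specificity_ci", "ppv_ci", "npv_ci"):
            d[k] = list(getattr(self, k))
        return d


def confusion_at(scores, labels, cutpoint: float) -> ConfusionSummary:
    """Confusion summary for the rule ``score >= cutpoint -> positive``."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= cutpoint
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    se = tp / (tp + fn) if tp + fn else np.nan
    sp = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    return ConfusionSummary(
        cutpoint=float(cutpoint), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        sensitivity_ci=wilson_interval(tp, tp + fn),
        specificity_ci=wilson_interval(tn, tn + fp),
        ppv_ci=wilson_interval(tp, tp + fp),
        npv_ci=wilson_interval(tn, tn + fn))


def youden_cutpoint(scores, labels) -> tuple[float, ConfusionSummary]:
    """Observed score maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed score values; ties in J are broken
    toward the larger cutpoint (fewer screen positives).
    """
    scores = np.asarray(scores, float)
    labels = _check_binary(labels)
    candidates = np.unique(scores)
    best_cut, best_j = None, -np.inf
    for c in candidates:
        pred = scores >= c
        se = np.sum(pred & (labels == 1)) / labels.sum()
        sp = np.sum(~pred & (labels == 0)) / (labels == 0).sum()
        j = se + sp - 1
        if j > best_j or (j == best_j and (best_cut is None or c > best_cut)):
            best_j, best_cut = j, c
    return float(best_cut), confusion_at(scores, labels, best_cut)


# ---------------------------------------------------------------------------
# prevalence projection
# ---------------------------------------------------------------------------

@dataclass
class PrevalenceProjection:
    prevalence: float
    ppv: float
    npv: float
    positive_screen_rate: float

    def to_dict(self) -> dict:
        return {"prevalence": self.prevalence, "ppv": self.ppv,
                "npv": self.npv,
                "positive_screen_rate": self.positive_screen_rate}


def prevalence_adjusted(sensitivity: float, specificity: float,
                        prevalence: float) -> PrevalenceProjection:
    """Project test performance to a population with a given prevalence.

    Closed-form Bayes projection::

        PPV  = se*p / (se*p + (1-sp)*(1-p))
        NPV  = sp*(1-p) / (sp*(1-p) + (1-se)*p)
        rate = se*p + (1-sp)*(1-p)
    """
    for name, v in (("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
    if not 0.0 < prevalence < 1.0:
        raise InvalidInputError(
            f"prevalence must lie in (0, 1), got {prevalence}")
    se, sp, p = sensitivity, specificity, prevalence
    denom_p = se * p + (1 - sp) * (1 - p)
    denom_n = sp * (1 - p) + (1 - se) * p
    if denom_p == 0.0 or denom_n == 0.0:
        raise InvalidInputError(
            "degenerate operating point: a predictive value is 0/0")
    ppv = se * p / denom_p
    npv = sp * (1 - p) / denom_n
    rate = denom_p
    return PrevalenceProjection(prevalence=p, ppv=ppv, npv=npv,
                                positive_screen_rate=rate)


# ---------------------------------------------------------------------------
# screen classification and false-positive prognosis
# ---------------------------------------------------------------------------

def classify_screen(records: pd.DataFrame, cutpoint: float) -> pd.Series:
    """Label each subject TP/FP/TN/FN at the cutpoint.

    The case definition is moderate/severe AS; mild AS counts as a
    non-case.  The partition is exhaustive and exclusive.
    """
    if not 0.0 <= cutpoint <= 1.0:
        raise InvalidInputError("cutpoint must lie in [0, 1]")
    pos = records["score"].to_numpy() >= cutpoint
    case = records["severity_class"].to_numpy() == CASE_CLASS
    out = np.where(pos & case, "TP",
                   np.where(pos & ~case, "FP",
                            np.where(~pos & ~case, "TN", "FN")))
    return pd.Series(out, index=records.index, name="screen_group")


@dataclass
class PrognosisContrast:
    outcome: str
    adjusted: bool
    n_fp: int
    n_tn: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    km_curves: dict    # group -> (times, survival probabilities)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("outcome", "adjusted", "n_fp", "n_tn", "hazard_ratio",
                 "ci_low", "ci_high", "p_value")}


def fp_prognosis(records: pd.DataFrame, cutpoint: float, outcome: str,
                 adjusted: bool = False) -> PrognosisContrast:
    """Compare false-positive vs. true-negative subjects on an outcome.

    Fits a proportional-hazards model of the outcome time on a
    false-positive indicator, optionally adjusted for the PCP-HF risk
    score, restricted to non-case subjects.  Also returns Kaplan-Meier
    curves per group for plotting.

    ``outcome`` selects the column pair ``time_to_<outcome>`` /
    ``<outcome>_event`` (e.g. ``"as_hosp"``, ``"hf"``).
    """
    groups = classify_screen(records, cutpoint)
    keep = groups.isin(["FP", "TN"])
    df = records.loc[keep].copy()
    df["fp"] = (groups[keep] == "FP").astype(int)
    tcol, ecol = f"time_to_{outcome}", f"{outcome}_event"
    if tcol not in df or ecol not in df:
        raise InvalidInputError(f"records lack columns for outcome {outcome!r}")
    n_fp, n_tn = int(df["fp"].sum()), int((1 - df["fp"]).sum())
    if n_fp == 0 or n_tn == 0:
        raise DegenerateModelError("both FP and TN groups must be non-empty")
    if df.groupby("fp")[ecol].sum().min() < 1:
        raise DegenerateModelError("each group needs at least one event")

    cols = ["fp"] + (["pcp_hf"] if adjusted else [])
    cph = CoxPHFitter()
    cph.fit(df[cols + [tcol, ecol]], duration_col=tcol, event_col=ecol)
    s = cph.summary.loc["fp"]
    km = {}
    for name, sub in (("FP", df[df["fp"] == 1]), ("TN", df[df["fp"] == 0])):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[tcol], sub[ecol])
        km[name] = (kmf.survival_function_.index.to_numpy(),
                    kmf.survival_function_.iloc[:, 0].to_numpy())
    return PrognosisContrast(
        outcome=outcome, adjusted=adjusted, n_fp=n_fp, n_tn=n_tn,
        hazard_ratio=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p_value=float(s["p"]), km_curves=km)
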