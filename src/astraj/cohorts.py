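"""Synthetic screening and trajectory cohorts.

Real cohorts behind the two analyses (a community screening population
and a pre-procedure trajectory population) are not publicly available,
so this module generates synthetic cohorts with the same statistical
structure: severity-class score distributions matched to published
median/IQR triplets, class prevalences, proportional-hazards outcome
models with configurable hazard ratios, three latent trajectory shapes,
irregular visit schedules, and cluster-dependent mortality.

Everything is driven by explicit config dataclasses with a mandatory
seed; equal seeds give byte-identical cohorts.

Defaults emulate the study conditions: a screening cohort of 3632
subjects with 0.4% moderate/severe and 3.4% mild AS prevalence, and a
trajectory cohort of 2040 subjects (~3.9 visits each on average) over
10 years with class proportions (19.3%, 23.6%, 57.1%) and mortality
hazard ratios 1.28 / 1.43 for the two elevated classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq, least_squares

from astraj.errors import ConvergenceError, InvalidInputError

SEVERITY_CLASSES = ("normal", "mild", "moderate_severe")
TRAJECTORY_CLASSES = ("StableLow", "AcceleratedProgression", "PersistentlyHigh")

# printed per-class score quartiles (q1, median, q3) used as generator targets
DEFAULT_SCORE_QUARTILES = {
    "normal": (0.36, 0.52, 0.67),
    "mild": (0.47, 0.62, 0.78),
    "moderate_severe": (0.66, 0.74, 0.85),
}


# ---------------------------------------------------------------------------
# quartile -> beta fitting
# ---------------------------------------------------------------------------

def fit_beta_to_quartiles(median: float, q1: float, q3: float,
                          tol: float | None = 0.005) -> tuple[float, float]:
    """Fit a two-parameter beta distribution to a (median, q1, q3) triplet.

    Solves for beta shape parameters (a, b) by least squares on the
    25th/50th/75th percentiles, with the median residual up-weighted so
    the fitted median stays tight even when the three quantiles are not
    exactly beta-attainable.

    Parameters
    ----------
    median, q1, q3:
        Target quantiles, required to satisfy ``0 < q1 < median < q3 < 1``.
    tol:
        Maximum allowed absolute quantile residual.  If the best fit
        misses any quantile by more than ``tol``, a
        :class:`~astraj.errors.ConvergenceError` carrying the residuals
        is raised.  Pass ``None`` for a best-effort fit (used by the
        cohort generator, since some published triplets are slightly
        skewer than any beta law allows).

    Returns
    -------
    (a, b):
        Beta shape parameters.
    """
    if not (0.0 < q1 < median < q3 < 1.0):
        raise InvalidInputError(
            f"quartiles must satisfy 0 < q1 < median < q3 < 1, got "
            f"({q1}, {median}, {q3})")
    targets = np.array([q1, median, q3])
    weights = np.sqrt(np.array([1.0, 4.0, 1.0]))

    def residuals(log_ab):
        a, b = np.exp(log_ab)
        return weights * (stats.beta.ppf([0.25, 0.5, 0.75], a, b) - targets)

    # moment-style initial guess
    mean0 = median
    sd0 = max((q3 - q1) / 1.349, 1e-3)
    nu0 = max(mean0 * (1 - mean0) / sd0**2 - 1.0, 0.5)
    x0 = np.log([max(mean0 * nu0, 0.1), max((1 - mean0) * nu0, 0.1)])
    sol = least_squares(residuals, x0=x0, xtol=1e-12, ftol=1e-12)
    a, b = np.exp(sol.x)
    resid = stats.beta.ppf([0.25, 0.5, 0.75], a, b) - targets
    if tol is not None and np.max(np.abs(resid)) > tol:
        raise ConvergenceError(
            f"no beta distribution matches quartiles ({q1}, {median}, {q3}) "
            f"within {tol}; residuals (q1, median, q3) = {resid.round(4)}",
            residuals=resid)
    return float(a), float(b)


# ---------------------------------------------------------------------------
# screening cohort
# ---------------------------------------------------------------------------

@dataclass
class ScreeningGeneratorConfig:
    """Configuration for the community screening cohort generator.

    The outcome model is proportional-hazards exponential: subjects
    whose score is at or above ``screening_threshold`` carry hazard
    ratio ``hr_as_hosp`` (AS hospitalisation) and ``hr_hf`` (heart
    failure) relative to the per-year baseline rates, with
    administrative censoring at ``followup_years``.
    """

    n_subjects: int = 3632
    class_prevalence: dict = field(default_factory=lambda: {
        "normal": 0.962, "mild": 0.034, "moderate_severe": 0.004})
    score_quartiles: dict = field(
        default_factory=lambda: dict(DEFAULT_SCORE_QUARTILES))
    followup_years: float = 6.2
    screening_threshold: float = 0.67
    hr_as_hosp: float = 4.05
    hr_hf: float = 1.52
    baseline_event_rates: dict = field(default_factory=lambda: {
        "as_hosp": 0.004, "hf": 0.010})
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        prev = [self.class_prevalence.get(c, 0.0) for c in SEVERITY_CLASSES]
        if abs(sum(prev) - 1.0) > 1e-9 or min(prev) < 0:
            raise InvalidInputError("class_prevalence must be a probability "
                                    "vector over severity classes")
        if self.hr_as_hosp <= 0 or self.hr_hf <= 0:
            raise InvalidInputError("hazard ratios must be positive")
        if any(r <= 0 for r in self.baseline_event_rates.values()):
            raise InvalidInputError("baseline event rates must be positive")
        if not 0.0 <= self.screening_threshold <= 1.0:
            raise InvalidInputError("screening_threshold must lie in [0, 1]")


@dataclass
class SyntheticScreeningCohort:
    """Screening cohort: one row per subject plus generation truth."""

    records: pd.DataFrame
    truth: pd.DataFrame
    config: ScreeningGeneratorConfig


def generate_screening_cohort(config: ScreeningGeneratorConfig) -> SyntheticScreeningCohort:
    """Draw a synthetic community screening cohort.

    Severity classes come from ``class_prevalence``; scores from
    class-specific beta laws fitted to the configured quartile triplets;
    event times from exponential proportional-hazards models keyed on
    score >= threshold.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    prev = np.array([config.class_prevalence[c] for c in SEVERITY_CLASSES])
    cls_idx = rng.choice(len(SEVERITY_CLASSES), size=n, p=prev)
    classes = np.array(SEVERITY_CLASSES, dtype=object)[cls_idx]

    betas = {c: fit_beta_to_quartiles(q[1], q[0], q[2], tol=None)
             for c, q in config.score_quartiles.items()}
    scores = np.empty(n)
    for i, c in enumerate(SEVERITY_CLASSES):
        mask = cls_idx == i
        a, b = betas[c]
        scores[mask] = stats.beta.rvs(a, b, size=mask.sum(), random_state=rng)
    scores = np.clip(scores, 0.0, 1.0)

    positive = scores >= config.screening_threshold
    # PCP-HF risk covariate (percent), weakly correlated with the score
    pcp_hf = np.clip(rng.normal(8.0 + 6.0 * scores, 3.0), 0.1, None)

    out = {"subject_id": np.arange(1, n + 1),
           "score": scores, "severity_class": classes, "pcp_hf": pcp_hf}
    rates_true = {}
    for outcome, hr in (("as_hosp", config.hr_as_hosp), ("hf", config.hr_hf)):
        base = config.baseline_event_rates[outcome]
        rate = base * np.where(positive, hr, 1.0)
        t_event = rng.exponential(1.0 / rate)
        event = t_event <= config.followup_years
        out[f"time_to_{outcome}"] = np.minimum(t_event, config.followup_years)
        out[f"{outcome}_event"] = event.astype(int)
        rates_true[f"rate_{outcome}"] = rate
    records = pd.DataFrame(out)
    truth = pd.DataFrame({"subject_id": out["subject_id"],
                          "severity_class": classes,
                          "screen_positive": positive.astype(int),
                          **rates_true})
    return SyntheticScreeningCohort(records=records, truth=truth, config=config)


# ---------------------------------------------------------------------------
# trajectory cohort
# ---------------------------------------------------------------------------

def _stable_low_curve(level: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda t: np.full_like(np.asarray(t, float), level)


def _accelerated_curve(plateau: float, peak: float, ramp_years: float):
    def curve(t):
        t = np.asarray(t, float)
        ramp = peak + (plateau - peak) * t / ramp_years
        return np.where(t >= ramp_years, plateau, ramp)
    return curve


def _persistently_high_curve(level_10y: float, floor: float):
    slope = (level_10y - floor) / 10.0
    return lambda t: floor + slope * np.asarray(t, float)


@dataclass
class TrajectoryGeneratorConfig:
    """Configuration for the pre-procedure trajectory cohort generator.

    Time is measured in years *before* the procedure (0 = procedure
    date, axis extends to 10).  The three latent classes follow mean
    curves:

    * ``StableLow`` — constant at ``stable_low_level``;
    * ``AcceleratedProgression`` — flat at ``accel_plateau`` until the
      final ``accel_ramp_years`` years, then a monotone linear ramp to
      ``accel_peak`` at the procedure;
    * ``PersistentlyHigh`` — gentle linear decline from
      ``high_level_10y`` at 10 years toward ``high_floor`` at the
      procedure (floor kept above 0.70).

    Mortality after the procedure is exponential with class hazard
    ratios ``class_hrs`` relative to StableLow and uniform
    administrative censoring on (0, ``censor_max_years``); the baseline
    hazard is solved so the expected event fraction equals
    ``target_event_fraction``.
    """

    n_subjects: int = 2040
    class_proportions: tuple = (0.193, 0.236, 0.571)
    stable_low_level: float = 0.475
    accel_plateau: float = 0.58
    accel_peak: float = 0.85
    accel_ramp_years: float = 2.0
    high_level_10y: float = 0.78
    high_floor: float = 0.715
    subject_random_intercept_sd: float = 0.04
    observation_noise_sd: float = 0.05
    visit_nb_r: float = 0.8           # visits = 1 + NegBinom(r, mean=mu)
    visit_nb_mean: float = 3.8        # -> quartiles (2, 3, 6)
    last_gap_median: float = 0.55     # years from last ECG to procedure
    last_gap_log_sd: float = 2.5
    class_hrs: tuple = (1.0, 1.28, 1.43)
    target_event_fraction: float = 0.23
    censor_max_years: float = 4.2
    frailty_log_hazard: float = 0.35  # effect of the latent risk factor
    sts_median: float = 4.2
    sts_log_sd: float = 0.548
    euroscore2_medians: tuple = (5.3, 6.3, 6.2)   # per class, percent
    euroscore2_log_sd: float = 0.55
    pacemaker_rates: tuple = (0.107, 0.164, 0.173)
    valve_sizes: tuple = (23.0, 26.0, 29.0)
    self_expanding_rate: float = 0.345
    agatston_mean: float = 2460.0
    agatston_sd: float = 1320.0
    bmi_median: float = 27.8
    bmi_log_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        props = np.asarray(self.class_proportions, float)
        if props.size != 3 or abs(props.sum() - 1.0) > 1e-9 or props.min() < 0:
            raise InvalidInputError(
                "class_proportions must be a 3-vector summing to 1")
        if any(h <= 0 for h in self.class_hrs):
            raise InvalidInputError("class hazard ratios must be positive")
        if not 0 < self.target_event_fraction < 1:
            raise InvalidInputError("target_event_fraction must be in (0,1)")

    def mean_curves(self) -> dict:
        return {
            "StableLow": _stable_low_curve(self.stable_low_level),
            "AcceleratedProgression": _accelerated_curve(
                self.accel_plateau, self.accel_peak, self.accel_ramp_years),
            "PersistentlyHigh": _persistently_high_curve(
                self.high_level_10y, self.high_floor),
        }


@dataclass
class SyntheticTrajectoryCohort:
    """Trajectory cohort: long-format scores, per-subject survival, truth."""

    scores: pd.DataFrame     # subject_id, time_years_before_procedure, score
    subjects: pd.DataFrame   # subject_id, survival + covariates + class_truth
    config: TrajectoryGeneratorConfig

    @property
    def truth(self) -> pd.Series:
        return self.subjects.set_index("subject_id")["class_truth"]


def _calibrate_baseline_hazard(config: TrajectoryGeneratorConfig) -> float:
    """Baseline mortality hazard giving the target expected event fraction.

    With T ~ Exp(lam) and independent censoring C ~ U(0, cmax),
    P(event) = 1 - (1 - exp(-lam*cmax)) / (lam*cmax); the class mix and
    the log-normal frailty are averaged out (Gauss-Hermite).
    """
    cmax = config.censor_max_years
    props = np.asarray(config.class_proportions)
    hrs = np.asarray(config.class_hrs)
    nodes, wts = np.polynomial.hermite_e.hermegauss(21)
    wts = wts / wts.sum()

    def objective(lam0):
        lam = lam0 * hrs[:, None] * np.exp(config.frailty_log_hazard * nodes[None, :])
        pe = 1.0 - (1.0 - np.exp(-lam * cmax)) / (lam * cmax)
        return float(props @ (pe @ wts)) - config.target_event_fraction

    return brentq(objective, 1e-6, 5.0)


def generate_trajectory_cohort(config: TrajectoryGeneratorConfig) -> SyntheticTrajectoryCohort:
    """Draw a synthetic pre-procedure trajectory cohort.

    Per subject: a latent class, an irregular visit schedule (shifted
    negative-binomial count, last-visit gap, uniform earlier visits),
    scores = class mean curve + subject intercept + observation noise
    clipped to [0, 1], survival with class-specific hazards, and the
    covariate panel used by the adjusted mortality models.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    props = np.asarray(config.class_proportions, float)

    cls_idx = rng.choice(3, size=n, p=props)
    class_labels = np.array(TRAJECTORY_CLASSES, dtype=object)[cls_idx]
    curves = config.mean_curves()

    # visit schedule
    p_nb = config.visit_nb_r / (config.visit_nb_r + config.visit_nb_mean)
    n_visits = 1 + rng.negative_binomial(config.visit_nb_r, p_nb, size=n)
    gaps = np.minimum(
        stats.lognorm.rvs(s=config.last_gap_log_sd,
                          scale=config.last_gap_median,
                          size=n, random_state=rng), 9.0)

    intercepts = rng.normal(0.0, config.subject_random_intercept_sd, size=n)

    sid_col, t_col, s_col = [], [], []
    for i in range(n):
        m = int(n_visits[i])
        times = np.empty(m)
        times[0] = gaps[i]
        if m > 1:
            times[1:] = rng.uniform(gaps[i], 10.0, size=m - 1)
        times = np.unique(np.round(times, 6))          # sorted, deduplicated
        mean = curves[class_labels[i]](times)
        noise = rng.normal(0.0, config.observation_noise_sd, size=times.size)
        vals = np.clip(mean + intercepts[i] + noise, 0.0, 1.0)
        sid_col.append(np.full(times.size, i + 1))
        t_col.append(times)
        s_col.append(vals)
    scores = pd.DataFrame({
        "subject_id": np.concatenate(sid_col).astype(int),
        "time_years_before_procedure": np.concatenate(t_col),
        "score": np.concatenate(s_col)})

    # survival with latent frailty shared with the surgical risk scores
    lam0 = _calibrate_baseline_hazard(config)
    z = rng.normal(size=n)
    hrs = np.asarray(config.class_hrs)[cls_idx]
    lam = lam0 * hrs * np.exp(config.frailty_log_hazard * z)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(0.0, config.censor_max_years, size=n)
    time_obs = np.maximum(np.minimum(t_event, t_cens), 1e-4)
    event = (t_event <= t_cens).astype(int)

    # covariates; the risk scores load on the same frailty z
    mix = lambda e: 0.7 * z + np.sqrt(1 - 0.7**2) * e
    sts = np.exp(np.log(config.sts_median)
                 + config.sts_log_sd * mix(rng.normal(size=n)))
    es2_med = np.asarray(config.euroscore2_medians)[cls_idx]
    es2 = np.exp(np.log(es2_med)
                 + config.euroscore2_log_sd * mix(rng.normal(size=n)))
    subjects = pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "class_truth": class_labels,
        "survival_time_years": time_obs,
        "event": event,
        "sts_score": sts,
        "euroscore2": es2,
        "valve_size": rng.choice(np.asarray(config.valve_sizes), size=n),
        "agatston": np.clip(rng.normal(config.agatston_mean,
                                       config.agatston_sd, size=n), 0.0, None),
        "valve_type": np.where(rng.random(n) < config.self_expanding_rate,
                               "self_expanding", "balloon_expanding"),
        "bmi": np.exp(np.log(config.bmi_median)
                      + config.bmi_log_sd * rng.normal(size=n)),
        "pacemaker": (rng.random(n)
                      < np.asarray(config.pacemaker_rates)[cls_idx]).astype(int),
    })
    return SyntheticTrajectoryCohort(scores=scores, subjects=subjects,
                                     config=config)
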