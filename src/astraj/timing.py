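"""Threshold-exceedance timing summaries.

How early does the score signal disease?  Two views: the mean time
before the procedure at which a score first exceeds a threshold (in the
subset with rich series, default >= 5 observations), and the proportion
of subjects above a threshold at a fixed time before the procedure.

"First detected" means the chronologically earliest observation above
the threshold — the largest years-before value — not a sustained-
crossing rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from astraj.errors import InvalidInputError, UndefinedMetricError


@dataclass
class CrossingSummary:
    threshold: float
    min_obs: int
    n_eligible: int
    n_crossed: int
    mean_years_before: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def first_crossing(trajectories, threshold: float,
                   min_obs: int = 5) -> CrossingSummary:
    """Mean first-detection time for score > threshold.

    Eligible subjects have at least ``min_obs`` observations; the first
    detection is the earliest (largest years-before) observation with
    score strictly above the threshold.  Subjects who never cross are
    counted in ``n_eligible`` but excluded from the mean.  The 95% CI
    is the normal approximation ``mean +/- 1.96*SE``.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    eligible = [t for t in trajectories if len(t) >= min_obs]
    if not eligible:
        raise UndefinedMetricError("no subjects meet the min_obs requirement")
    firsts = []
    for t in eligible:
        above = t.scores > threshold
        if above.any():
            firsts.append(float(t.times[above].max()))
    if not firsts:
        return CrossingSummary(threshold=threshold, min_obs=min_obs,
                               n_eligible=len(eligible), n_crossed=0,
                               mean_years_before=np.nan,
                               ci_low=np.nan, ci_high=np.nan)
    firsts = np.asarray(firsts)
    mean = float(firsts.mean())
    se = float(firsts.std(ddof=1) / np.sqrt(firsts.size)) if firsts.size > 1 else 0.0
    return CrossingSummary(threshold=threshold, min_obs=min_obs,
                           n_eligible=len(eligible), n_crossed=firsts.size,
                           mean_years_before=mean,
                           ci_low=mean - 1.96 * se, ci_high=mean + 1.96 * se)


@dataclass
class ProportionAbove:
    threshold: float
    at_years_before: float
    window: float
    n_contributing: int
    n_above: int
    proportion: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def proportion_above(trajectories, threshold: float, at_years_before: float,
                     window: float = 0.5) -> ProportionAbove:
    """Proportion of subjects above a threshold near a fixed time point.

    For each subject the observation nearest ``at_years_before`` within
    ``+/- window`` years is selected (ties toward the more recent, i.e.
    smaller years-before).  The denominator is the subjects that
    contribute an observation.
    """
    if not 0.0 <= at_years_before <= 10.0:
        raise InvalidInputError("at_years_before must lie in [0, 10]")
    n_contrib = 0
    n_above = 0
    for t in trajectories:
        d = np.abs(t.times - at_years_before)
        in_win = d <= window
        if not in_win.any():
            continue
        n_contrib += 1
        cand = np.flatnonzero(in_win)
        best = cand[np.lexsort((t.times[cand], d[cand]))][0]
        if t.scores[best] > threshold:
            n_above += 1
    if n_contrib == 0:
        raise UndefinedMetricError(
            "no subject has an observation inside the window")
    return ProportionAbove(threshold=threshold,
                           at_years_before=at_years_before, window=window,
                           n_contributing=n_contrib, n_above=n_above,
                           proportion=n_above / n_contrib)
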