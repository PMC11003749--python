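"""Signal-detection and reaction-time summaries of trial outcomes.

Sensitivity follows the equal-variance Gaussian observer:
``d' = Phi^-1(P_hit) - Phi^-1(P_FA)`` and
``criterion = -(Phi^-1(P_hit) + Phi^-1(P_FA)) / 2``, with every proportion
first rescaled to ``P^ = 0.005 + 0.99*P`` so empty cells (0% or 100%) stay
finite.  The orientation-masking profile of d' is summarized by an
inverted, dc-shifted Gaussian with its minimum at the target orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .utils import wrap_orientation


@dataclass
class OrientationBehavior:
    """Per-orientation counts and signal-detection summaries."""

    orientation: float
    n_hit: int
    n_miss: int
    n_cr: int
    n_fa: int
    dprime: float
    criterion: float
    rt_mean_ms: Optional[float]
    rt_sem_ms: Optional[float]


@dataclass
class BehaviorSummary:
    """Session-level behavioral summary across background orientations."""

    per_orientation: list
    masking_fit: Optional[tuple] = None      # (A, sigma, c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.per_orientation])

    @property
    def orientations(self):
        return np.array([o.orientation for o in self.per_orientation])

    @property
    def dprimes(self):
        return np.array([o.dprime for o in self.per_orientation])

    @property
    def trial_counts(self):
        return np.array([o.n_hit + o.n_miss + o.n_cr + o.n_fa
                         for o in self.per_orientation])


def _scaled(p: float) -> float:
    """Proportion rescaling P^ = 0.005 + 0.99*P, applied unconditionally."""
    return 0.005 + 0.99 * p


def dprime_criterion(hits: int, misses: int, correct_rejects: int,
                     false_alarms: int):
    """d' and criterion from outcome counts (scaled-proportion convention).

    Requires at least one target-present and one target-absent trial.
    Scaling caps the proportions at [0.005, 0.995], so perfect performance
    maps to the finite ``d' = 2*Phi^-1(0.995)``.
    """
    n_present = hits + misses
    n_absent = correct_rejects + false_alarms
    if n_present < 1 or n_absent < 1:
        raise ValueError("need >=1 target-present and >=1 target-absent trial")
    zh = sps.norm.ppf(_scaled(hits / n_present))
    zf = sps.norm.ppf(_scaled(false_alarms / n_absent))
    return float(zh - zf), float(-(zh + zf) / 2.0)


def pc_max(dprime: float) -> float:
    """Unbiased maximum proportion correct implied by d': ``Phi(d'/2)``."""
    if not np.isfinite(dprime):
        raise ValueError("d' must be finite")
    return float(sps.norm.cdf(dprime / 2.0))


def _masking_model(theta, A, sigma, c):
    return c - A * np.exp(-(theta ** 2) / (2.0 * sigma ** 2))


def fit_masking_curve(dprime_by_orientation, orientations, trial_counts=None):
    """Weighted fit of the inverted dc-shifted Gaussian masking profile.

    ``d'(theta) = c - A*exp(-theta^2/(2 sigma^2))`` with A >= 0 (minimum at
    the target orientation).  Weights are trial counts when given.  Returns
    ``(A, sigma, c)``.
    """
    y = np.asarray(dprime_by_orientation, dtype=float)
    th = wrap_orientation(orientations)
    if y.size < 5:
        raise ValueError("need at least 5 orientations")
    w = np.ones_like(y) if trial_counts is None \
        else np.asarray(trial_counts, dtype=float)
    sigma_res = 1.0 / np.sqrt(np.maximum(w, 1e-12))

    c0 = float(y[np.argmax(np.abs(th))])
    A0 = max(c0 - float(y[np.argmin(np.abs(th))]), 1e-3)
    p0 = [A0, 30.0, c0]
    try:
        popt, _ = optimize.curve_fit(
            _masking_model, th, y, p0=p0, sigma=sigma_res,
            bounds=([0.0, 1.0, -np.inf], [np.inf, 1000.0, np.inf]),
            maxfev=20000)
    except RuntimeError as err:
        # moment-based fallback initialization, reported in the diagnostic
        p0b = [max(y.max() - y.min(), 1e-3), float(np.std(th)) or 30.0,
               float(y.max())]
        try:
            popt, _ = optimize.curve_fit(
                _masking_model, th, y, p0=p0b, sigma=sigma_res,
                bounds=([0.0, 1.0, -np.inf], [np.inf, 1000.0, np.inf]),
                maxfev=40000)
        except RuntimeError:
            raise RuntimeError(
                f"masking-curve fit failed (initializations {p0} and {p0b})"
            ) from err
    return tuple(float(v) for v in popt)


def reaction_time_summary(trials) -> pd.DataFrame:
    """Mean and SEM of reaction time over hit trials, per background orientation.

    Only hit trials contribute (fixation outcomes carry no RT; false alarms
    are excluded by convention).  Orientations without hits are absent from
    the output.  SEM uses the n-1 sample SD.
    """
    rows = {}
    for tr in trials:
        if tr.outcome != "hit" or tr.reaction_time_ms is None:
            continue
        ori = float(wrap_orientation(tr.stimulus.background_orientation))
        rows.setdefault(ori, []).append(tr.reaction_time_ms)
    recs = []
    for ori in sorted(rows):
        rts = np.asarray(rows[ori], dtype=float)
        sem = float(rts.std(ddof=1) / np.sqrt(rts.size)) if rts.size > 1 else 0.0
        recs.append({"orientation_deg": ori, "n_hits": rts.size,
                     "rt_mean_ms": float(rts.mean()), "rt_sem_ms": sem})
    return pd.DataFrame(recs, columns=["orientation_deg", "n_hits",
                                       "rt_mean_ms", "rt_sem_ms"])


def summarize_session(trials, fit_masking: bool = True) -> BehaviorSummary:
    """Aggregate detection-block trials into a BehaviorSummary."""
    by_ori = {}
    for tr in trials:
        ori = float(wrap_orientation(tr.stimulus.background_orientation))
        by_ori.setdefault(ori, []).append(tr)
    rt_table = reaction_time_summary(trials)
    per = []
    for ori in sorted(by_ori):
        ts = by_ori[ori]
        counts = {o: sum(1 for t in ts if t.outcome == o)
                  for o in ("hit", "miss", "correct_reject", "false_alarm")}
        d, c = dprime_criterion(counts["hit"], counts["miss"],
                                counts["correct_reject"], counts["false_alarm"])
        row = rt_table[rt_table.orientation_deg == ori]
        per.append(OrientationBehavior(
            orientation=ori, n_hit=counts["hit"], n_miss=counts["miss"],
            n_cr=counts["correct_reject"], n_fa=counts["false_alarm"],
            dprime=d, criterion=c,
            rt_mean_ms=float(row.rt_mean_ms.iloc[0]) if len(row) else None,
            rt_sem_ms=float(row.rt_sem_ms.iloc[0]) if len(row) else None))
    summary = BehaviorSummary(per_orientation=per)
    if fit_masking and len(per) >= 5:
        summary.masking_fit = fit_masking_curve(
            summary.dprimes, summary.orientations, summary.trial_counts)
    return summary
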