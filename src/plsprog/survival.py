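"""Kaplan-Meier estimation, log-rank comparison, and two-group Cox models.

These are the classical right-censored survival tools used to translate a
classifier's predicted prognosis groups into clinically interpretable
statistics: the product-limit survivor curve per group, the log-rank
chi-square comparing the curves, and the hazard ratio from a one-covariate
Cox proportional-hazards model (with its 95% confidence interval).

The Cox partial likelihood is maximized by Newton-Raphson with Breslow
handling of tied event times by default (Efron behind a flag).  With
Breslow ties and untied event times the Cox score test at beta = 0 is
algebraically the log-rank statistic, which the test suite uses as a
cross-check between the two routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConvergenceError, ValidationError

#: p-values below double precision are reported as this string.
P_FLOOR = 1e-15


def format_pvalue(p: float) -> str:
    return f"<{P_FLOOR:g}" if p < P_FLOOR else f"{p:.6g}"


def _check_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.shape != events.shape:
        raise ValidationError("times and events differ in length")
    if (times < 0).any():
        raise ValidationError("negative times")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0/1")
    return times, events


def _check_group(group, n: int) -> np.ndarray:
    group = np.asarray(group).ravel()
    if group.shape[0] != n:
        raise ValidationError("group vector length mismatch")
    values = np.unique(group)
    if len(values) != 2:
        raise ValidationError("need exactly two non-empty groups")
    return (group == values[1]).astype(int)  # 0/1 coding, second value = 1


@dataclass
class SurvivalCurve:
    """Product-limit survivor estimate S(t) with risk-set bookkeeping."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), stepping down at each event time <= t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "n_events": self.n_events,
        })


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator over distinct event times.

    At each distinct event time t_i with d_i events and n_i subjects still
    at risk, the survivor estimate multiplies by (1 - d_i / n_i); censored
    subjects leave the risk set without contributing a factor.
    """
    times, events = _check_times(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(times >= t))
        n_events[i] = int(np.sum((times == t) & (events == 1)))
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / at_risk) if len(event_times) else np.array([])
    return SurvivalCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=n_events,
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, group) -> tuple[float, float]:
    """Standard (unweighted) log-rank chi-square test between two groups.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; the statistic
    is (sum(O - E))^2 / sum(V) on one degree of freedom.
    """
    times, events = _check_times(times, events)
    g = _check_group(group, len(times))
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 1)).sum())
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & (g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class CoxResult:
    """Two-group Cox proportional-hazards fit."""

    log_hr: float
    hr: float
    se: float
    ci95: tuple[float, float]
    n_events: int
    score_chi2: float
    ties: str

    @property
    def wald_p(self) -> float:
        return float(chi2.sf((self.log_hr / self.se) ** 2, df=1))


def _cox_derivatives(b: float, times, events, g, ties: str):
    """Log partial likelihood derivatives U(b), I(b) for a binary covariate.

    Works over distinct event times with risk-set sums; g is 0/1 so the
    exp(b g) risk scores take only two values and the risk-set sums reduce
    to counts.
    """
    event_times = np.unique(times[events == 1])
    U = 0.0
    I = 0.0
    eb = np.exp(b)
    for t in event_times:
        at_risk = times >= t
        n1 = int((at_risk & (g == 1)).sum())
        n0 = int(at_risk.sum()) - n1
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & (g == 1)).sum())
        s0 = n0 + n1 * eb  # sum over risk set of exp(b g)
        s1 = n1 * eb       # sum of g exp(b g); g^2 = g so s2 = s1
        if ties == "breslow":
            U += d1 - d * s1 / s0
            I += d * (s1 / s0 - (s1 / s0) ** 2)
        else:  # efron: remove an average tied-death contribution stepwise
            e1 = d1 * eb / d if d else 0.0  # per-step tied-death drain
            e0 = (d - d1) / d if d else 0.0
            for r in range(d):
                s0r = s0 - r * (e0 + e1)
                s1r = s1 - r * e1
                U += d1 / d - s1r / s0r
                I += s1r / s0r - (s1r / s0r) ** 2
    return U, I


def cox_two_group(
    times, events, group, ties: str = "breslow",
    max_iter: int = 100, tol: float = 1e-12,
) -> CoxResult:
    """One-parameter Cox fit by Newton-Raphson on the partial likelihood."""
    if ties not in ("breslow", "efron"):
        raise ValidationError("ties must be 'breslow' or 'efron'")
    times, events = _check_times(times, events)
    g = _check_group(group, len(times))
    n_events = int(events.sum())
    if n_events == 0:
        raise ValidationError("no events: Cox model is undefined")
    u0, i0 = _cox_derivatives(0.0, times, events, g, ties)
    score_chi2 = u0**2 / i0 if i0 > 0 else 0.0
    b = 0.0
    for _ in range(max_iter):
        U, I = _cox_derivatives(b, times, events, g, ties)
        if not np.isfinite(I) or I <= 1e-12:
            raise ConvergenceError(
                "information vanished: the partial likelihood is monotone "
                "(complete separation of event times between groups)"
            )
        step = U / I
        b += step
        if abs(b) > 50:
            raise ConvergenceError(
                "partial likelihood is monotone (complete separation of "
                "event times between groups); hazard ratio diverges"
            )
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} steps")
    _, I = _cox_derivatives(b, times, events, g, ties)
    se = float(1.0 / np.sqrt(I))
    return CoxResult(
        log_hr=float(b), hr=float(np.exp(b)), se=se,
        ci95=(float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
        n_events=n_events, score_chi2=float(score_chi2), ties=ties,
    )


@dataclass
class PrognosisEvaluation:
    """KM curves, log-rank test, and Cox hazard ratio for predicted groups."""

    curve_high: SurvivalCurve
    curve_low: SurvivalCurve
    logrank_chi2: float
    logrank_p: float
    cox: CoxResult
    groups: np.ndarray  # True where predicted high risk

    @property
    def logrank_p_text(self) -> str:
        return format_pvalue(self.logrank_p)


def evaluate_prognosis_groups(
    times, events, scores, threshold: float = 0.0, ties: str = "breslow",
) -> PrognosisEvaluation:
    """Bundle the survival comparison of classifier-predicted groups.

    ``scores`` are real-valued classifier outputs on the +-1-coded risk
    scale (or already-binary group indicators); samples scoring above
    ``threshold`` form the predicted high-risk group.  The Cox model is
    oriented so the hazard ratio is high-risk versus low-risk.
    """
    times, events = _check_times(times, events)
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.shape[0] != times.shape[0]:
        raise ValidationError("scores length does not match survival data")
    high = scores > threshold
    if high.all() or (~high).all():
        raise ValidationError("threshold puts every sample in one group")
    stat, p = logrank_test(times, events, high)
    cox = cox_two_group(times, events, high.astype(int), ties=ties)
    return PrognosisEvaluation(
        curve_high=km_curve(times[high], events[high]),
        curve_low=km_curve(times[~high], events[~high]),
        logrank_chi2=stat, logrank_p=p, cox=cox, groups=high,
    )
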