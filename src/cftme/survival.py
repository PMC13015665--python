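"""Group comparison and survival stratification.

Mann-Whitney U (the default two-group comparison throughout the pipeline),
median-split stratification of module scores, Kaplan-Meier curves, the
log-rank test, and a univariate Cox proportional-hazards model with a Wald
test.

The Cox model is fit by Newton-Raphson on the partial likelihood with
Breslow handling of tied event times; convergence requires the score
(first derivative) to vanish below 1e-8, which is also what the tests
verify directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    effect_estimate: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    log_hr: float
    se: float
    wald_z: float
    p_value: float
    n_iterations: int
    ties: str = "breslow"

    @property
    def test_result(self) -> TestResult:
        return TestResult(self.wald_z, self.p_value, "cox_wald", self.hazard_ratio)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when n1*n2 <= 64 and the pooled sample has no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size * y.size <= 64 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), f"mann_whitney_{method}", float(res.statistic))


def median_split(scores) -> np.ndarray:
    """Binary stratification: strictly above the median -> ``"high"``, else ``"low"``."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("median split needs at least 2 samples")
    if np.all(scores == scores[0]):
        raise ValueError("all scores identical: no stratification possible")
    med = np.median(scores)
    return np.where(scores > med, "high", "low")


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a table with one row per distinct observed time: at-risk count,
    observed events, censored count, and the survival estimate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table.copy()
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
            "events": tab["observed"].to_numpy(dtype=int),
            "censored": tab["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(tab.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


def logrank_test(time, event, groups) -> TestResult:
    """Two-group log-rank test (chi-square on 1 df from observed-expected events)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {levels.size}")
    if event.sum() == 0:
        raise ValueError("log-rank is undefined with no events")
    a = groups == levels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return TestResult(float(res.test_statistic), float(res.p_value), "logrank", float(res.test_statistic))


def _cox_quantities(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Partial log-likelihood, score and information under Breslow ties."""
    order = np.argsort(-time, kind="stable")  # descending time
    xs, ts, es = x[order], time[order], event[order]
    eta = beta * xs
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xs)
    s2 = np.cumsum(w * xs * xs)
    loglik = score = info = 0.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # risk set = everything with time >= ts[i] = entries [0, j)
        d_idx = [k for k in range(i, j) if es[k]]
        if d_idx:
            d = len(d_idx)
            sx = xs[d_idx].sum()
            r0, r1, r2 = s0[j - 1], s1[j - 1], s2[j - 1]
            loglik += beta * sx - d * np.log(r0)
            score += sx - d * r1 / r0
            info += d * (r2 / r0 - (r1 / r0) ** 2)
        i = j
    return loglik, score, info


def cox_partial_loglik(beta: float, x, time, event) -> float:
    """Breslow partial log-likelihood at a given coefficient (for diagnostics)."""
    return _cox_quantities(
        float(beta), np.asarray(x, float), np.asarray(time, float), np.asarray(event, int)
    )[0]


def cox_univariate(
    covariate,
    time,
    event,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit with a Wald test.

    Newton-Raphson on the Breslow partial likelihood; converged when
    |score| < ``tol``.  Raises on a constant covariate, absence of events,
    or monotone likelihood (risk perfectly separated by the covariate).
    """
    x = np.asarray(covariate, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite")
    if np.all(x == x[0]):
        raise ValueError("constant covariate: hazard ratio unidentifiable")
    if event.sum() == 0:
        raise ValueError("no events observed")
    beta = 0.0
    for it in range(1, max_iter + 1):
        _, score, info = _cox_quantities(beta, x, time, event)
        if abs(score) < tol:
            break
        if info <= 0:
            raise RuntimeError("non-positive information: Cox fit failed")
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        # a |log HR| beyond 15 (HR > 3e6) only arises when the covariate
        # perfectly orders the risk and the likelihood is monotone
        if abs(beta) > 15:
            raise RuntimeError("monotone partial likelihood: risk is perfectly separated")
    else:
        _, score, info = _cox_quantities(beta, x, time, event)
        if abs(score) >= tol:
            raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")
        it = max_iter
    _, _, info = _cox_quantities(beta, x, time, event)
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        log_hr=float(beta),
        se=float(se),
        wald_z=float(z),
        p_value=float(p),
        n_iterations=it,
    )


def survival_by_median_score(scores, time, event) -> dict:
    """Fig-2-style stratification: median-split a score vector, then KM per
    stratum, log-rank, and Cox Wald on the high/low indicator."""
    labels = median_split(scores)
    high = labels == "high"
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    return {
        "labels": labels,
        "km_high": kaplan_meier(time[high], event[high]),
        "km_low": kaplan_meier(time[~high], event[~high]),
        "logrank": logrank_test(time, event, labels),
        "cox": cox_univariate(high.astype(float), time, event),
    }
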