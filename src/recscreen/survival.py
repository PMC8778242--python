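"""Kaplan-Meier estimation, log-rank testing, and the expression-cutoff scan.

The scan emulates the "Kaplan scan" stratification: every distinct
expression value that leaves both groups at least ``min_group`` patients is
tested as a cutoff (high group = expression strictly above the cutoff), the
minimal raw log-rank p is reported, and a Bonferroni factor equal to the
number of cutoffs actually tested corrects the minimum-p selection.  The
scan is rank-based over cutoffs, so it is invariant to monotone transforms
of expression.

Single KM curves and the two-group log-rank test wrap lifelines; the scan
itself evaluates the 1-df log-rank statistic for all cutoffs in one
O(n * n_cutoffs) vectorized sweep (cross-checked against lifelines in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .core_io import logger

__all__ = ["km_estimate", "logrank", "kaplan_scan", "ScanResult", "one_way_anova"]


@dataclass
class ScanResult:
    """Best-cutoff log-rank result for one gene."""

    gene: str
    best_cutoff: float
    n_high: int
    n_low: int
    raw_p: float
    chi2: float
    bonf_p: float
    n_cutoffs_tested: int
    km_high: pd.DataFrame = field(repr=False)
    km_low: pd.DataFrame = field(repr=False)


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate as a right-continuous step function.

    Returns a frame with columns time and survival, starting at S(0) = 1.
    A fully censored sample yields a curve flat at 1 (with a warning).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty sample")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if events.sum() == 0:
        logger.warning("km_estimate: no events observed; survival flat at 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Standard 1-df two-group log-rank test: (chi2, p)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.sum(events_a) + np.sum(events_b) == 0:
        raise ValueError("need at least one event")
    res = logrank_test(times_a, times_b,
                       event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def _logrank_scan(
    times: np.ndarray,
    events: np.ndarray,
    high_matrix: np.ndarray,
) -> np.ndarray:
    """1-df log-rank chi-square for many group splits at once.

    ``high_matrix`` is (patients, cutoffs) boolean membership of the high
    group.  Returns chi2 per cutoff.
    """
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    high = high_matrix[order].astype(float)
    n = times.shape[0]
    K = high.shape[1]
    o_minus_e = np.zeros(K)
    var = np.zeros(K)
    at_risk_high = high.sum(axis=0)
    i = 0
    n_at_risk = float(n)
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        block = slice(i, j)
        d = float(events[block].sum())
        if d > 0 and n_at_risk > 1:
            d_high = (events[block, None] * high[block]).sum(axis=0)
            frac = at_risk_high / n_at_risk
            o_minus_e += d_high - d * frac
            var += d * frac * (1 - frac) * (n_at_risk - d) / (n_at_risk - 1)
        at_risk_high -= high[block].sum(axis=0)
        n_at_risk -= j - i
        i = j
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / var, 0.0)
    return chi2


def kaplan_scan(
    cohort: pd.DataFrame,
    gene: str,
    min_group: int | None = None,
) -> ScanResult:
    """Scan every admissible expression cutoff for survival-group separation.

    ``min_group`` defaults to max(8, 5% of the cohort) to forbid degenerate
    tiny groups.  Ties at the cutoff value go to the low group (high group
    is strictly greater).  The best cutoff is the one with minimal raw
    log-rank p; ``bonf_p = min(1, raw_p * n_cutoffs_tested)``.
    """
    if gene not in cohort.columns:
        raise KeyError(f"gene {gene!r} not in cohort")
    expr = cohort[gene].to_numpy(dtype=float)
    ok = np.isfinite(expr)
    if not ok.all():
        logger.warning("kaplan_scan: dropping %d record(s) with non-finite "
                       "expression", int((~ok).sum()))
    times = cohort["time"].to_numpy(dtype=float)[ok]
    events = cohort["event"].to_numpy(dtype=int)[ok]
    expr = expr[ok]
    n = expr.size
    if min_group is None:
        min_group = max(8, int(np.ceil(0.05 * n)))
    if n < 2 * min_group:
        raise ValueError(f"cohort of {n} cannot form two groups of {min_group}")

    values = np.unique(expr)
    n_high_per = (expr[:, None] > values[None, :]).sum(axis=0)
    admissible = (n_high_per >= min_group) & (n - n_high_per >= min_group)
    cutoffs = values[admissible]
    if cutoffs.size == 0:
        raise ValueError("no admissible cutoff")

    high = expr[:, None] > cutoffs[None, :]
    chi2 = _logrank_scan(times, events, high)
    raw_p = stats.chi2.sf(chi2, df=1)
    raw_p = np.where(chi2 > 0, raw_p, 1.0)
    best = int(np.argmin(raw_p))
    best_cut = float(cutoffs[best])
    hi = expr > best_cut
    return ScanResult(
        gene=gene,
        best_cutoff=best_cut,
        n_high=int(hi.sum()),
        n_low=int((~hi).sum()),
        raw_p=float(raw_p[best]),
        chi2=float(chi2[best]),
        bonf_p=float(min(1.0, raw_p[best] * cutoffs.size)),
        n_cutoffs_tested=int(cutoffs.size),
        km_high=km_estimate(times[hi], events[hi]),
        km_low=km_estimate(times[~hi], events[~hi]),
    )


def one_way_anova(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Descriptive helper: per-group means plus a one-way ANOVA p-value.

    Used for stage-wise expression summaries in reports; not a scored stage.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    f, p = stats.f_oneway(*arrays)
    rows = [
        {"group": k, "n": a.size, "mean": a.mean(), "sd": a.std(ddof=1) if a.size > 1 else np.nan}
        for k, a in zip(groups, arrays)
    ]
    df = pd.DataFrame(rows)
    df["anova_F"] = f
    df["anova_p"] = p
    return df
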