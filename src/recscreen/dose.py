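"""IC50 estimation from viability-vs-concentration tables.

Two estimators are provided: a four-parameter logistic (4PL) fit with free
top and bottom asymptotes, least-squares on log-dose with three fixed
multi-starts (deterministic given the data), and a log-linear interpolation
between the doses bracketing 50% viability.  The dose-0 control is excluded
from the log-dose fit (log 0 is undefined) and used only to normalize
viability to percent of control.

The reported IC50 is the half-effect point of the fitted transition (the
4PL midpoint parameter).  Fits whose IC50 falls outside
[min positive dose / 10, max dose * 10] are flagged extrapolated; a curve
that never crosses 50% is not identifiable and raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["fit_ic50", "Ic50Fit"]


@dataclass(frozen=True)
class Ic50Fit:
    ic50: float
    hill: float
    method: str
    top: float
    bottom: float
    rss: float
    extrapolated: bool


def _validate(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    for col in ("dose", "viability"):
        if col not in table.columns:
            raise ValueError(f"dose-response table missing column {col!r}")
    doses = table["dose"].to_numpy(dtype=float)
    viab = table["viability"].to_numpy(dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be nonnegative")
    if not np.isfinite(viab).all():
        raise ValueError("non-finite viability")
    return doses, viab


def _normalize(doses: np.ndarray, viab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale viability to percent of the dose-0 control mean; drop dose 0.

    Without a dose-0 record, viability is taken as already percent of
    control.
    """
    if np.any(doses == 0):
        baseline = viab[doses == 0].mean()
        if baseline <= 0:
            raise ValueError("non-positive dose-0 baseline")
        viab = viab / baseline * 100.0
    pos = doses > 0
    return doses[pos], viab[pos]


def _four_pl(logd: np.ndarray, log_ic50: float, hill: float,
             top: float, bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logd - log_ic50)))


def fit_ic50(table: pd.DataFrame, method: str = "4pl") -> Ic50Fit:
    """Estimate the IC50 from a viability table (columns dose, viability).

    ``method='4pl'`` fits the four-parameter logistic (requires >= 4
    distinct positive doses); ``method='interpolation'`` log-linearly
    interpolates the mean viability between the doses bracketing 50%.
    Raises ``ValueError('IC50 not identifiable')`` when the response never
    crosses half-maximum.
    """
    doses, viab = _validate(table)
    d, v = _normalize(doses, viab)
    lo_band = d.min() / 10.0
    hi_band = d.max() * 10.0

    if method == "interpolation":
        means = pd.Series(v).groupby(pd.Series(d)).mean()
        dd, vv = means.index.to_numpy(), means.to_numpy()
        ic50 = None
        for i in range(len(dd) - 1):
            v0, v1 = vv[i], vv[i + 1]
            if (v0 - 50.0) * (v1 - 50.0) <= 0 and v0 != v1:
                frac = (v0 - 50.0) / (v0 - v1)
                log_ic = np.log10(dd[i]) + frac * (np.log10(dd[i + 1]) - np.log10(dd[i]))
                ic50 = 10.0 ** log_ic
                break
        if ic50 is None:
            raise ValueError("IC50 not identifiable: no 50% crossing")
        hill_est = np.nan
        return Ic50Fit(ic50=float(ic50), hill=hill_est, method=method,
                       top=float(vv.max()), bottom=float(vv.min()), rss=np.nan,
                       extrapolated=not lo_band <= ic50 <= hi_band)

    if method != "4pl":
        raise ValueError("method must be '4pl' or 'interpolation'")
    if np.unique(d).size < 4:
        raise ValueError("4PL fit requires >= 4 distinct positive doses")

    logd = np.log(d)
    top0, bot0 = float(v.max()), float(v.min())
    geo = float(np.exp(logd.mean()))
    best = None
    for ic0 in (geo, float(d.min()), float(d.max())):
        x0 = np.array([np.log(ic0), 1.0, top0, bot0])
        res = least_squares(
            lambda x: _four_pl(logd, *x) - v,
            x0,
            bounds=([np.log(lo_band / 10), 0.05, -50.0, -50.0],
                    [np.log(hi_band * 10), 20.0, 200.0, 200.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    rss, (log_ic50, hill, top, bottom) = best
    ic50 = float(np.exp(log_ic50))
    # identifiability: the fitted transition must actually cross 50%
    if not (min(top, bottom) < 50.0 < max(top, bottom)):
        raise ValueError("IC50 not identifiable: fitted curve does not cross 50%")
    return Ic50Fit(ic50=ic50, hill=float(hill), method="4pl",
                   top=float(top), bottom=float(bottom), rss=rss,
                   extrapolated=not lo_band <= ic50 <= hi_band)
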