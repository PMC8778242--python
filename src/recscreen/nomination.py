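"""Candidate nomination: basal-expression/sensitivity correlation crossed
with REC recurrence evidence.

A compound is nominated when, for *every* target gene and *every* timepoint,
its REC score is negative, survives the FDR cutoff and ranks inside the
top-k most negative scores, and when for every target gene the basal
expression of the gene correlates negatively with the compound's sensitivity
AUC (lower AUC = more sensitive, so "high expression -> sensitive" is r < 0)
at the configured p cutoff.  All filters combine by conjunction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RunConfig, logger
from .rec import rank_rec

__all__ = [
    "CorrelationResult",
    "sensitivity_correlation",
    "correlate_all",
    "nominate",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Basal expression vs sensitivity AUC correlation across cell lines."""

    gene: str
    compound: str
    n: int
    r: float
    p: float
    method: str = "pearson"


def sensitivity_correlation(
    expr: pd.DataFrame,
    sens: pd.DataFrame,
    gene: str,
    compound: str,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate basal expression of ``gene`` with the AUC of ``compound``
    across their shared cell lines.

    ``expr`` is (cell line x gene, log2 scale); ``sens`` is
    (compound x cell line) AUC.  Requires >= 3 shared cell lines with finite
    values; a zero-variance vector is a degenerate correlation and an error.
    """
    if gene not in expr.columns:
        raise KeyError(f"gene {gene!r} not in basal expression matrix")
    if compound not in sens.index:
        raise KeyError(f"compound {compound!r} not in sensitivity table")
    shared = expr.index.intersection(sens.columns)
    x = expr.loc[shared, gene].to_numpy(dtype=float)
    y = sens.loc[compound, shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(
            f"({gene}, {compound}): only {n} shared cell line(s) with finite "
            "values; need >= 3"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"({gene}, {compound}): degenerate correlation "
                         "(zero variance)")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(gene=gene, compound=compound, n=n,
                             r=float(r), p=float(p), method=method)


def correlate_all(
    expr: pd.DataFrame,
    sens: pd.DataFrame,
    genes: list[str],
    compounds: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation results for every (target gene, compound) pair as a frame."""
    compounds = list(compounds) if compounds is not None else list(sens.index)
    rows = []
    for g in genes:
        for c in compounds:
            try:
                res = sensitivity_correlation(expr, sens, g, c, method=method)
            except ValueError as exc:
                logger.warning("correlation skipped: %s", exc)
                continue
            rows.append(vars(res))
    return pd.DataFrame(rows)


def nominate(
    rec: pd.DataFrame,
    corr: pd.DataFrame,
    config: RunConfig,
    target_genes: list[str],
    timepoints: list[str] | None = None,
) -> pd.DataFrame:
    """Join REC and correlation evidence into a per-compound candidate table.

    Returns one row per compound with, for every (target gene, timepoint):
    rec, fdr and top-k membership; per target gene: r and p; and the final
    ``nominated`` flag (AND of all filters).
    """
    if corr is None or len(corr) == 0:
        raise ValueError("empty correlation evidence")
    if timepoints is None:
        timepoints = sorted(rec["timepoint"].unique())
    compounds = sorted(rec["compound"].unique())
    table = pd.DataFrame(index=pd.Index(compounds, name="compound"))
    nominated = pd.Series(True, index=table.index)

    for g in target_genes:
        for t in timepoints:
            sl = rec[(rec["gene"] == g) & (rec["timepoint"] == t)]
            if sl.empty:
                raise KeyError(f"missing REC slice ({g}, {t})")
            sl = sl.set_index("compound")
            top = set(rank_rec(rec, g, t, config.rec_top_k))
            col = f"{g}_{t}"
            table[f"rec_{col}"] = sl["rec"]
            table[f"fdr_{col}"] = sl["fdr"]
            table[f"top{config.rec_top_k}_{col}"] = [
                c in top for c in table.index
            ]
            passes = (
                (table[f"rec_{col}"] < 0)
                & (table[f"fdr_{col}"] <= config.rec_fdr_max)
                & table[f"top{config.rec_top_k}_{col}"]
            )
            nominated &= passes.fillna(False)

    for g in target_genes:
        gc = corr[corr["gene"] == g]
        if gc.empty:
            raise KeyError(f"missing correlation evidence for gene {g}")
        gc = gc.set_index("compound")
        table[f"r_{g}"] = gc["r"].reindex(table.index)
        table[f"p_{g}"] = gc["p"].reindex(table.index)
        passes = (table[f"r_{g}"] < 0) & (table[f"p_{g}"] <= config.corr_p_max)
        nominated &= passes.fillna(False)

    table["nominated"] = nominated
    return table.reset_index()
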