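"""Preranked gene set enrichment analysis on REC-ranked gene lists.

The enrichment score is the classic weighted Kolmogorov-Smirnov running sum:
walking down the ranked list, hitting a set member increments the sum in
proportion to |score|^weight (normalized over the set's hits) and missing
decrements by 1/(N - Nh); the ES is the signed maximum deviation, and the
leading edge is the set members encountered up to (for positive ES) or after
(for negative ES) the extremum.

Null distributions come from gene-label permutation: shuffling which genes
carry which scores is equivalent to placing the set's members at random list
positions.  (A sample-level permutation is not defined for a preranked list,
which carries no samples.)  NES normalizes the ES by the mean of the
same-sign null ES; the FDR q-value is the standard GSEA ratio of null to
observed NES tail fractions, pooled across sets and clipped to [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import GeneSetCollection, RunConfig, logger, substream

__all__ = ["make_ranked_list", "enrichment_score", "gsea"]


def make_ranked_list(
    rec: pd.DataFrame,
    compound: str,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Ranked gene list (descending REC score) for one compound.

    ``timepoint=None`` averages the available timepoints per gene; otherwise
    a single slice is used.  Ties are broken stably by gene identifier.
    """
    sl = rec[rec["compound"] == compound]
    if timepoint is not None:
        sl = sl[sl["timepoint"] == timepoint]
    if sl.empty:
        raise KeyError(f"no REC results for compound {compound!r}")
    scores = sl.groupby("gene")["rec"].mean()
    df = scores.reset_index().rename(columns={"rec": "score"})
    df = df.sort_values(["gene"], kind="mergesort")
    df = df.sort_values(["score"], ascending=False, kind="mergesort")
    return df.reset_index(drop=True)


def _es_core(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """ES and extremum index from the full running sum (O(N))."""
    N = scores.shape[0]
    Nh = int(hit_mask.sum())
    w = np.abs(scores[hit_mask]) ** weight
    if w.sum() == 0:
        w = np.ones(Nh)
    steps = np.zeros(N)
    steps[hit_mask] = w / w.sum()
    if Nh < N:
        steps[~hit_mask] = -1.0 / (N - Nh)
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def enrichment_score(
    ranked: pd.DataFrame,
    gene_set: tuple[str, ...] | list[str] | set[str],
    weight: float = 1.0,
) -> tuple[float, list[str]] | None:
    """Enrichment score and leading edge of one gene set.

    Returns None (and logs) when the set does not intersect the list.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hit_mask = np.isin(genes, list(gene_set))
    if not hit_mask.any():
        logger.info("gene set disjoint from ranked list; skipped")
        return None
    es, i = _es_core(scores, hit_mask, weight)
    if es >= 0:
        leading = genes[: i + 1][hit_mask[: i + 1]]
    else:
        leading = genes[i:][hit_mask[i:]]
    return es, [str(g) for g in leading]


def _null_es_batch(
    scores: np.ndarray, k: int, B: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """B null enrichment scores for a set of size k under gene-label
    permutation, evaluated only at hit positions (O(B * k * log k))."""
    N = scores.shape[0]
    pos = np.empty((B, k), dtype=np.int64)
    for b in range(B):
        pos[b] = rng.choice(N, size=k, replace=False)
    pos.sort(axis=1)
    w = np.abs(scores[pos]) ** weight
    wsum = w.sum(axis=1, keepdims=True)
    zero = wsum[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        wsum[zero] = k
    cum_hit = np.cumsum(w, axis=1) / wsum
    miss_step = 1.0 / (N - k) if k < N else 0.0
    j = np.arange(k)
    # running sum right after the j-th hit, and right before it
    after = cum_hit - (pos - j) * miss_step
    before = after - w / wsum
    cand = np.concatenate([after, before], axis=1)
    # the walk ends at 0 only in exact balance; endpoint candidates suffice
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def gsea(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    config: RunConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Enrichment results for every admissible set in the collection.

    Sets are filtered to an intersection size within
    [gsea_set_min, gsea_set_max]; the null uses ``gsea_permutations``
    gene-label permutations.  Results are sorted by NES, descending.
    """
    if len(ranked) <= config.gsea_set_min:
        raise ValueError("ranked list shorter than gsea_set_min")
    seed = config.seed if seed is None else seed
    rng = substream(seed, "gsea")
    scores = ranked["score"].to_numpy(dtype=float)
    genes = ranked["gene"].to_numpy()
    B, weight = config.gsea_permutations, config.gsea_weight

    kept: list[tuple[str, np.ndarray]] = []
    for name in collection.names():
        hit_mask = np.isin(genes, list(collection.members(name)))
        k = int(hit_mask.sum())
        if k == 0:
            logger.info("set %s disjoint from list; skipped", name)
            continue
        if not config.gsea_set_min <= k <= config.gsea_set_max:
            logger.info("set %s size %d outside [%d, %d]; excluded",
                        name, k, config.gsea_set_min, config.gsea_set_max)
            continue
        kept.append((name, hit_mask))
    if not kept:
        raise ValueError("no gene sets remain after size filtering")

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, hit_mask in kept:
        k = int(hit_mask.sum())
        es, i = _es_core(scores, hit_mask, weight)
        if k not in null_cache:
            null_cache[k] = _null_es_batch(scores, k, B, weight, rng)
        null = null_cache[k]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        if es >= 0:
            p = (1 + int(np.sum(pos_null >= es))) / (1 + pos_null.size)
            nes = es / mean_pos if pos_null.size else np.nan
        else:
            p = (1 + int(np.sum(neg_null <= es))) / (1 + neg_null.size)
            nes = es / mean_neg if neg_null.size else np.nan
        null_nes = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        if es >= 0:
            leading = genes[: i + 1][hit_mask[: i + 1]]
        else:
            leading = genes[i:][hit_mask[i:]]
        rows.append(
            {
                "set": name, "size_used": k, "es": es, "nes": nes, "p": p,
                "leading_edge": ",".join(map(str, leading)),
            }
        )

    df = pd.DataFrame(rows)
    pooled = np.concatenate(null_nes_pool)
    obs = df["nes"].to_numpy(dtype=float)
    q = np.full(len(df), np.nan)
    n_null_pos = max(1, int(np.sum(pooled >= 0)))
    n_null_neg = max(1, int(np.sum(pooled < 0)))
    n_obs_pos = max(1, int(np.sum(obs >= 0)))
    n_obs_neg = max(1, int(np.sum(obs < 0)))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = np.sum(pooled >= nes) / n_null_pos
            obs_frac = np.sum(obs >= nes) / n_obs_pos
        else:
            null_frac = np.sum(pooled <= nes) / n_null_neg
            obs_frac = np.sum(obs <= nes) / n_obs_neg
        q[i] = min(1.0, null_frac / max(obs_frac, 1e-12))
    df["fdr_q"] = q
    return df.sort_values("nes", ascending=False).reset_index(drop=True)
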