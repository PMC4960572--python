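"""Empirical significance of similarity scores.

A raw similarity score has no intrinsic scale — each measure distributes
differently over the all-pairs background.  Significance is therefore
empirical, per method, in four steps:

1. score all disease pairs with the method;
2. z-score each value against the mean and population standard
   deviation of that all-pairs background;
3. convert to a one-sided upper-tail P-value (high similarity = small P)
   under a standard-normal reference;
4. adjust for multiplicity with the Benjamini-Hochberg step-up
   procedure, the family being all scored pairs of the method in the run.

A pair is then called significant at ``alpha`` (0.05 or 0.10 by
convention) when its adjusted P falls below it; a result table retains a
pair when at least ``min_methods`` methods call it significant, and
renders the per-method cells that fail the threshold as null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from dsim.errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackgroundStats:
    """All-pairs score distribution summary for one method."""

    method: str
    mean: float
    sd: float
    n_pairs: int


def background(scores: Sequence[float], method: str = "") -> BackgroundStats:
    """Mean and population SD of the non-null all-pairs scores.

    Requires at least two scores and nonzero variance — a constant
    background admits no z-scoring.
    """
    arr = np.asarray([s for s in scores if s is not None and math.isfinite(s)],
                     dtype=float)
    if arr.size < 2:
        raise InputError(
            f"background for {method or 'method'} needs >= 2 scores, "
            f"got {arr.size}"
        )
    sd = float(arr.std(ddof=0))
    if sd == 0.0:
        raise InputError(f"degenerate background for {method or 'method'}: "
                         "all scores equal")
    return BackgroundStats(method=method, mean=float(arr.mean()), sd=sd,
                           n_pairs=int(arr.size))


def zscore(score: float, stats: BackgroundStats) -> float:
    return (score - stats.mean) / stats.sd


def one_sided_p(score: float, stats: BackgroundStats) -> float:
    """Upper-tail P-value ``1 - Phi(z)``; strictly decreasing in score."""
    return float(norm.sf(zscore(score, stats)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order.

    Sort ascending, set ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at
    1, and undo the sort.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def attach_significance(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, BackgroundStats]]:
    """Add z, p, q columns to a long (d1, d2, method, score) table.

    Null scores keep null z/p/q; the BH family is the set of scored pairs
    of each method.  Returns the augmented table and the per-method
    background statistics.
    """
    out = records.copy()
    out["z"] = np.nan
    out["p"] = np.nan
    out["q"] = np.nan
    backgrounds: dict[str, BackgroundStats] = {}
    for method, group in out.groupby("method", sort=False):
        scored = group["score"].notna()
        if scored.sum() < 2:
            logger.warning("method %s: fewer than 2 scored pairs, "
                           "no significance computed", method)
            continue
        stats = background(group.loc[scored, "score"].tolist(), method)
        backgrounds[method] = stats
        idx = group.index[scored]
        z = (out.loc[idx, "score"] - stats.mean) / stats.sd
        out.loc[idx, "z"] = z
        out.loc[idx, "p"] = norm.sf(z)
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out, backgrounds


def significant_pairs(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_methods: int = 1,
) -> pd.DataFrame:
    """Wide per-pair table of significant results.

    A pair is retained when at least ``min_methods`` methods give it an
    adjusted P below ``alpha`` ("1 or more" = union over methods).  Cells
    of methods that fail the threshold are nulled, never zeroed.  Columns:
    ``d1, d2, n_significant, <method>_score, <method>_q`` per method.
    """
    if alpha not in (0.05, 0.10):
        logger.warning("non-standard significance threshold alpha=%g", alpha)
    if min_methods < 1:
        raise InputError("min_methods must be >= 1")
    rec = records.copy()
    sig = rec["q"] < alpha
    rec.loc[~sig.fillna(False), ["score", "z", "p", "q"]] = np.nan

    methods = list(dict.fromkeys(records["method"]))
    wide = rec.pivot_table(
        index=["d1", "d2"], columns="method", values=["score", "q"],
        aggfunc="first", dropna=False, observed=True,
    )
    rows = []
    for (d1, d2), row in wide.iterrows():
        n_sig = sum(
            1 for m in methods
            if ("q", m) in row.index and pd.notna(row[("q", m)])
        )
        if n_sig < min_methods:
            continue
        entry = {"d1": d1, "d2": d2, "n_significant": n_sig}
        for m in methods:
            entry[f"{m}_score"] = row.get(("score", m), np.nan)
            entry[f"{m}_q"] = row.get(("q", m), np.nan)
        rows.append(entry)
    cols = ["d1", "d2", "n_significant"]
    for m in methods:
        cols += [f"{m}_score", f"{m}_q"]
    out = pd.DataFrame(rows, columns=cols)
    if not out.empty:
        out["best_q"] = out[[f"{m}_q" for m in methods]].min(axis=1)
        out = out.sort_values(
            ["best_q", "d1", "d2"], kind="stable"
        ).drop(columns="best_q").reset_index(drop=True)
    return out
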