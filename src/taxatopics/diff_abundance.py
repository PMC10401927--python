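"""Two-group differential abundance on log relative abundances with
compositional bias correction.

Per feature, an ordinary least-squares fit of log2 relative abundance
(after an optional winsorization and a pseudocount) on the group indicator
gives a raw coefficient.  Because the log-ratio transform confounds every
feature with the unobserved sampling fractions, the shared compositional
bias is estimated as the mode of the raw coefficient distribution (kernel
density) and subtracted before testing.  Dual thresholds on the raw p and
the BH q call significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CountTable, DaResult, TopicAbundanceTable

__all__ = [
    "winsorize",
    "linda_fit",
    "benjamini_hochberg",
    "call_significant",
]


def winsorize(values: np.ndarray, upper_quantile: float = 0.97) -> np.ndarray:
    """Cap values above the per-feature empirical upper quantile.

    Only the upper tail is touched; the empirical quantile uses linear
    interpolation of order statistics.
    """
    if not 0.5 < upper_quantile <= 1.0:
        raise ValueError("upper_quantile must be in (0.5, 1]")
    values = np.asarray(values, dtype=float)
    if upper_quantile == 1.0:
        return values.copy()
    cap = np.quantile(values, upper_quantile, method="linear")
    return np.minimum(values, cap)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be a vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _mode_of(values: np.ndarray) -> float:
    """Mode of an empirical distribution via a Gaussian KDE grid search."""
    values = np.asarray(values, dtype=float)
    if values.size == 1 or np.allclose(values, values[0]):
        return float(values[0])
    kde = stats.gaussian_kde(values)
    bw = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, 512)
    return float(grid[np.argmax(kde(grid))])


def linda_fit(
    table: CountTable | TopicAbundanceTable,
    group_key: str | None = None,
    winsorize_flag: bool = False,
    pseudocount: float = 0.5,
    winsor_quantile: float = 0.97,
    p_max: float = 0.05,
    q_max: float = 0.25,
    reference_level: str | None = None,
) -> DaResult:
    """Two-group differential abundance with mode-based bias correction.

    Requires exactly two group levels with >= 2 samples each.  The effect is
    the bias-corrected log2 fold change of the second level relative to the
    reference (alphabetically first unless given).  Features with zero
    residual variance are flagged degenerate with p = 1.
    """
    group = table.group
    if group is None:
        raise ValueError("table has no group labels; attach metadata first")
    labels = [g for g in group]
    if any(g is None for g in labels):
        raise ValueError("every sample must have a non-missing group label")
    levels = sorted({str(g) for g in labels})
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, found {len(levels)}: {levels}")
    if reference_level is None:
        reference_level = levels[0]
    elif reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} not among {levels}")
    other = [lv for lv in levels if lv != reference_level][0]
    x = np.array([0.0 if str(g) == reference_level else 1.0 for g in labels])
    n0, n1 = int((x == 0).sum()), int((x == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each group level needs at least 2 samples")

    counts = np.asarray(table.counts, dtype=float)
    if winsorize_flag:
        counts = np.column_stack(
            [winsorize(counts[:, j], winsor_quantile) for j in range(counts.shape[1])]
        )
    y = counts + pseudocount
    z = np.log2(y) - np.log2(y.sum(axis=1))[:, None]  # log2 relative abundance

    n = z.shape[0]
    df = n - 2
    mean1 = z[x == 1].mean(axis=0)
    mean0 = z[x == 0].mean(axis=0)
    raw = mean1 - mean0
    resid = z.copy()
    resid[x == 1] -= mean1
    resid[x == 0] -= mean0
    s2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))

    m = z.shape[1]
    degenerate = se <= 0
    if m == 1:
        # bias correction collapses: report a null result by convention
        effect = np.zeros(1)
        p = np.ones(1)
        t = np.zeros(1)
        degenerate = np.ones(1, dtype=bool)
        bias = float(raw[0])
    else:
        bias = _mode_of(raw)
        effect = raw - bias
        t = np.zeros(m)
        np.divide(effect, se, out=t, where=~degenerate)
        p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    q = benjamini_hochberg(p)
    frame = pd.DataFrame(
        {
            "feature": list(table.feature_ids),
            "effect_log2": effect,
            "se": se,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": (p <= p_max) & (q <= q_max),
            "degenerate": degenerate,
        }
    )
    meta = {
        "winsorized": bool(winsorize_flag),
        "pseudocount": pseudocount,
        "winsor_quantile": winsor_quantile,
        "group_levels": levels,
        "reference_level": reference_level,
        "contrast_level": other,
        "bias": float(bias),
        "p_max": p_max,
        "q_max": q_max,
        "group_key": group_key,
    }
    return DaResult(table=frame, meta=meta)


def call_significant(result: DaResult, p_max: float = 0.05, q_max: float = 0.25) -> DaResult:
    """Re-flag significance under the dual rule p <= p_max AND q <= q_max
    (boundary values inclusive)."""
    frame = result.table.copy()
    frame["significant"] = (frame["p"] <= p_max) & (frame["q"] <= q_max)
    meta = dict(result.meta)
    meta.update(p_max=p_max, q_max=q_max)
    return DaResult(table=frame, meta=meta)
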