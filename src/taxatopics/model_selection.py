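"""Topic-number selection: topic-density and singular-value divergence metrics.

Two criteria are computed over a grid of candidate topic numbers and both
are minimized:

* ``caojuan_metric`` — mean pairwise cosine similarity among topic-term
  rows (distinct topics score low).
* ``arun_metric`` — symmetric KL divergence between the normalized singular
  values of the topic-term matrix and the length-weighted aggregate
  topic distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svdvals

from .data_model import CountTable
from .lda import LdaModel, fit_lda

__all__ = ["KSelectionResult", "caojuan_metric", "arun_metric", "select_topic_number"]

_KL_FLOOR = 1e-12


@dataclass
class KSelectionResult:
    """Metric curves over a K grid and the averaged choice."""

    k_grid: list[int]
    caojuan: np.ndarray  # n_tables x n_K
    arun: np.ndarray     # n_tables x n_K
    best_k_per_metric: dict[str, list[int]]  # metric -> per-table argmin K
    chosen_k: int
    table_names: list[str] = field(default_factory=list)

    def curves_frame(self):
        import pandas as pd

        rows = []
        for t, name in enumerate(self.table_names):
            for j, k in enumerate(self.k_grid):
                rows.append(
                    {"table": name, "K": k,
                     "caojuan": self.caojuan[t, j], "arun": self.arun[t, j]}
                )
        return pd.DataFrame(rows)


def caojuan_metric(beta: np.ndarray) -> float:
    """Mean pairwise cosine similarity among the rows of ``beta``."""
    beta = np.asarray(beta, dtype=float)
    K = beta.shape[0]
    if K < 2:
        raise ValueError("metric requires at least 2 topics")
    norms = np.linalg.norm(beta, axis=1)
    unit = beta / norms[:, None]
    cos = unit @ unit.T
    iu = np.triu_indices(K, k=1)
    return float(cos[iu].mean())


def arun_metric(
    beta: np.ndarray, gamma_norm: np.ndarray, doc_lengths: np.ndarray
) -> float:
    """Symmetric KL between beta's singular-value spectrum and the
    length-weighted topic distribution, both normalized to sum 1."""
    beta = np.asarray(beta, dtype=float)
    gamma_norm = np.asarray(gamma_norm, dtype=float)
    doc_lengths = np.asarray(doc_lengths, dtype=float)
    K = beta.shape[0]
    if gamma_norm.shape[1] != K:
        raise ValueError("gamma_norm column count must equal beta row count")
    if doc_lengths.shape[0] != gamma_norm.shape[0]:
        raise ValueError("doc_lengths must align with gamma_norm rows")
    if np.any(doc_lengths <= 0):
        raise ValueError("doc_lengths must be positive")
    if K > min(gamma_norm.shape[0], beta.shape[1]):
        raise ValueError("K must not exceed min(D, V)")
    c1 = svdvals(beta)
    c1 = c1 / c1.sum()
    c2 = doc_lengths @ gamma_norm
    c2 = c2 / c2.sum()
    c1 = np.maximum(c1, _KL_FLOOR)
    c2 = np.maximum(c2, _KL_FLOOR)
    c1, c2 = c1 / c1.sum(), c2 / c2.sum()
    return float(np.sum(c1 * np.log(c1 / c2)) + np.sum(c2 * np.log(c2 / c1)))


def _argmin_smallest_k(values: np.ndarray, k_grid: list[int]) -> int:
    """Smallest K attaining the minimum (parsimony tie-break)."""
    vmin = values.min()
    for k, v in zip(k_grid, values):
        if v == vmin:
            return k
    raise AssertionError("unreachable")


def select_topic_number(
    tables: CountTable | list[CountTable],
    k_grid: list[int],
    seed: int = 0,
    lda_settings: dict | None = None,
    table_names: list[str] | None = None,
) -> KSelectionResult:
    """Fit every K on every table, evaluate both metrics, average the argmins.

    ``chosen_k`` is the round-half-to-even mean of the per-metric per-table
    minimizing K values.  Each K is fitted with the same seed and restart
    count for comparability.
    """
    if isinstance(tables, CountTable):
        tables = [tables]
    k_grid = sorted(int(k) for k in k_grid)
    if len(k_grid) < 2:
        raise ValueError("k_grid must contain at least 2 values")
    if any(k < 2 for k in k_grid):
        raise ValueError("all K in the grid must be >= 2")
    settings = dict(lda_settings or {})
    names = table_names or [f"table_{i + 1}" for i in range(len(tables))]

    cao = np.empty((len(tables), len(k_grid)))
    arn = np.empty((len(tables), len(k_grid)))
    for t, table in enumerate(tables):
        for j, k in enumerate(k_grid):
            model: LdaModel = fit_lda(table, K=k, seed=seed, **settings)
            cao[t, j] = caojuan_metric(model.beta)
            arn[t, j] = arun_metric(
                model.beta, model.gamma_norm, table.library_sizes
            )
    best = {
        "caojuan": [_argmin_smallest_k(cao[t], k_grid) for t in range(len(tables))],
        "arun": [_argmin_smallest_k(arn[t], k_grid) for t in range(len(tables))],
    }
    all_best = best["caojuan"] + best["arun"]
    # round-half-to-even, matching Python's round()
    chosen = int(round(float(np.mean(all_best))))
    return KSelectionResult(
        k_grid=k_grid,
        caojuan=cao,
        arun=arn,
        best_k_per_metric=best,
        chosen_k=chosen,
        table_names=names,
    )
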