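"""Prevalence filtering, rank aggregation, and relative abundance."""

from __future__ import annotations

from typing import Literal

import numpy as np

from .data_model import CountTable, TaxonomyTable

__all__ = ["filter_low_prevalence", "aggregate_to_rank", "relative_abundance"]

UNCLASSIFIED = "unclassified"


def filter_low_prevalence(
    table: CountTable,
    threshold: float = 1e-5,
    basis: Literal["overall", "mean-per-sample", "max-per-sample"] = "overall",
) -> CountTable:
    """Remove features whose relative abundance falls below ``threshold``.

    The default basis is overall relative abundance: feature total divided
    by the grand total of the table.  Per-sample bases are available for
    sensitivity analysis.  The returned table carries the dropped feature
    IDs on its ``filter_log`` attribute; the sample set is unchanged.
    """
    if table.n_features == 0 or table.n_samples == 0:
        raise ValueError("table is empty")
    grand = table.counts.sum()
    if grand <= 0:
        raise ValueError("grand total is zero; nothing to filter on")
    if basis == "overall":
        rel = table.counts.sum(axis=0) / grand
    elif basis in ("mean-per-sample", "max-per-sample"):
        totals = table.library_sizes
        if np.any(totals <= 0):
            bad = table.sample_ids[int(np.argmax(totals <= 0))]
            raise ValueError(f"sample {bad!r} has zero total")
        per_sample = table.counts / totals[:, None]
        rel = per_sample.mean(axis=0) if basis == "mean-per-sample" else per_sample.max(axis=0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    keep = rel >= threshold
    out = CountTable(
        table.counts[:, keep],
        list(table.sample_ids),
        [f for f, k in zip(table.feature_ids, keep) if k],
        None if table.group is None else list(table.group),
    )
    out.filter_log = [f for f, k in zip(table.feature_ids, keep) if not k]
    return out


def aggregate_to_rank(
    table: CountTable, taxonomy: TaxonomyTable, rank: str = "genus"
) -> CountTable:
    """Sum counts of features sharing the same label at ``rank``.

    Features with a missing/empty label at the rank are pooled under a
    single ``unclassified`` feature.  Grand total is conserved exactly.
    """
    labels = []
    for fid in table.feature_ids:
        if fid not in taxonomy:
            raise ValueError(f"feature {fid!r} absent from taxonomy")
        lab = taxonomy.label(fid, rank).strip()
        labels.append(lab if lab else UNCLASSIFIED)
    # stable first-appearance order of aggregated labels
    out_labels: list[str] = []
    index: dict[str, int] = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(out_labels)
            out_labels.append(lab)
    agg = np.zeros((table.n_samples, len(out_labels)))
    for j, lab in enumerate(labels):
        agg[:, index[lab]] += table.counts[:, j]
    return CountTable(
        agg,
        list(table.sample_ids),
        out_labels,
        None if table.group is None else list(table.group),
    )


def relative_abundance(table: CountTable) -> np.ndarray:
    """Per-sample proportions; each row sums to 1.

    Raises on zero-total samples, naming the first offender.
    """
    totals = table.library_sizes
    if np.any(totals <= 0):
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return table.counts / totals[:, None]
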