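"""Read-to-topic assignment and cross-cohort topic matching."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import CountTable, TopicAbundanceTable
from .lda import LdaModel

__all__ = [
    "TopicMatch",
    "assign_reads",
    "topic_cosine_matrix",
    "match_topics",
    "top_terms",
]


@dataclass
class TopicMatch:
    """A retained cross-cohort topic pair."""

    topic_a: str
    topic_b: str
    cosine: float


def assign_reads(model: LdaModel, table: CountTable, round_to_int: bool = False) -> TopicAbundanceTable:
    """Distribute each sample's reads across topics in proportion to gamma.

    ``values[d][k] = gamma_norm[d][k] * library_size(d)``; row sums equal the
    library sizes exactly up to floating tolerance.  Values stay fractional
    unless ``round_to_int`` requests largest-remainder integer rounding.
    """
    if model.sample_ids and list(model.sample_ids) != list(table.sample_ids):
        raise ValueError("model was not fitted on this table (sample sets differ)")
    if model.gamma_norm.shape[0] != table.n_samples:
        raise ValueError("model/table sample count mismatch")
    values = model.gamma_norm * table.library_sizes[:, None]
    if round_to_int:
        values = _largest_remainder_round(values)
    return TopicAbundanceTable(
        values,
        list(table.sample_ids),
        model.topic_ids,
        None if table.group is None else list(table.group),
    )


def _largest_remainder_round(values: np.ndarray) -> np.ndarray:
    out = np.floor(values)
    for d in range(values.shape[0]):
        short = int(round(values[d].sum() - out[d].sum()))
        if short > 0:
            frac = values[d] - out[d]
            top = np.argsort(-frac)[:short]
            out[d, top] += 1
    return out


def _align_union(
    beta_a: np.ndarray, vocab_a: list[str], beta_b: np.ndarray, vocab_b: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    union = list(vocab_a) + [v for v in vocab_b if v not in set(vocab_a)]
    pos = {v: i for i, v in enumerate(union)}
    a = np.zeros((beta_a.shape[0], len(union)))
    b = np.zeros((beta_b.shape[0], len(union)))
    a[:, [pos[v] for v in vocab_a]] = beta_a
    b[:, [pos[v] for v in vocab_b]] = beta_b
    return a, b


def topic_cosine_matrix(
    beta_a: np.ndarray,
    vocab_a: list[str],
    beta_b: np.ndarray,
    vocab_b: list[str],
    align: str = "union",
) -> np.ndarray:
    """Pairwise cosine similarity between two sets of topic-term rows.

    Vocabularies are aligned on the union of genus names; a genus absent
    from one model contributes probability 0 there (no renormalization).
    ``align='intersection'`` restricts to shared genera instead.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    if beta_a.shape[1] != len(vocab_a) or beta_b.shape[1] != len(vocab_b):
        raise ValueError("beta column counts must match vocab lengths")
    if align == "union":
        a, b = _align_union(beta_a, list(vocab_a), beta_b, list(vocab_b))
    elif align == "intersection":
        shared = [v for v in vocab_a if v in set(vocab_b)]
        ia = [list(vocab_a).index(v) for v in shared]
        ib = [list(vocab_b).index(v) for v in shared]
        a, b = beta_a[:, ia], beta_b[:, ib]
    else:
        raise ValueError(f"unknown align mode {align!r}")
    if not set(vocab_a) & set(vocab_b):
        warnings.warn("vocabularies share no genus names; all cosines are 0", stacklevel=2)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    na = np.where(na > 0, na, 1.0)
    nb = np.where(nb > 0, nb, 1.0)
    cos = (a / na[:, None]) @ (b / nb[:, None]).T
    return np.clip(cos, 0.0, 1.0)


def match_topics(
    cosine: np.ndarray,
    threshold: float = 0.80,
    topics_a: list[str] | None = None,
    topics_b: list[str] | None = None,
) -> list[TopicMatch]:
    """All topic pairs at or above the cosine threshold, descending.

    Matching is many-to-many: several topics from one cohort may match a
    single topic in the other.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    cosine = np.asarray(cosine, dtype=float)
    Ka, Kb = cosine.shape
    topics_a = topics_a or [f"a:topic_{i + 1}" for i in range(Ka)]
    topics_b = topics_b or [f"b:topic_{j + 1}" for j in range(Kb)]
    matches = [
        TopicMatch(topics_a[i], topics_b[j], float(cosine[i, j]))
        for i in range(Ka)
        for j in range(Kb)
        if cosine[i, j] >= threshold
    ]
    matches.sort(key=lambda m: (-m.cosine, m.topic_a, m.topic_b))
    return matches


def top_terms(
    model: LdaModel,
    topic: int | str,
    rule: str = "cumulative",
    cutoff: float = 0.95,
    n: int | None = None,
) -> list[tuple[str, float]]:
    """Ranked (genus, probability) list for one topic, truncated by rule.

    Rules: ``cumulative`` keeps the smallest prefix reaching ``cutoff`` total
    mass; ``floor`` keeps genera with probability >= ``cutoff``; ``top-n``
    keeps the ``n`` most probable.  Ties break alphabetically.
    """
    if isinstance(topic, str):
        try:
            k = model.topic_ids.index(topic)
        except ValueError:
            raise ValueError(f"unknown topic {topic!r}") from None
    else:
        k = int(topic)
        if not 0 <= k < model.K:
            raise ValueError(f"topic index {k} out of range")
    row = model.beta[k]
    order = sorted(range(len(row)), key=lambda v: (-row[v], model.vocab[v]))
    ranked = [(model.vocab[v], float(row[v])) for v in order]
    if rule == "cumulative":
        out, total = [], 0.0
        for g, p in ranked:
            out.append((g, p))
            total += p
            if total >= cutoff:
                break
        return out
    if rule == "floor":
        return [(g, p) for g, p in ranked if p >= cutoff]
    if rule == "top-n":
        if n is None:
            raise ValueError("top-n rule requires n")
        return ranked[: min(n, len(ranked))]
    raise ValueError(f"unknown rule {rule!r}")
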