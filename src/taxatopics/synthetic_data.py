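"""Dirichlet-multinomial cohort simulator with known community structure.

Samples are drawn from the same generative family the model fits: each
sample's topic proportions come from a group-specific Dirichlet, library
sizes are log-normal, and counts are multinomial over the mixed topic-term
distribution.  Group effects live in the Dirichlet concentrations so that
parameter recovery is a fair test of the inference code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CountTable
from .lda import LdaModel
from .topic_pipeline import topic_cosine_matrix

__all__ = [
    "SyntheticTruth",
    "PairedCohorts",
    "RecoveryReport",
    "generate_topics",
    "generate_cohort",
    "generate_paired_cohorts",
    "evaluate_recovery",
]


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated cohort."""

    beta_true: np.ndarray                 # K x V topic-term probabilities
    theta_true: np.ndarray                # D x K per-sample topic proportions
    group: list[str]
    alpha_by_group: dict[str, np.ndarray]
    seed: int
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.beta_true.sum(axis=1), 1.0):
            raise ValueError("beta_true rows must sum to 1")
        if not np.allclose(self.theta_true.sum(axis=1), 1.0):
            raise ValueError("theta_true rows must sum to 1")
        for g, a in self.alpha_by_group.items():
            if np.any(np.asarray(a) <= 0):
                raise ValueError(f"non-positive Dirichlet concentration for group {g!r}")


@dataclass
class PairedCohorts:
    """An exploratory/validation cohort pair with shared (jittered) topics."""

    table_a: CountTable
    truth_a: SyntheticTruth
    table_b: CountTable
    truth_b: SyntheticTruth
    true_cosines: np.ndarray  # K_a x K_b, computed on the true beta matrices


@dataclass
class RecoveryReport:
    """Greedy fitted-to-true topic matching diagnostics."""

    pairs: list[tuple[int, int, float]]   # (fitted index, true index, cosine)
    matched_cosines: np.ndarray
    fraction_matched: float
    mean_cosine: float
    gamma_theta_corr: float
    k_fitted: int
    k_true: int


def _feature_ids(V: int) -> list[str]:
    return [f"g{v:03d}" for v in range(V)]


def generate_topics(
    K: int,
    V: int,
    dominant_per_topic: int,
    dominance: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """Block topics: each topic puts ``dominance`` total mass uniformly on
    its own randomly placed block of genera and the rest uniformly elsewhere.

    Blocks are disjoint across topics, so the pairwise topic cosine is
    bounded by a closed-form function of the dominance.
    """
    if not 0 < dominance <= 1:
        raise ValueError("dominance must be in (0, 1]")
    b = int(dominant_per_topic)
    if b < 1 or K * b > V:
        raise ValueError(
            f"cannot place {K} disjoint blocks of {b} genera in a vocabulary of {V}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(V, size=K * b, replace=False).reshape(K, b)
    beta = np.zeros((K, V))
    for k in range(K):
        if dominance < 1.0 and V > b:
            beta[k, :] = (1.0 - dominance) / (V - b)
        beta[k, chosen[k]] = dominance / b
    return beta


def generate_cohort(
    beta_true: np.ndarray,
    alpha_by_group: dict[str, np.ndarray],
    group_sizes: dict[str, int],
    depth_log_mean: float = np.log(2e4),
    depth_log_sd: float = 0.7,
    seed: int = 0,
    feature_ids: list[str] | None = None,
    sample_prefix: str = "s",
) -> tuple[CountTable, SyntheticTruth]:
    """Simulate one cohort from the LDA generative process.

    Per sample: theta ~ Dirichlet(alpha of its group), library size ~
    log-normal (rounded, floor 100), counts ~ Multinomial(library,
    theta @ beta_true).
    """
    beta_true = np.asarray(beta_true, dtype=float)
    K, V = beta_true.shape
    alpha_by_group = {g: np.asarray(a, dtype=float) for g, a in alpha_by_group.items()}
    for g, a in alpha_by_group.items():
        if a.shape != (K,):
            raise ValueError(f"alpha for group {g!r} must have length K={K}")
        if np.any(a <= 0):
            raise ValueError(f"non-positive concentration for group {g!r}")
    if set(group_sizes) != set(alpha_by_group):
        raise ValueError("group_sizes and alpha_by_group must share the same groups")
    rng = np.random.default_rng(seed)
    groups: list[str] = []
    thetas: list[np.ndarray] = []
    counts_rows: list[np.ndarray] = []
    for g in sorted(group_sizes):
        for _ in range(group_sizes[g]):
            theta = rng.dirichlet(alpha_by_group[g])
            depth = max(100, int(round(rng.lognormal(depth_log_mean, depth_log_sd))))
            probs = theta @ beta_true
            counts_rows.append(rng.multinomial(depth, probs / probs.sum()).astype(float))
            thetas.append(theta)
            groups.append(g)
    D = len(groups)
    fids = feature_ids or _feature_ids(V)
    sids = [f"{sample_prefix}{i + 1:03d}" for i in range(D)]
    table = CountTable(np.vstack(counts_rows), sids, fids, groups)
    truth = SyntheticTruth(
        beta_true=beta_true,
        theta_true=np.vstack(thetas),
        group=groups,
        alpha_by_group=alpha_by_group,
        seed=seed,
        feature_ids=list(fids),
        sample_ids=sids,
    )
    return table, truth


def _jitter_topics(beta: np.ndarray, epsilon: float, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet-jittered copy: row k ~ Dirichlet(beta_k / epsilon)."""
    if epsilon == 0:
        return beta.copy()
    out = np.empty_like(beta)
    floor = 1e-8  # Dirichlet needs strictly positive concentrations
    for k in range(beta.shape[0]):
        conc = np.maximum(beta[k], floor) / epsilon
        out[k] = rng.dirichlet(conc)
    return out


def generate_paired_cohorts(
    beta_true: np.ndarray,
    alpha_by_group: dict[str, np.ndarray],
    group_sizes_a: dict[str, int],
    group_sizes_b: dict[str, int] | None = None,
    epsilon: float = 0.0,
    vocab_overlap: float = 1.0,
    independent_b: bool = False,
    depth_log_mean: float = np.log(2e4),
    depth_log_sd: float = 0.7,
    seed: int = 0,
    dominant_per_topic: int = 5,
    dominance: float = 0.9,
) -> PairedCohorts:
    """Two cohorts sharing (perturbed) community structure.

    Cohort B's topics are Dirichlet-jittered copies of cohort A's at scale
    ``epsilon`` (0 = identical), or a fully independent redraw when
    ``independent_b`` is set.  A fraction ``1 - vocab_overlap`` of genus
    names is made private to each cohort by renaming.  The true
    cross-cohort topic cosine matrix (on the renamed vocabularies) is
    recorded.
    """
    if not 0 < vocab_overlap <= 1:
        raise ValueError("vocab_overlap must be in (0, 1]")
    beta_true = np.asarray(beta_true, dtype=float)
    K, V = beta_true.shape
    root = np.random.SeedSequence(seed)
    s_jit, s_a, s_b, s_vocab, s_indep = root.spawn(5)
    rng_jit = np.random.default_rng(s_jit)
    if independent_b:
        beta_b = generate_topics(
            K, V, dominant_per_topic, dominance,
            seed=int(np.random.default_rng(s_indep).integers(2**31)),
        )
    else:
        beta_b = _jitter_topics(beta_true, epsilon, rng_jit)
    group_sizes_b = group_sizes_b or dict(group_sizes_a)

    base = _feature_ids(V)
    rng_vocab = np.random.default_rng(s_vocab)
    n_priv = int(round((1.0 - vocab_overlap) * V))
    vocab_a, vocab_b = list(base), list(base)
    if n_priv:
        priv_a = rng_vocab.choice(V, size=n_priv, replace=False)
        priv_b = rng_vocab.choice(V, size=n_priv, replace=False)
        for v in priv_a:
            vocab_a[v] = f"{base[v]}__a"
        for v in priv_b:
            vocab_b[v] = f"{base[v]}__b"

    table_a, truth_a = generate_cohort(
        beta_true, alpha_by_group, group_sizes_a, depth_log_mean, depth_log_sd,
        seed=int(np.random.default_rng(s_a).integers(2**31)),
        feature_ids=vocab_a, sample_prefix="a",
    )
    table_b, truth_b = generate_cohort(
        beta_b, alpha_by_group, group_sizes_b, depth_log_mean, depth_log_sd,
        seed=int(np.random.default_rng(s_b).integers(2**31)),
        feature_ids=vocab_b, sample_prefix="b",
    )
    true_cos = topic_cosine_matrix(beta_true, vocab_a, beta_b, vocab_b)
    return PairedCohorts(table_a, truth_a, table_b, truth_b, true_cos)


def evaluate_recovery(
    model: LdaModel, truth: SyntheticTruth, threshold: float = 0.80
) -> RecoveryReport:
    """Greedy one-to-one matching of fitted topics to true topics by cosine.

    Reports the matched cosines, the fraction of true topics matched at or
    above the threshold, and the mean Pearson correlation between fitted
    topic proportions and true theta over matched topics.  A K mismatch is
    reported, not an error.
    """
    vocab_t = truth.feature_ids or [f"g{v:03d}" for v in range(truth.beta_true.shape[1])]
    cos = topic_cosine_matrix(model.beta, model.vocab, truth.beta_true, vocab_t)
    kf, kt = cos.shape
    work = cos.copy()
    pairs: list[tuple[int, int, float]] = []
    for _ in range(min(kf, kt)):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        pairs.append((int(i), int(j), float(cos[i, j])))
        work[i, :] = -1.0
        work[:, j] = -1.0
    matched = np.array([c for _, _, c in pairs])
    corrs = []
    same_samples = model.gamma_norm.shape[0] == truth.theta_true.shape[0]
    for i, j, _ in pairs:
        if not same_samples:
            break
        a = model.gamma_norm[:, i]
        b = truth.theta_true[:, j]
        if a.std() > 0 and b.std() > 0:
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
    return RecoveryReport(
        pairs=sorted(pairs, key=lambda t: t[1]),
        matched_cosines=matched,
        fraction_matched=float((matched >= threshold).mean()),
        mean_cosine=float(matched.mean()),
        gamma_theta_corr=float(np.mean(corrs)) if corrs else float("nan"),
        k_fitted=kf,
        k_true=kt,
    )
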