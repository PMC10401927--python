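import numpy as np
import pytest

from taxatopics import CountTable


@pytest.fixture
def tiny_table() -> CountTable:
    counts = np.array([[3.0, 0.0, 7.0], [1.0, 4.0, 5.0]])
    return CountTable(counts, ["s1", "s2"], ["Blautia", "Dorea", "Bacteroides"])


@pytest.fixture
def grouped_table() -> CountTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(8, 5)).astype(float) + 1.0
    return CountTable(
        counts,
        [f"s{i}" for i in range(8)],
        [f"g{j}" for j in range(5)],
        ["HC"] * 4 + ["RRMS"] * 4,
    )


@pytest.fixture
def random_table() -> CountTable:
    """A moderately sized seeded table drawn from a Dirichlet-multinomial."""
    rng = np.random.default_rng(7)
    base = rng.dirichlet(np.full(30, 0.8))
    counts = np.vstack(
        [rng.multinomial(int(rng.lognormal(8.0, 0.4)), base) for _ in range(20)]
    ).astype(float)
    return CountTable(
        counts, [f"s{i}" for i in range(20)], [f"g{j}" for j in range(30)]
    )
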