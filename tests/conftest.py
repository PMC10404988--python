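import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASES = np.array(list("ACGT"))


def random_seq(rng, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def mutate(rng, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = [b for b in "ACGT" if b != s[pos]][rng.integers(0, 3)]
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def v9_refs():
    """Three small V9 references with rank-delimited taxonomy."""
    from v9var.refdb import V9Reference

    rng = np.random.default_rng(99)
    seqs = [random_seq(rng, 110) for _ in range(3)]
    return [
        V9Reference(f"ref_{i}", ["Eukaryota", f"Phylum{i}", f"Species{i}"], s, (0, 110))
        for i, s in enumerate(seqs)
    ]
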