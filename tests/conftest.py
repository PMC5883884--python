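import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsalign3.genome import Genome
from bsalign3.index import build_genome_index

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_random_genome(length: int, seed: int, name: str = "chr1") -> Genome:
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return Genome([name], {name: seq})


def levenshtein_full(a, b) -> int:
    """Unbanded Levenshtein DP; the independent oracle for banded distances."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


@pytest.fixture(scope="session")
def tiny_genome() -> Genome:
    return Genome(["chr1"], {"chr1": "ACGT"})


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return make_random_genome(10_000, seed=42)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_genome_index(small_genome, seed_len=20)
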