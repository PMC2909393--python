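import numpy as np
import pytest

from slpotu.pwdist import AlignScoring
from slpotu.seqio import UniqueSeq, dereplicate
from slpotu.simdata import ErrorModel, simulate_reads, simulate_templates


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_positions(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute a different base at each given position."""
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


@pytest.fixture(scope="session")
def scoring() -> AlignScoring:
    return AlignScoring()


@pytest.fixture(scope="session")
def five_templates():
    """Five 60-nt templates, all pairwise more than 6% apart."""
    return simulate_templates(5, length=60, min_pairwise_dist=0.06, seed=3)


@pytest.fixture(scope="session")
def noisy_pool(five_templates):
    """2000 reads with the default error model (heavy tail on), seed 5."""
    reads, truth = simulate_reads(
        five_templates, n=2000, error_model=ErrorModel(seed=5)
    )
    return reads, truth


@pytest.fixture(scope="session")
def noisy_uniques(noisy_pool):
    reads, _ = noisy_pool
    return dereplicate(reads)


@pytest.fixture()
def make_unique():
    def _make(seq: str, count: int, prefix: str = "r") -> UniqueSeq:
        return UniqueSeq(
            sequence=seq, count=count,
            member_ids=[f"{prefix}{i}" for i in range(count)],
        )

    return _make
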