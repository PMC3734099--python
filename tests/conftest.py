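import random

import pytest

from cnvscan import CNVCall, CNVType, Cohort
from cnvscan import simulate as sm


@pytest.fixture(scope="session")
def default_cohort() -> sm.SimulatedCohort:
    """The desk-scale synthetic cohort (150 cases / 150 controls, 5 planted
    regions) used by the recovery tests."""
    return sm.simulate_cohort(sm.SimulationConfig(seed=1))


@pytest.fixture()
def call_factory():
    def make(chrom="1", start=100, end=200, cnv_type=CNVType.LOSS,
             sample_id="s1", cohort=Cohort.CASE, **kw):
        return CNVCall(chrom, start, end, cnv_type, sample_id, cohort, **kw)

    return make


def random_calls(
    n: int,
    seed: int,
    *,
    n_samples: int = 60,
    chroms=("1", "2"),
    span: int = 2_000_000,
    max_len: int = 60_000,
) -> list[CNVCall]:
    """Dense random call sets for oracle-equivalence checks."""
    rng = random.Random(seed)
    calls = []
    for _ in range(n):
        start = rng.randint(1, span)
        length = rng.randint(500, max_len)
        calls.append(
            CNVCall(
                chrom=rng.choice(chroms),
                start=start,
                end=start + length,
                cnv_type=rng.choice((CNVType.LOSS, CNVType.GAIN)),
                sample_id=f"s{rng.randint(1, n_samples):03d}",
                cohort=Cohort.CASE,
            )
        )
    return calls
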