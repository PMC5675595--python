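import numpy as np
import pytest

from retscan.compartment import GeneSetPartition
from retscan.motif import IUPACMotif
from retscan.simulate import generate_transcripts

SRSF1 = IUPACMotif("SRSF1_1", "SRSF1", "KGRWGSM")


@pytest.fixture(scope="session")
def srsf1():
    return SRSF1


@pytest.fixture(scope="session")
def planted_dataset(srsf1):
    """70 positive 3'UTRs with 4 planted SRSF1 sites each, 200 clean negatives."""
    positives = [f"T{i + 1:04d}" for i in range(70)]
    records, truth = generate_transcripts(
        270, srsf1, positive_ids=positives, sites_per_positive=4,
        background_rate=0.0, seed=1,
    )
    by_id = {r.transcript_id: r for r in records}
    partition = GeneSetPartition(
        positives, [r.transcript_id for r in records if r.transcript_id not in positives]
    )
    return by_id, partition, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
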