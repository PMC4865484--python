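import numpy as np
import pytest

import denovopost as dp


@pytest.fixture(scope="session")
def skewed_table():
    return dp.skewed_codon_table()


@pytest.fixture(scope="session")
def host_set():
    """500 coding transcripts with planted ORFs (20% antisense)."""
    records, truth = dp.generate_host_transcripts(500, seed=3)
    return records, truth


@pytest.fixture(scope="session")
def decoy_set():
    """200 non-coding decoys from the host-like order-1 chain."""
    records, truth = dp.generate_contaminants(
        200, model=dp.HOST_CHAIN, len_range=(400, 1300), seed=4, id_prefix="decoy"
    )
    return records, truth


@pytest.fixture(scope="session")
def cds_run(host_set, decoy_set):
    """Iterative CDS prediction over coding + decoy transcripts."""
    records = host_set[0] + decoy_set[0]
    return dp.iterative_cds_prediction(records, n_iter=4)


def reading_frame(start: int, end: int, strand: str, length: int) -> int:
    """Frame of an interval on its reading strand."""
    return start % 3 if strand == "+" else (length - end) % 3


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
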