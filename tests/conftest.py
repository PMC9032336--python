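import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snofrag.ingest import NcRNARecord, RnaClass

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_record(rng, rec_id, length):
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
    return NcRNARecord(id=rec_id, name=rec_id, rna_class=RnaClass.OTHER, sequence=seq)


@pytest.fixture
def toy_records(rng):
    """Three random precursors, 120/150/200 nt."""
    return [
        random_record(rng, f"SNO{i + 1}", n)
        for i, n in enumerate((120, 150, 200))
    ]
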