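import numpy as np
import pytest

from panedit.seqio import CdsRecord, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_cds(rng, n_bases: int, p=(0.25, 0.25, 0.25, 0.25), id="r") -> CdsRecord:
    seq = "".join(rng.choice(list("ACGU"), size=n_bases, p=list(p)))
    return CdsRecord(id=id, seq=seq)


def random_protein(rng, n: int, id="p") -> ProteinRecord:
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return ProteinRecord(id=id, seq=seq)
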