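import numpy as np
import pytest

from coevkit.io import MultipleAlignment, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_alignment():
    return MultipleAlignment(
        ids=["ref", "s1", "s2", "s3"],
        sequences=["ACDEF", "ACDEF", "ACD-F", "AGDEF"],
    )


@pytest.fixture
def make_records():
    def _make(seqs: dict[str, str], organism_fmt: str = "Genus species{i}"):
        out = []
        for i, (rid, seq) in enumerate(seqs.items()):
            out.append(SequenceRecord(id=rid, organism=organism_fmt.format(i=i), sequence=seq))
        return out

    return _make
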