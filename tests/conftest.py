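import numpy as np
import pytest

from famspace import Alignment, attach_labels


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Six sequences from two obvious families: the first three columns
    discriminate, the last four are conserved."""
    seqs = {
        "a1": "AAAGKTW",
        "a2": "AACGKTW",
        "a3": "AAAGKTW",
        "b1": "WWWGKTW",
        "b2": "WWCGKTW",
        "b3": "WWWGKTW",
    }
    aln = Alignment(ids=tuple(seqs), seqs=tuple(seqs.values()))
    return attach_labels(
        aln, {i: ("famA" if i.startswith("a") else "famB") for i in seqs}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
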