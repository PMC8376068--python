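import pytest

from ribocure.io_formats import Read
from ribocure.synthetic import random_reference


@pytest.fixture(scope="session")
def rrna_refs():
    return [
        random_reference("rrna18S", 1800, seed=11, role="rrna"),
        random_reference("rrna28S", 3000, seed=12, role="rrna"),
    ]


@pytest.fixture(scope="session")
def virus_ref():
    return random_reference("virusX", 4000, seed=13, role="virus")


def make_read(read_id: str, bases: str, phred: int = 30) -> Read:
    return Read(read_id=read_id, bases=bases, quals=[phred] * len(bases))


def original_id(cured_id: str) -> str:
    """Strip the per-round |cut:...| suffixes from a cured read id."""
    return cured_id.split("|cut:")[0]


def residual_rrna_bases(cured_read: Read, original_read: Read, truth_rec) -> int:
    """Bases of a cured read that the truth record labels as rRNA-derived.

    Relies on the substring-conservation invariant: a cured read's bases are
    an exact contiguous substring of the source read.
    """
    off = original_read.bases.find(cured_read.bases)
    assert off != -1, "cured read is not a substring of its source"
    lo, hi = off, off + len(cured_read.bases)
    total = 0
    for s, e in truth_rec.rrna_read_intervals():
        total += max(0, min(e, hi) - max(s, lo))
    return total
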