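import numpy as np
import pytest

from tdrprofiler import classify as C
from tdrprofiler.index import SequenceIndex
from tdrprofiler.profiles import composition_profile
from tdrprofiler.simulate import simulate_small_rna_reads
from tdrprofiler.toyref import toy_reference_set


@pytest.fixture(scope="session")
def refset():
    return toy_reference_set()


@pytest.fixture(scope="session")
def index0(refset):
    return SequenceIndex(refset, 0)


@pytest.fixture(scope="session")
def small_sperm_library(refset):
    """20k-read wt_sperm library shared by recovery-style unit tests."""
    profile = composition_profile("wt_sperm", read_count=20_000, seed=11)
    return simulate_small_rna_reads(profile, refset)


@pytest.fixture(scope="session")
def small_sperm_assignments(small_sperm_library, refset, index0):
    reads = [C.Read(r.read_id, r.sequence) for r in small_sperm_library.reads]
    return C.classify_reads(reads, index0, refset)


def hamming_hits(read, ref, max_mm):
    """Brute-force oracle: all (1-based start, mm) windows of ref matching read."""
    out = []
    for i in range(len(ref) - len(read) + 1):
        mm = sum(a != b for a, b in zip(ref[i : i + len(read)], read))
        if mm <= max_mm:
            out.append((i + 1, mm))
    return out


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
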