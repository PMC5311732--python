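import numpy as np
import pytest

from tesrna import pipelines as pl
from tesrna import synthetic_data as sd


def brute_force_hits(seq, references):
    """Quadratic both-strand window scan: the independent mapping oracle."""
    from tesrna.mapping import Hit, revcomp

    seq = seq.upper()
    rc = revcomp(seq)
    L = len(seq)
    hits = set()
    for name, ref in references.items():
        ref = ref.upper()
        for i in range(len(ref) - L + 1):
            window = ref[i : i + L]
            if window == seq:
                hits.add(Hit(name, i, "sense"))
            if window == rc:
                hits.add(Hit(name, i, "antisense"))
    return sorted(hits)


@pytest.fixture(scope="session")
def two_family_specs():
    return [
        sd.FamilySpec("famA", 12, ltr_length=400, int_length=1200),
        sd.FamilySpec("famB", 12, ltr_length=400, int_length=1200),
    ]


@pytest.fixture(scope="session")
def small_study(two_family_specs):
    """A small simulated study shared by read-only tests."""
    return pl.simulate_study(two_family_specs, background_length=120_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
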