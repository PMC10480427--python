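import numpy as np
import pytest

from epigram import GAConfig, LabeledSequence, make_fixture_suite
from epigram.types import ALPHABET


@pytest.fixture(scope="session")
def fixture_suite():
    """The four named synthetic datasets (fixed seeds)."""
    return make_fixture_suite()


@pytest.fixture(scope="session")
def fast_ga_cfg():
    """Small GA settings so unit tests stay quick."""
    return GAConfig(ns=4, ni=3, mu=0.2, tr=0.7, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230905)


def random_peptides(rng, n, lo=5, hi=30, label=None):
    """Random standard-alphabet peptides, optionally all with one label."""
    alpha = np.array(list(ALPHABET))
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(alpha, size=length))
        lab = int(rng.integers(0, 2)) if label is None else label
        out.append(LabeledSequence(id=f"r{i}", residues=residues, label=lab))
    return out


@pytest.fixture
def small_labeled_set(rng):
    """Twenty short random peptides, both classes present."""
    seqs = random_peptides(rng, 20, lo=6, hi=15)
    # force both classes
    seqs[0] = LabeledSequence(id=seqs[0].id, residues=seqs[0].residues, label=0)
    seqs[1] = LabeledSequence(id=seqs[1].id, residues=seqs[1].residues, label=1)
    return seqs
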