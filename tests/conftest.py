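import numpy as np
import pytest

from methylstoich import PeptideObservation, ProteinRecord
from methylstoich.psm import ModificationSite, ModKind


@pytest.fixture
def single_k_protein():
    """A minimal protein with one lysine at position 2."""
    return ProteinRecord("prot1", "MKAAAR")


@pytest.fixture
def repeat_protein():
    """Two exact copies of the unit AKGG; K at positions 2 and 6."""
    return ProteinRecord("rep1", "AKGGAKGG")


def make_obs(seq, abundance, mono_at=(), di_at=(), tri_at=(), confident=True):
    """Observation factory: methyl positions given as within-peptide 1-based."""
    mods = (
        [ModificationSite(p, seq[p - 1], ModKind.MONOMETHYL) for p in mono_at]
        + [ModificationSite(p, seq[p - 1], ModKind.DIMETHYL) for p in di_at]
        + [ModificationSite(p, seq[p - 1], ModKind.TRIMETHYL) for p in tri_at]
    )
    return PeptideObservation(
        peptide_seq=seq,
        modifications=tuple(mods),
        abundance=abundance,
        localization_confident=confident,
    )


@pytest.fixture
def obs_factory():
    return make_obs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
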