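import numpy as np
import pytest

from polyrep.germline import HEAVY, KAPPA, load_default_germline
from polyrep.simulate import simulate_library, sjs_preset


@pytest.fixture(scope="session")
def reference():
    return load_default_germline()


@pytest.fixture(scope="session")
def aged_sjs_library(reference):
    """Aged autoimmune-prone library with two expanded lineages (seeded)."""
    cfg = sjs_preset(66, library_size=120, seed=7,
                     n_expanded_lineages=2, lineage_sizes=(2, 3),
                     extra_members_per_lineage=(0, 1))
    return simulate_library(cfg, reference)


@pytest.fixture(scope="session")
def shm_free_library(reference):
    """SHM-free library: annotation must recover the construction exactly."""
    cfg = sjs_preset(28, library_size=80, seed=13, shm_rate_per_nt=0.0,
                     ns_fraction=0.0)
    return simulate_library(cfg, reference)


def chain_sequences(library):
    """(id, chain) -> sequence mapping for annotate_library."""
    seqs = {}
    for r in library.records:
        if r.heavy_seq:
            seqs[(r.id, HEAVY)] = r.heavy_seq
        if r.kappa_seq:
            seqs[(r.id, KAPPA)] = r.kappa_seq
    return seqs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
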