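import numpy as np
import pytest

import protevol as pe
from protevol.fixtures import (
    FixtureSpec,
    compact_protein_fixture,
    evolve_sequence,
    make_potential,
)
from protevol.mutation import codon_mutation_model, gc_params


@pytest.fixture(scope="session")
def pot():
    return pe.shipped_potential()


@pytest.fixture(scope="session")
def rank1_pot():
    return make_potential(FixtureSpec(potential_kind="rank1"))


@pytest.fixture(scope="session")
def wag():
    return pe.load_shipped_empirical("wag")


@pytest.fixture(scope="session")
def sparams():
    return pe.StabilityParams()


@pytest.fixture(scope="session")
def protein50(pot, sparams):
    """Compact 50-residue toy protein with density-matched decoys and a
    wild-type sequence equilibrated under the stability landscape."""
    spec = FixtureSpec(seed=3, L=50, n_decoys=15, compactness=1.0)
    chain, cmap, decoys = compact_protein_fixture(spec)
    stats = pe.decoy_contact_statistics(decoys, spec.L)
    _, background = codon_mutation_model(gc_params(0.5))
    seq = evolve_sequence(cmap, pot, stats, sparams, background, lam=20.0, seed=7)
    return {"chain": chain, "cmap": cmap, "stats": stats, "seq": seq,
            "background": background}


@pytest.fixture(scope="session")
def toy_decoys():
    """Three hand-built 6-residue decoy maps (one empty)."""
    d1 = np.zeros((6, 6), int); d1[0, 3] = d1[3, 0] = 1
    d2 = np.zeros((6, 6), int)
    d2[1, 5] = d2[5, 1] = 1
    d2[0, 4] = d2[4, 0] = 1
    d3 = np.zeros((6, 6), int)
    return [pe.ContactMap(m) for m in (d1, d2, d3)]
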