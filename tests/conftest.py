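import numpy as np
import pytest

from polyqcg import ForceField, ParameterSet, build_beta_sheet, build_chain


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def chain6(params):
    """A six-residue chain (topology, state); treat as read-only."""
    return build_chain(6, params)


@pytest.fixture(scope="session")
def sheet_2x8(params):
    """Two-strand antiparallel Q8 sheet in ideal registry; read-only."""
    return build_beta_sheet(2, 8, "antiparallel", params)


def numerical_forces(ff: ForceField, state, h=1.0e-6, hb_enabled=True,
                     beads=None):
    """Central-difference gradient oracle for force validation."""
    top = ff.topology
    beads = np.flatnonzero(top.is_massive) if beads is None else beads
    out = np.zeros((len(beads), 3))
    for k, i in enumerate(beads):
        for d in range(3):
            sp = state.copy()
            sp.positions[i, d] += h
            sm = state.copy()
            sm.positions[i, d] -= h
            ep = ff.compute(sp, hb_enabled).total
            em = ff.compute(sm, hb_enabled).total
            out[k, d] = -(ep - em) / (2 * h)
    return out
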