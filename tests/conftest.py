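import numpy as np
import pytest

from incdock import EngineConfig, ProtocolConfig, make_chain_ligand, make_planted_complex

# small mol2 documents used across parser tests -----------------------------

ETHANE_MOL2 = """\
@<TRIPOS>MOLECULE
ethane
8 7 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1  0.0000  0.0000  0.0000 C.3 1 ETH -0.0600
2 C2  1.5400  0.0000  0.0000 C.3 1 ETH -0.0600
3 H1 -0.3600  0.5100  0.8900 H   1 ETH  0.0200
4 H2 -0.3600  0.5100 -0.8900 H   1 ETH  0.0200
5 H3 -0.3600 -1.0200  0.0000 H   1 ETH  0.0200
6 H4  1.9000 -0.5100  0.8900 H   1 ETH  0.0200
7 H5  1.9000 -0.5100 -0.8900 H   1 ETH  0.0200
8 H6  1.9000  1.0200  0.0000 H   1 ETH  0.0200
@<TRIPOS>BOND
1 1 2 1
2 1 3 1
3 1 4 1
4 1 5 1
5 2 6 1
6 2 7 1
7 2 8 1
"""

BENZENE_MOL2 = """\
@<TRIPOS>MOLECULE
benzene
6 6 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
1 C1  1.3900  0.0000 0.0000 C.ar 1 BNZ
2 C2  0.6950  1.2037 0.0000 C.ar 1 BNZ
3 C3 -0.6950  1.2037 0.0000 C.ar 1 BNZ
4 C4 -1.3900  0.0000 0.0000 C.ar 1 BNZ
5 C5 -0.6950 -1.2037 0.0000 C.ar 1 BNZ
6 C6  0.6950 -1.2037 0.0000 C.ar 1 BNZ
@<TRIPOS>BOND
1 1 2 ar
2 2 3 ar
3 3 4 ar
4 4 5 ar
5 5 6 ar
6 6 1 ar
"""

# heavy-atom n-butane: only the central C-C bond is rotatable
BUTANE_MOL2 = """\
@<TRIPOS>MOLECULE
butane
4 3 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
1 C1 0.0000 0.0000 0.0000 C.3 1 BUT -0.05
2 C2 1.5400 0.0000 0.0000 C.3 1 BUT  0.05
3 C3 2.0540 1.4520 0.0000 C.3 1 BUT  0.05
4 C4 3.5940 1.4520 0.0000 C.3 1 BUT -0.05
@<TRIPOS>BOND
1 1 2 1
2 2 3 1
3 3 4 1
"""

# PDB snippet with A/B alternate locations for one atom
ALTLOC_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AGLY A   1       1.460   0.000   0.000  0.40  0.00           C
ATOM      3  CA BGLY A   1       1.470   0.100   0.000  0.60  0.00           C
ATOM      4  C   GLY A   1       2.200   1.200   0.000  1.00  0.00           C
ATOM      5  O   GLY A   1       2.000   2.300   0.500  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def chain9():
    return make_chain_ligand(9)


@pytest.fixture(scope="session")
def chain14():
    return make_chain_ligand(14)


@pytest.fixture(scope="session")
def planted9():
    """9-torsion chain in a harmonic funnel; planted pose is the global minimum."""
    return make_planted_complex(n_torsions=9, seed=3)


@pytest.fixture(scope="session")
def planted5():
    return make_planted_complex(n_torsions=5, seed=7)


def fast_engine(**overrides) -> EngineConfig:
    """A low-budget engine configuration for structural (non-search) tests."""
    base = dict(ga_num_evals=600, ga_run=3, population_size=40, local_search_steps=2, seed=0)
    base.update(overrides)
    return EngineConfig(**base)


def fast_protocol(**overrides) -> ProtocolConfig:
    base = dict(step_num_evals=200, seed=0)
    base.update(overrides)
    return ProtocolConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
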