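"""Shared fixtures: hand-written PDB texts and small synthetic systems."""

import numpy as np
import pytest

import allodyn as ad

TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       0.500   1.300   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  CB  SER A   3       8.100   1.300   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA B   7      20.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA B   8      23.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture(scope="session")
def globule20():
    return ad.make_structure(ad.SynthSpec(20, "globule", seed=7))


@pytest.fixture(scope="session")
def globule30():
    return ad.make_structure(ad.SynthSpec(30, "globule", seed=9))


@pytest.fixture(scope="session")
def dumbbell40():
    return ad.make_structure(
        ad.SynthSpec(40, "dumbbell", linker_range=(18, 22), seed=3)
    )


@pytest.fixture(scope="session")
def complex24():
    return ad.make_structure(ad.SynthSpec(24, "two-chain-complex", seed=5))


@pytest.fixture(scope="session")
def anm20(globule20):
    return ad.ANM(globule20).fit()


@pytest.fixture(scope="session")
def anm30(globule30):
    return ad.ANM(globule30).fit()


def line_structure(xs, chain="A"):
    """Structure with Cα at given x positions (no Cβ), single chain."""
    xs = np.asarray(xs, dtype=float)
    coords = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    residues = [ad.ResidueKey(chain, i + 1, "ALA") for i in range(len(xs))]
    return ad.CoarseStructure(residues, coords)


def point_structure(coords, chains=None):
    """Structure from explicit Cα coordinates (no Cβ)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    chains = chains or ["A"] * n
    counts: dict[str, int] = {}
    residues = []
    for c in chains:
        counts[c] = counts.get(c, 0) + 1
        residues.append(ad.ResidueKey(c, counts[c], "ALA"))
    return ad.CoarseStructure(residues, coords)
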