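"""Shared fixtures: hand-written PDB snippets and tiny synthetic systems."""

from __future__ import annotations

import numpy as np
import pytest

from tcrdyn.model_io import AtomRecord, Topology, Trajectory

TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ATOM      3  C   ALA A   1      12.759   7.093  -4.973  1.00 14.00           C
END
"""

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ENDMDL
MODEL        3
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ENDMDL
MODEL        4
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ENDMDL
MODEL        5
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 12.00           C
ENDMDL
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A 101      10.000  10.000  10.000  1.00 20.00           O
HETATM    2  O   HOH A 102      13.000  10.000  10.000  1.00 20.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.40 10.00           C
ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.60 10.00           C
ATOM      4  OG ASER A   1       3.000   0.000   0.000  0.50 10.00           O
ATOM      5  OG BSER A   1       4.000   0.000   0.000  0.50 10.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def multi_model_pdb(tmp_path):
    p = tmp_path / "multi.pdb"
    p.write_text(MULTI_MODEL_PDB)
    return p


@pytest.fixture
def water_only_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_ONLY_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_ca_chain(n_residues: int, chain_id: str = "A", spacing: float = 3.8,
                  res_name: str = "ALA", b_factor: float = 0.0) -> Trajectory:
    """Straightish (slightly zig-zagged, non-collinear) Cα-only chain."""
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element="C", res_name=res_name,
                   res_seq=i + 1, chain_id=chain_id, b_factor=b_factor)
        for i in range(n_residues)
    ]
    coords = np.zeros((1, n_residues, 3))
    coords[0, :, 0] = spacing * np.arange(n_residues)
    coords[0, :, 1] = 0.5 * (np.arange(n_residues) % 2)
    coords[0, :, 2] = 0.3 * (np.arange(n_residues) % 3)
    return Trajectory(Topology(atoms=atoms), coords)


@pytest.fixture
def ca_chain_276():
    return make_ca_chain(276)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
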