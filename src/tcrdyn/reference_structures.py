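"""Analyses bound to the reference crystal-structure accessions.

The three reference entries (two unliganded pMHC structures and one
two-conformation TCR-pMHC complex) are not redistributed with the package.
Place the deposited PDB files (lower-case names, e.g. ``1zhk.pdb``) in
``src/tcrdyn/data/structures/`` or in ``data/structures/`` under the
working directory and these helpers will pick them up; otherwise
:func:`find_structure` returns ``None`` and callers should report the
analysis as unavailable rather than fail.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .flexibility import mean_bfactor, pairwise_rmsd
from .model_io import Selection, Trajectory, read_structure
from .motion import docking_angle_difference

__all__ = [
    "find_structure",
    "peptide_ca_rmsd",
    "peptide_mean_bfactor",
    "tcr_docking_angle",
]

#: default residue span of the TCR variable domains used for docking geometry
VARIABLE_DOMAIN_RANGE = (1, 110)


def find_structure(accession: str) -> Optional[Path]:
    """Locate a reference PDB file by accession, or ``None`` if absent."""
    name = f"{accession.lower()}.pdb"
    candidates = [
        Path(str(resources.files("tcrdyn").joinpath(f"data/structures/{name}"))),
        Path("data/structures") / name,
    ]
    for c in candidates:
        if c.is_file():
            return c
    return None


def _matched_ca_indices(
    a: Trajectory, b: Trajectory, chain_a: str, chain_b: str, lo: int, hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """CA atom indices for residues in [lo, hi] present in BOTH chains.

    Crystal structures may differ in modelled residues, so correspondence is
    by author residue number rather than positional order.
    """
    def ca_map(traj: Trajectory, chain: str) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, atom in enumerate(traj.topology.atoms):
            if (
                atom.chain_id == chain
                and atom.name == "CA"
                and not atom.is_hetero
                and lo <= atom.res_seq <= hi
                and atom.res_seq not in out
            ):
                out[atom.res_seq] = i
        return out

    map_a, map_b = ca_map(a, chain_a), ca_map(b, chain_b)
    common = sorted(set(map_a) & set(map_b))
    return (
        np.array([map_a[r] for r in common], dtype=int),
        np.array([map_b[r] for r in common], dtype=int),
    )


def peptide_ca_rmsd(
    path_a: str | Path,
    path_b: str | Path,
    peptide_chain_a: str = "C",
    peptide_chain_b: str = "C",
    res_range: tuple[int, int] = (1, 13),
) -> tuple[float, int]:
    """Superposed Cα RMSD (Å) between the two structures' peptides.

    Returns ``(rmsd, n_atoms)``; the compared selection itself is superposed.
    """
    a = read_structure(path_a)
    b = read_structure(path_b)
    idx_a, idx_b = _matched_ca_indices(a, b, peptide_chain_a, peptide_chain_b, *res_range)
    value = pairwise_rmsd(a, b, idx_a, idx_b, superpose=True)
    return value, int(idx_a.size)


def peptide_mean_bfactor(
    path: str | Path, peptide_chain: str = "C"
) -> tuple[float, int]:
    """Mean heavy-atom B-factor (Å²) of the peptide chain; returns (mean, n)."""
    traj = read_structure(path)
    sel = Selection.make(chains=[peptide_chain])
    idx = sel.resolve(traj.topology)
    heavy = [i for i in idx if not traj.topology.atoms[int(i)].is_hydrogen]
    return mean_bfactor(traj, sel), len(heavy)


def tcr_docking_angle(
    path: str | Path,
    mhc_chain_a: str = "K",
    mhc_chain_b: str = "A",
    tcr_chains_a: tuple[str, str] = ("O", "P"),
    tcr_chains_b: tuple[str, str] = ("D", "E"),
    mhc_range: tuple[int, int] = (1, 180),
    variable_range: tuple[int, int] = VARIABLE_DOMAIN_RANGE,
) -> tuple[float, int]:
    """Rotation angle (degrees) between the two complex conformations' TCRs.

    The two complexes are superposed on their MHC heavy-chain Cα atoms
    (residues 1–180); the Kabsch rotation between the two TCR
    variable-domain Cα sets (α then β chain, matched by residue number)
    is reported.  Returns ``(angle, n_tcr_atoms)``.
    """
    traj = read_structure(path)
    mhc_a, mhc_b = _matched_ca_indices(traj, traj, mhc_chain_a, mhc_chain_b, *mhc_range)
    tcr_a_parts, tcr_b_parts = [], []
    for ca, cb in zip(tcr_chains_a, tcr_chains_b):
        ia, ib = _matched_ca_indices(traj, traj, ca, cb, *variable_range)
        tcr_a_parts.append(ia)
        tcr_b_parts.append(ib)
    tcr_a = np.concatenate(tcr_a_parts)
    tcr_b = np.concatenate(tcr_b_parts)
    angle = docking_angle_difference(traj, traj, mhc_a, tcr_a, mhc_b, tcr_b)
    return angle, int(tcr_a.size)
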