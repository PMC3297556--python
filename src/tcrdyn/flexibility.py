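"""Per-residue flexibility: RMSF profiles, B-factor summaries, pairwise RMSD."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import align_trajectory, average_structure, kabsch_superpose
from .model_io import Selection, Trajectory

__all__ = ["RMSFProfile", "rmsf", "mean_bfactor", "pairwise_rmsd"]

# 8*pi^2/3: isotropic conversion between mean-square displacement and B.
_B_FROM_MSD = 8.0 * np.pi**2 / 3.0


@dataclass
class RMSFProfile:
    """Ordered per-residue RMSF values (Å) with provenance."""

    entries: list[tuple[str, int, str, float]]  # (chain_id, res_seq, res_name, rmsf)
    fit_description: str = ""
    n_frames: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain, res, name, value in self.entries:
            if value < 0:
                raise ValueError(f"negative RMSF for {chain}{res} {name}")

    @property
    def values(self) -> np.ndarray:
        return np.array([e[3] for e in self.entries])

    def to_frame(self, bfactor_column: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["chain", "res_seq", "res_name", "rmsf_A"])
        if bfactor_column:
            # optional annotation only: crystallographic-B equivalent of the RMSF
            df["b_equivalent_A2"] = _B_FROM_MSD * df["rmsf_A"] ** 2
        return df

    def to_csv(self, path: str | Path | io.TextIOBase, bfactor_column: bool = False) -> None:
        self.to_frame(bfactor_column).to_csv(path, index=False, float_format="%.4f")


def rmsf(
    traj: Trajectory,
    report_selection: Selection | np.ndarray,
    fit_selection: Optional[Selection | np.ndarray] = None,
    align: bool = True,
) -> RMSFProfile:
    """Root-mean-square fluctuation per reported residue about the mean structure.

    Frames are first aligned on ``fit_selection`` to the iterative average
    structure (set ``align=False`` for pre-aligned/synthetic input); the
    reported selection must resolve to exactly one atom per residue
    (Cα by convention).
    """
    top = traj.topology
    rep_idx = (
        report_selection.resolve(top)
        if isinstance(report_selection, Selection)
        else np.asarray(report_selection, dtype=int)
    )
    if rep_idx.size == 0:
        raise ValueError("report selection resolved to zero atoms")

    seen: dict[tuple, int] = {}
    for i in rep_idx:
        key = top.residue_of(int(i))
        if key in seen:
            chain, res, icode = key
            raise ValueError(
                f"residue {chain}{res}{icode} contributes more than one atom "
                "to the report selection; pick a single atom (e.g. CA) per residue"
            )
        seen[key] = int(i)

    if align:
        if fit_selection is None:
            fit_selection = rep_idx
        avg = average_structure(traj, fit_selection)
        work = align_trajectory(traj, fit_selection, avg)
    else:
        work = traj

    mean_pos = work.coords[:, rep_idx].mean(axis=0)  # (n_rep, 3)
    dev = work.coords[:, rep_idx] - mean_pos[None]
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))

    entries = []
    for i, value in zip(rep_idx, per_atom):
        a = top.atoms[int(i)]
        entries.append((a.chain_id, a.res_seq, a.res_name, float(value)))
    fit_desc = "none (alignment disabled)" if not align else repr(fit_selection)
    return RMSFProfile(
        entries=entries,
        fit_description=fit_desc,
        n_frames=traj.n_frames,
        provenance={"aligned": bool(align), "n_frames": traj.n_frames},
    )


def mean_bfactor(
    structure: Trajectory,
    sel: Selection | np.ndarray,
    heavy_only: bool = True,
) -> float:
    """Unweighted arithmetic mean B-factor (Å²) over the selected atoms.

    By default hydrogens are excluded (crystal structures rarely refine
    them); pass ``heavy_only=False`` to average over every selected atom.
    """
    top = structure.topology
    idx = sel.resolve(top) if isinstance(sel, Selection) else np.asarray(sel, dtype=int)
    if heavy_only:
        idx = np.array([i for i in idx if not top.atoms[int(i)].is_hydrogen], dtype=int)
    if idx.size == 0:
        raise ValueError("selection resolved to zero atoms for mean B-factor")
    return float(np.mean([top.atoms[int(i)].b_factor for i in idx]))


def pairwise_rmsd(
    a: Trajectory,
    b: Trajectory,
    sel_a: Selection | np.ndarray,
    sel_b: Selection | np.ndarray,
    superpose: bool = True,
    frame_a: int = 0,
    frame_b: int = 0,
) -> float:
    """RMSD (Å) between two order-matched atom selections of two structures.

    With ``superpose`` (default) the compared atoms themselves are first
    optimally superposed; otherwise the raw deviation is returned.
    """
    idx_a = sel_a.resolve(a.topology) if isinstance(sel_a, Selection) else np.asarray(sel_a, int)
    idx_b = sel_b.resolve(b.topology) if isinstance(sel_b, Selection) else np.asarray(sel_b, int)
    if idx_a.size != idx_b.size:
        raise ValueError(
            f"selections resolve to different atom counts: {idx_a.size} vs {idx_b.size}"
        )
    if idx_a.size == 0:
        raise ValueError("empty selections for pairwise RMSD")
    pa = a.coords[frame_a, idx_a]
    pb = b.coords[frame_b, idx_b]
    if superpose:
        _t, value = kabsch_superpose(pa, pb)
        return value
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
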