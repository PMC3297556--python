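"""Rigid-body characterisation of TCR movement atop the pMHC.

Per-frame rocking angle/axis of the TCR relative to a reference after
aligning each frame on the MHC Cα frame; displacement direction decomposed
parallel/perpendicular to the antigen-binding cleft axis within the MHC
plane; docking-angle difference between two complexes.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose, rotation_angle_axis
from .model_io import Selection, Trajectory

__all__ = [
    "MotionSeries",
    "DirectionSummary",
    "cleft_axis",
    "mhc_plane_normal",
    "tcr_motion_series",
    "motion_direction",
    "docking_angle_difference",
]

#: parallel-fraction thresholds for the direction label
PARALLEL_THRESHOLD = 0.6
ORTHOGONAL_THRESHOLD = 0.4


def _resolve(traj_or_top, sel: Selection | np.ndarray) -> np.ndarray:
    top = traj_or_top.topology if isinstance(traj_or_top, Trajectory) else traj_or_top
    idx = sel.resolve(top) if isinstance(sel, Selection) else np.asarray(sel, dtype=int)
    return idx


def cleft_axis(structure: Trajectory, peptide_selection: Selection | np.ndarray) -> np.ndarray:
    """Principal axis of the peptide Cα trace, oriented N→C terminus.

    Defines the direction of the antigen-binding cleft.  Deterministic
    orientation: positive dot product with the first-to-last residue vector.
    """
    idx = _resolve(structure, peptide_selection)
    if idx.size < 3:
        raise ValueError(f"cleft axis needs at least 3 peptide atoms; got {idx.size}")
    pts = structure.coords[0, idx]
    centered = pts - pts.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    span = pts[-1] - pts[0]
    if np.dot(axis, span) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def mhc_plane_normal(structure: Trajectory, mhc_selection: Selection | np.ndarray) -> np.ndarray:
    """Normal of the MHC platform plane: third principal axis of the MHC Cα set."""
    idx = _resolve(structure, mhc_selection)
    if idx.size < 3:
        raise ValueError("plane normal needs at least 3 atoms")
    pts = structure.coords[0, idx]
    centered = pts - pts.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    n = vt[2]
    return n / np.linalg.norm(n)


@dataclass
class MotionSeries:
    """Per-frame TCR rigid-body state relative to a reference, in the MHC frame."""

    angles: np.ndarray  # (F,) degrees, ≥ 0
    axes: np.ndarray  # (F, 3) unit vectors
    displacements: np.ndarray  # (F, 3) TCR centroid displacement, Å
    reference: str = ""
    cleft: Optional[np.ndarray] = None
    plane_normal: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if (self.angles < 0).any():
            raise ValueError("rotation angles must be non-negative")
        norms = np.linalg.norm(self.axes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("axes must be unit vectors")
        if not (self.angles.shape[0] == self.axes.shape[0] == self.displacements.shape[0]):
            raise ValueError("per-frame arrays disagree in length")

    @property
    def n_frames(self) -> int:
        return int(self.angles.size)

    @property
    def max_angle(self) -> float:
        return float(self.angles.max())

    @property
    def max_angle_frame(self) -> int:
        return int(self.angles.argmax())

    def to_frame(self) -> pd.DataFrame:
        d_par, d_perp = _decompose(self.displacements, self.cleft, self.plane_normal)
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "angle_deg": self.angles,
                "axis_x": self.axes[:, 0],
                "axis_y": self.axes[:, 1],
                "axis_z": self.axes[:, 2],
                "disp_par_A": d_par,
                "disp_perp_A": d_perp,
            }
        )

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        df = self.to_frame()
        if isinstance(path, (str, Path)):
            with open(path, "w") as fh:
                if self.provenance:
                    fh.write("# provenance: " + json.dumps(self.provenance, sort_keys=True) + "\n")
                df.to_csv(fh, index=False, float_format="%.6f")
        else:
            df.to_csv(path, index=False, float_format="%.6f")


def _decompose(
    displacements: np.ndarray,
    cleft: Optional[np.ndarray],
    plane_normal: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Split displacements into |parallel| and |perpendicular| magnitudes.

    Perpendicular is measured within the MHC plane when a plane normal is
    given (out-of-plane motion is projected away first).
    """
    if cleft is None:
        zeros = np.zeros(displacements.shape[0])
        return zeros, np.linalg.norm(displacements, axis=1)
    cleft = cleft / np.linalg.norm(cleft)
    d = displacements
    if plane_normal is not None:
        n = plane_normal / np.linalg.norm(plane_normal)
        d = d - np.outer(d @ n, n)
        cleft_in_plane = cleft - np.dot(cleft, n) * n
        if np.linalg.norm(cleft_in_plane) > 1e-12:
            cleft = cleft_in_plane / np.linalg.norm(cleft_in_plane)
    d_par = d @ cleft
    d_perp_vec = d - np.outer(d_par, cleft)
    return np.abs(d_par), np.linalg.norm(d_perp_vec, axis=1)


def tcr_motion_series(
    traj: Trajectory,
    mhc_fit_selection: Selection | np.ndarray,
    tcr_selection: Selection | np.ndarray,
    reference_frame: int = 0,
    cleft: Optional[np.ndarray] = None,
    plane_normal: Optional[np.ndarray] = None,
) -> MotionSeries:
    """Per-frame rigid rotation and centroid displacement of the TCR subunit.

    Every frame is first superposed onto the reference frame using the MHC
    fit atoms; the residual Kabsch rotation between the frame's TCR atoms
    and the reference TCR atoms is then the rocking state for that frame.
    A rigid motion of the whole complex therefore produces zero angles.
    """
    mhc_idx = _resolve(traj, mhc_fit_selection)
    tcr_idx = _resolve(traj, tcr_selection)
    if mhc_idx.size == 0 or tcr_idx.size == 0:
        raise ValueError("MHC and TCR selections must be non-empty")
    if set(map(int, mhc_idx)) & set(map(int, tcr_idx)):
        raise ValueError("MHC and TCR selections must be disjoint")

    ref = traj.coords[reference_frame]
    angles = np.zeros(traj.n_frames)
    axes = np.tile(np.array([1.0, 0.0, 0.0]), (traj.n_frames, 1))
    disp = np.zeros((traj.n_frames, 3))
    ref_tcr_centroid = ref[tcr_idx].mean(axis=0)
    for f in range(traj.n_frames):
        fit, _ = kabsch_superpose(traj.coords[f, mhc_idx], ref[mhc_idx])
        frame_in_ref = fit.apply(traj.coords[f])
        t, _rmsd = kabsch_superpose(ref[tcr_idx], frame_in_ref[tcr_idx])
        angles[f], axes[f] = rotation_angle_axis(t)
        disp[f] = frame_in_ref[tcr_idx].mean(axis=0) - ref_tcr_centroid
    return MotionSeries(
        angles=angles,
        axes=axes,
        displacements=disp,
        reference=f"frame {reference_frame}",
        cleft=cleft,
        plane_normal=plane_normal,
        provenance={"reference_frame": reference_frame, "n_frames": traj.n_frames},
    )


@dataclass
class DirectionSummary:
    parallel_fraction: float
    label: str  # parallel | orthogonal | mixed | static
    total_parallel: float
    total_perpendicular: float


def motion_direction(
    series: MotionSeries,
    cleft: np.ndarray,
    plane_normal: Optional[np.ndarray] = None,
) -> DirectionSummary:
    """Classify TCR centroid motion as parallel/orthogonal to the cleft axis.

    parallel-fraction = Σ|d_par| / (Σ|d_par| + Σ|d_perp|); labels:
    ≥ 0.6 parallel, ≤ 0.4 orthogonal, otherwise mixed.  All-zero
    displacement is labelled "static".
    """
    if series.n_frames == 0:
        raise ValueError("empty motion series")
    d_par, d_perp = _decompose(series.displacements, cleft, plane_normal)
    total_par = float(d_par.sum())
    total_perp = float(d_perp.sum())
    total = total_par + total_perp
    if total < 1e-12:
        return DirectionSummary(0.0, "static", 0.0, 0.0)
    frac = total_par / total
    if frac >= PARALLEL_THRESHOLD:
        label = "parallel"
    elif frac <= ORTHOGONAL_THRESHOLD:
        label = "orthogonal"
    else:
        label = "mixed"
    return DirectionSummary(frac, label, total_par, total_perp)


def docking_angle_difference(
    complex_a: Trajectory,
    complex_b: Trajectory,
    mhc_sel_a: Selection | np.ndarray,
    tcr_sel_a: Selection | np.ndarray,
    mhc_sel_b: Optional[Selection | np.ndarray] = None,
    tcr_sel_b: Optional[Selection | np.ndarray] = None,
) -> float:
    """Rotation angle (degrees) between two complexes' TCR orientations.

    Complex B is superposed onto complex A on the MHC Cα atoms; the Kabsch
    rotation between the two TCR atom sets is then reported.  Symmetric in
    its arguments to within numerical precision.
    """
    mhc_sel_b = mhc_sel_a if mhc_sel_b is None else mhc_sel_b
    tcr_sel_b = tcr_sel_a if tcr_sel_b is None else tcr_sel_b
    mhc_a = complex_a.coords[0, _resolve(complex_a, mhc_sel_a)]
    tcr_a = complex_a.coords[0, _resolve(complex_a, tcr_sel_a)]
    mhc_b = complex_b.coords[0, _resolve(complex_b, mhc_sel_b)]
    tcr_b = complex_b.coords[0, _resolve(complex_b, tcr_sel_b)]
    if tcr_a.shape != tcr_b.shape:
        raise ValueError(
            f"TCR selections differ in atom count: {tcr_a.shape[0]} vs {tcr_b.shape[0]}"
        )
    fit, _ = kabsch_superpose(mhc_b, mhc_a)
    tcr_b_in_a = fit.apply(tcr_b)
    t, _rmsd = kabsch_superpose(tcr_a, tcr_b_in_a)
    angle, _axis = rotation_angle_axis(t)
    return angle
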