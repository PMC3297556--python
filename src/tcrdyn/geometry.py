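"""Rigid-body superposition and alignment machinery.

All angles are degrees at the API surface and radians internally; RMSD is
mass-unweighted over the stated atom selection only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_io import Selection, Trajectory

__all__ = [
    "RigidTransform",
    "kabsch_superpose",
    "rotation_angle_axis",
    "average_structure",
    "align_trajectory",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Point set too small or collinear for a unique superposition."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation (det = +1) plus translation, y = R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("RigidTransform needs a 3x3 rotation and a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError(f"rotation must be proper (det=+1); det={np.linalg.det(R)}")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _check_nondegenerate(points: np.ndarray, label: str) -> None:
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError(
            f"{label} point set is collinear (or degenerate); superposition is not unique"
        )


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``target``.

    Returns the proper-rotation transform (reflections corrected via the
    SVD sign trick) and the post-fit RMSD in Å.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"point sets differ in shape: mobile {mobile.shape} vs target {target.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be (n, 3)")
    if mobile.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for superposition")
    _check_nondegenerate(mobile, "mobile")
    _check_nondegenerate(target, "target")

    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    transform = RigidTransform(R, t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return transform, rmsd


def rotation_angle_axis(t: RigidTransform) -> tuple[float, np.ndarray]:
    """Angle (degrees in [0, 180]) and unit axis of a rigid transform's rotation.

    Axis sign convention: first nonzero component positive.  For the
    identity rotation the conventional axis ``(1, 0, 0)`` is returned.
    """
    R = t.rotation
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_theta = np.linalg.norm(skew) / 2.0
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    # atan2 form of arccos((trace-1)/2): identical value, stable near 0°/180°
    theta = float(np.arctan2(sin_theta, cos_theta))
    if theta < 1e-12:
        return 0.0, np.array([1.0, 0.0, 0.0])
    if np.pi - theta < 1e-6:
        # near 180°: skew part vanishes; take the eigenvector for eigenvalue +1
        w, v = np.linalg.eigh((R + R.T) / 2.0)
        axis = v[:, np.argmax(w)]
    else:
        axis = skew / (2.0 * sin_theta)
    axis = axis / np.linalg.norm(axis)
    for c in axis:
        if abs(c) > 1e-12:
            if c < 0:
                axis = -axis
            break
    return float(np.degrees(theta)), axis


def _resolve_fit(traj: Trajectory, fit_selection: Optional[Selection | np.ndarray]) -> np.ndarray:
    if fit_selection is None:
        raise ValueError("fit selection must not be empty")
    if isinstance(fit_selection, Selection):
        idx = fit_selection.resolve(traj.topology)
    else:
        idx = np.asarray(fit_selection, dtype=int)
    if idx.size == 0:
        raise ValueError("fit selection resolved to zero atoms")
    return idx


def average_structure(
    traj: Trajectory,
    fit_selection: Optional[Selection | np.ndarray] = None,
    n_iterations: int = 2,
) -> np.ndarray:
    """Per-atom mean coordinates after iterative alignment on ``fit_selection``.

    Two passes by default: frames are first aligned to frame 0 on the fit
    atoms and averaged, then re-aligned to that mean and re-averaged.
    ``fit_selection=None`` disables alignment (plain mean) for use with
    pre-aligned or synthetic data.
    """
    if fit_selection is None:
        return traj.coords.mean(axis=0)
    idx = _resolve_fit(traj, fit_selection)
    reference = traj.coords[0]
    coords = traj.coords
    for _ in range(max(1, n_iterations)):
        aligned = np.empty_like(coords)
        for f in range(coords.shape[0]):
            transform, _ = kabsch_superpose(coords[f, idx], reference[idx])
            aligned[f] = transform.apply(coords[f])
        reference = aligned.mean(axis=0)
        coords = aligned
    return reference


def align_trajectory(
    traj: Trajectory,
    fit_selection: Selection | np.ndarray,
    reference: np.ndarray,
) -> Trajectory:
    """Rigid-transform every frame so the fit atoms best match ``reference``.

    ``reference`` is either a full (N, 3) frame or just the fit-atom subset
    in selection order.  Intra-frame geometry is untouched (rigid motion).
    """
    idx = _resolve_fit(traj, fit_selection)
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] == traj.n_atoms:
        ref_fit = reference[idx]
    elif reference.shape[0] == idx.size:
        ref_fit = reference
    else:
        raise ValueError(
            f"reference has {reference.shape[0]} atoms; expected {traj.n_atoms} "
            f"(full frame) or {idx.size} (fit atoms)"
        )
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        transform, _ = kabsch_superpose(traj.coords[f, idx], ref_fit)
        out[f] = transform.apply(traj.coords[f])
    return traj.with_coords(out)
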