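"""Structure and trajectory I/O: PDB parsing, atom selection, hydrogen attachment.

The internal model is deliberately small: a :class:`Topology` (atoms grouped
into residues, plus a hydrogen-to-heavy-atom attachment map) and a
:class:`Trajectory` (an ``(F, N, 3)`` coordinate array bound to a topology).
Only the PDB dialect actually needed for analysis is handled:
ATOM/HETATM/MODEL/ENDMDL/TER records with fixed columns per wwPDB v3.3.

Conventions:

* author residue numbering (``resSeq``) is authoritative; ranges are 1-based
  and inclusive,
* for alternate locations the highest-occupancy conformer is kept
  (ties broken by lowest altloc identifier),
* waters/ions (HETATM) are parsed and carried in the topology but excluded
  from selections by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "Selection",
    "PDBParseError",
    "ModelIndexError",
    "FrameMismatchError",
    "EmptyStructureError",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "select",
    "infer_h_attachment",
    "H_COVALENT_CUTOFF",
]

#: Covalent cutoff used to attach a hydrogen to its nearest heavy atom (Å).
H_COVALENT_CUTOFF = 1.2

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "SOL", "TIP3"})

# Two-letter element symbols that occur in common HETATM groups; used only
# when the element column is absent.
_TWO_LETTER_ELEMENTS = frozenset(
    {"FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO", "SE", "CD", "HG"}
)


class PDBParseError(ValueError):
    """A malformed record; the message names the offending line number."""


class ModelIndexError(IndexError):
    """Requested MODEL index not present in file."""


class FrameMismatchError(ValueError):
    """A trajectory frame disagrees with the topology atom count."""


class EmptyStructureError(ValueError):
    """No protein (non-HETATM) atoms survived parsing."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    insertion_code: str = ""
    b_factor: float = 0.0
    occupancy: float = 1.0
    is_hetero: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_water(self) -> bool:
        return self.res_name in _WATER_NAMES


@dataclass
class Topology:
    """Ordered atom catalogue with residue grouping and H attachment map."""

    atoms: list[AtomRecord]
    residues: dict[tuple[str, int, str], list[int]] = field(default_factory=dict)
    h_attachment: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            self.residues = _group_residues(self.atoms)
        for h, heavy in self.h_attachment.items():
            if not self.atoms[h].is_hydrogen:
                raise ValueError(f"h_attachment key {h} is not a hydrogen")
            if self.atoms[heavy].is_hydrogen:
                raise ValueError(f"h_attachment value {heavy} is a hydrogen")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_of(self, atom_index: int) -> tuple[str, int, str]:
        return self.atoms[atom_index].residue_key

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


def _group_residues(atoms: Sequence[AtomRecord]) -> dict[tuple[str, int, str], list[int]]:
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i, a in enumerate(atoms):
        groups.setdefault(a.residue_key, []).append(i)
    return groups


@dataclass
class Trajectory:
    """F frames × N atoms × 3 Cartesian coordinates (Å) bound to a Topology."""

    topology: Topology
    coords: np.ndarray
    frame_times: Optional[np.ndarray] = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, N, 3); got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FrameMismatchError(
                f"coordinate array has {self.coords.shape[1]} atoms but the "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("trajectory coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.frame_times)


@dataclass(frozen=True)
class Selection:
    """Declarative atom predicate; resolves to a topology-ordered index list.

    Any component left as ``None`` matches everything.  ``hetero=False``
    (the default) restricts to ATOM records, so waters/ions are excluded
    unless asked for explicitly (``hetero=None`` matches both).
    """

    chains: Optional[frozenset[str]] = None
    res_ranges: Optional[tuple[tuple[int, int], ...]] = None
    names: Optional[frozenset[str]] = None
    elements: Optional[frozenset[str]] = None
    hetero: Optional[bool] = False

    @classmethod
    def make(
        cls,
        chains: Optional[Iterable[str]] = None,
        res_ranges: Optional[Iterable[tuple[int, int]]] = None,
        names: Optional[Iterable[str]] = None,
        elements: Optional[Iterable[str]] = None,
        hetero: Optional[bool] = False,
    ) -> "Selection":
        return cls(
            chains=frozenset(chains) if chains is not None else None,
            res_ranges=tuple(tuple(r) for r in res_ranges) if res_ranges is not None else None,
            names=frozenset(names) if names is not None else None,
            elements=frozenset(elements) if elements is not None else None,
            hetero=hetero,
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.hetero is not None and atom.is_hetero != self.hetero:
            return False
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.res_ranges is not None and not any(
            lo <= atom.res_seq <= hi for lo, hi in self.res_ranges
        ):
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        if self.elements is not None and atom.element not in self.elements:
            return False
        return True

    def resolve(self, topology: Topology) -> np.ndarray:
        return select(topology, self)


def select(topology: Topology, expr: Selection) -> np.ndarray:
    """Resolve a :class:`Selection` to a deterministic topology-ordered index array.

    Unknown chains yield an empty result (logged at warning level), never an
    error; an empty selection is a valid value.
    """
    if expr.chains is not None:
        present = set(topology.chain_ids())
        for c in sorted(expr.chains - present):
            logger.warning("selection references unknown chain %r", c)
    idx = [i for i, a in enumerate(topology.atoms) if expr.matches(a)]
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _infer_element(name: str, res_name: str, is_hetero: bool) -> str:
    """Derive the element from the atom-name field per PDB naming rules."""
    raw = name.strip()
    if not raw:
        return ""
    if raw[0].isdigit():  # e.g. 1HB2
        raw = raw[1:]
    if is_hetero and raw[:2].upper() in _TWO_LETTER_ELEMENTS and len(name.strip()) <= 2:
        return raw[:2].upper().capitalize()
    for ch in raw:
        if ch.isalpha():
            return ch.upper()
    return raw[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_seq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        b_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        b_factor = float(b_field) if b_field else 0.0
        elem_field = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    is_het = line.startswith("HETATM")
    element = elem_field.capitalize() if elem_field else _infer_element(name, res_name, is_het)
    if element == "D":  # deuterium behaves as hydrogen
        element = "H"
    rec = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        insertion_code=icode,
        b_factor=b_factor,
        occupancy=occupancy,
        is_hetero=is_het,
    )
    return rec, np.array([x, y, z]), altloc


def _parse_models(path: Path) -> list[list[tuple[AtomRecord, np.ndarray, str]]]:
    """Parse every MODEL in a PDB file into raw (record, xyz, altloc) lists."""
    models: list[list[tuple[AtomRecord, np.ndarray, str]]] = []
    current: list[tuple[AtomRecord, np.ndarray, str]] = []
    in_model = False
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("MODEL"):
            if current:
                models.append(current)
                current = []
            in_model = True
        elif line.startswith("ENDMDL"):
            models.append(current)
            current = []
            in_model = False
        elif line.startswith(("ATOM  ", "HETATM")):
            current.append(_parse_atom_line(line, lineno))
    if current or not models:
        models.append(current)
    del in_model
    return [m for m in models if m] or [[]]


def _collapse_altlocs(
    raw: list[tuple[AtomRecord, np.ndarray, str]],
) -> tuple[list[AtomRecord], np.ndarray]:
    """Keep the highest-occupancy altloc per atom site (ties: lowest altloc id)."""
    best: dict[tuple, tuple[float, str, int]] = {}
    for i, (rec, _xyz, altloc) in enumerate(raw):
        key = (rec.chain_id, rec.res_seq, rec.insertion_code, rec.res_name, rec.name)
        cand = (-rec.occupancy, altloc or "A", i)
        if key not in best or cand < best[key]:
            best[key] = cand
    keep = sorted(i for (_occ, _al, i) in best.values())
    atoms = [raw[i][0] for i in keep]
    coords = np.array([raw[i][1] for i in keep]) if keep else np.empty((0, 3))
    return atoms, coords


def read_structure(
    path: str | Path,
    model_index: int = 0,
    require_protein: bool = True,
) -> Trajectory:
    """Read a single MODEL of a PDB file into a one-frame :class:`Trajectory`.

    Parameters
    ----------
    path:
        PDB-dialect text file.
    model_index:
        0-based MODEL to read (default: first).
    require_protein:
        When true (default), a file whose selected model holds only HETATM
        records (e.g. waters) raises :class:`EmptyStructureError`.
    """
    path = Path(path)
    models = _parse_models(path)
    if not (0 <= model_index < len(models)):
        raise ModelIndexError(
            f"model_index {model_index} out of range: file has {len(models)} model(s)"
        )
    atoms, coords = _collapse_altlocs(models[model_index])
    if require_protein and not any(not a.is_hetero for a in atoms):
        raise EmptyStructureError(f"{path} contains no protein (ATOM) records")
    topology = Topology(atoms=atoms)
    traj = Trajectory(topology, coords[None])
    topology.h_attachment = infer_h_attachment(topology, traj.frame(0))
    return traj


def read_trajectory(
    structure_path: str | Path,
    frames_path: Optional[str | Path] = None,
    require_protein: bool = True,
) -> Trajectory:
    """Read a multi-frame trajectory.

    With only ``structure_path`` given, every MODEL of that file becomes a
    frame.  With ``frames_path`` also given, the topology comes from the
    structure file and the coordinates from the frames file, which is either
    a multi-MODEL PDB or (optionally, via MDAnalysis) a binary DCD.
    All frames must match the structure's atom count and order; a mismatch
    at frame ``k`` is reported naming ``k``.
    """
    first = read_structure(structure_path, model_index=0, require_protein=require_protein)
    topology = first.topology
    if frames_path is None:
        models = _parse_models(Path(structure_path))
        frames = []
        for k, raw in enumerate(models):
            _atoms, coords = _collapse_altlocs(raw)
            if coords.shape[0] != topology.n_atoms:
                raise FrameMismatchError(
                    f"frame {k} has {coords.shape[0]} atoms, expected {topology.n_atoms}"
                )
            frames.append(coords)
        return _finish_trajectory(topology, np.stack(frames))

    frames_path = Path(frames_path)
    if frames_path.suffix.lower() == ".dcd":
        return _read_dcd(topology, structure_path, frames_path)
    models = _parse_models(frames_path)
    frames = []
    for k, raw in enumerate(models):
        _atoms, coords = _collapse_altlocs(raw)
        if coords.shape[0] != topology.n_atoms:
            raise FrameMismatchError(
                f"frame {k} has {coords.shape[0]} atoms, expected {topology.n_atoms}"
            )
        frames.append(coords)
    return _finish_trajectory(topology, np.stack(frames))


def _finish_trajectory(topology: Topology, coords: np.ndarray) -> Trajectory:
    traj = Trajectory(topology, coords)
    topology.h_attachment = infer_h_attachment(topology, traj.frame(0))
    return traj


def _read_dcd(topology: Topology, structure_path, frames_path) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading DCD trajectories requires MDAnalysis") from exc
    u = mda.Universe(str(structure_path), str(frames_path))
    frames = []
    for k, _ts in enumerate(u.trajectory):
        pos = u.atoms.positions.astype(float)
        if pos.shape[0] != topology.n_atoms:
            raise FrameMismatchError(
                f"frame {k} has {pos.shape[0]} atoms, expected {topology.n_atoms}"
            )
        frames.append(pos.copy())
    return _finish_trajectory(topology, np.stack(frames))


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # One/two-letter elements with short names start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(rec: AtomRecord, xyz: np.ndarray, serial: int) -> str:
    tag = "HETATM" if rec.is_hetero else "ATOM  "
    return (
        f"{tag}{serial:5d} {_format_atom_name(rec.name, rec.element)}"
        f" {rec.res_name:>3s} {rec.chain_id:1s}{rec.res_seq:4d}{rec.insertion_code or ' ':1s}"
        f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{rec.occupancy:6.2f}{rec.b_factor:6.2f}"
        f"          {rec.element.upper():>2s}"
    )


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as fixed-width (wwPDB v3.3) PDB, multi-MODEL if F > 1."""
    path = Path(path)
    lines: list[str] = []
    multi = traj.n_frames > 1
    for f in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        prev_chain: Optional[str] = None
        serial = 0
        for i, rec in enumerate(traj.topology.atoms):
            if prev_chain is not None and rec.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = rec.chain_id
            serial += 1
            lines.append(_atom_line(rec, traj.coords[f, i], serial))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hydrogen attachment
# ---------------------------------------------------------------------------

def infer_h_attachment(
    topology: Topology,
    frame: np.ndarray,
    cutoff: float = H_COVALENT_CUTOFF,
) -> dict[int, int]:
    """Map each hydrogen to its nearest heavy atom within ``cutoff`` Å.

    Hydrogens with no heavy atom in range stay unmapped and are logged at
    warning level; a partial map is a valid result.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.isfinite(frame).all():
        raise ValueError("frame coordinates must be finite")
    h_idx = [i for i, a in enumerate(topology.atoms) if a.is_hydrogen]
    heavy_idx = [i for i, a in enumerate(topology.atoms) if not a.is_hydrogen]
    if not h_idx or not heavy_idx:
        return {}
    tree = cKDTree(frame[heavy_idx])
    dist, nn = tree.query(frame[h_idx], k=1)
    mapping: dict[int, int] = {}
    for h, d, j in zip(h_idx, np.atleast_1d(dist), np.atleast_1d(nn)):
        if d <= cutoff:
            mapping[h] = heavy_idx[int(j)]
        else:
            a = topology.atoms[h]
            logger.warning(
                "hydrogen %s %s%d:%s has no heavy atom within %.2f Å (nearest %.2f Å)",
                a.name, a.chain_id, a.res_seq, a.res_name, cutoff, d,
            )
    return mapping
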