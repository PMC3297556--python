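"""Hydrogen-bond and heavy-atom contact detection between two molecular groups.

Geometric criterion: a bond is formed in a frame when the donor-heavy to
acceptor distance is at most ``d_max`` (default 3.5 Å) AND, for at least one
hydrogen attached to the donor, the angle at that hydrogen between donor and
acceptor is at least ``theta_min`` (default 150°, i.e. 180° ± 30°).  Both
boundaries are inclusive.  The distance cutoff is interpreted
donor-heavy ↔ acceptor-heavy.

For hydrogen-free structures (crystal references) a distance-only mode pairs
table-derived potential donors with acceptors under ``d_max`` alone; outputs
record which mode produced them.

Input coordinates are assumed pre-imaged (molecules whole): there is NO
periodic-boundary minimum-image handling anywhere in this module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import Selection, Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "AtomRef",
    "HBondSeries",
    "ContactSeries",
    "assign_donors_acceptors",
    "hbonds_in_frame",
    "hbond_series",
    "contacts_in_frame",
    "contact_series",
    "salt_bridge_flag",
    "hbond_table",
    "greek_atom_label",
]


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5  # donor-heavy to acceptor distance cutoff, Å
    theta_min: float = 150.0  # minimum donor–H–acceptor angle, degrees

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0.0 < self.theta_min <= 180.0):
            raise ValueError("theta_min must be in (0, 180]")


@dataclass(frozen=True)
class AtomRef:
    """Human-readable handle for one participant of an interaction."""

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    index: int = -1  # topology index; -1 for merged/symbolic refs

    def label(self) -> str:
        return f"{self.res_name.capitalize()}{self.res_seq}^{greek_atom_label(self.atom_name)}^"


@dataclass
class HBondSeries:
    """One donor/acceptor pair with its per-frame formed/broken vector."""

    donor: AtomRef
    acceptor: AtomRef
    formed: np.ndarray  # (F,) bool
    hydrogen: Optional[AtomRef] = None
    distance_only: bool = False

    def __post_init__(self) -> None:
        self.formed = np.asarray(self.formed, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.formed.size)

    @property
    def n_formed(self) -> int:
        return int(self.formed.sum())


@dataclass
class ContactSeries:
    """Closest heavy-atom approach between one residue pair, per frame."""

    res_a: tuple[str, int, str]  # (chain, res_seq, res_name)
    res_b: tuple[str, int, str]
    min_distance: np.ndarray  # (F,) Å
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        self.min_distance = np.asarray(self.min_distance, dtype=float)
        if (self.min_distance < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def formed(self) -> np.ndarray:
        return self.min_distance <= self.cutoff


# ---------------------------------------------------------------------------
# Donor/acceptor chemistry
# ---------------------------------------------------------------------------

# Side-chain acceptors by residue type (atoms carrying an accessible lone pair).
_SIDECHAIN_ACCEPTORS: frozenset[tuple[str, str]] = frozenset(
    {
        ("ASP", "OD1"), ("ASP", "OD2"),
        ("GLU", "OE1"), ("GLU", "OE2"),
        ("ASN", "OD1"),
        ("GLN", "OE1"),
        ("SER", "OG"),
        ("THR", "OG1"),
        ("TYR", "OH"),
        ("HIS", "ND1"), ("HIS", "NE2"),  # treated as acceptors unless protonated
        ("MET", "SD"),
    }
)

# Potential donors for hydrogen-free (distance-only) structures: heavy atoms
# that would carry a polar hydrogen in the standard protonation state.
_POTENTIAL_SIDECHAIN_DONORS: frozenset[tuple[str, str]] = frozenset(
    {
        ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
        ("LYS", "NZ"),
        ("ASN", "ND2"),
        ("GLN", "NE2"),
        ("HIS", "ND1"), ("HIS", "NE2"),
        ("SER", "OG"),
        ("THR", "OG1"),
        ("TYR", "OH"),
        ("TRP", "NE1"),
        ("CYS", "SG"),
    }
)

# Chemically equivalent atom pairs reported as a single "1/2" site.
_EQUIVALENT_ATOMS: dict[tuple[str, str], str] = {
    ("ARG", "NH1"): "NH1/2",
    ("ARG", "NH2"): "NH1/2",
    ("ASP", "OD1"): "OD1/2",
    ("ASP", "OD2"): "OD1/2",
    ("GLU", "OE1"): "OE1/2",
    ("GLU", "OE2"): "OE1/2",
}

# PDB remoteness letters → Greek, for display labels (e.g. OD1 → Oδ1).
_GREEK = {"A": "α", "B": "β", "G": "γ", "D": "δ", "E": "ε", "Z": "ζ", "H": "η"}


def greek_atom_label(atom_name: str) -> str:
    """Render a PDB atom name with its remoteness letter in Greek (OD1 → Oδ1)."""
    name = atom_name
    if len(name) >= 2 and name[0] in "NOS" and name[1] in _GREEK:
        return name[0] + _GREEK[name[1]] + name[2:]
    return name


def equivalent_site_name(res_name: str, atom_name: str) -> str:
    """Merged site name for chemically equivalent atoms, else the atom name."""
    return _EQUIVALENT_ATOMS.get((res_name.upper(), atom_name.upper()), atom_name)


def assign_donors_acceptors(
    topology: Topology,
    restrict: Optional[np.ndarray] = None,
    include_potential_donors: bool = False,
) -> tuple[list[tuple[int, list[int]]], list[int]]:
    """Classify N/O/S heavy atoms of a topology into donors and acceptors.

    Donors are N/O/S atoms with at least one attached hydrogen (proline
    backbone N is never a donor).  Acceptors are backbone O/OXT plus the
    side-chain lone-pair table.  With ``include_potential_donors`` the
    standard-protonation donor table is added for hydrogen-free structures.

    Returns ``(donors, acceptors)`` where each donor is
    ``(heavy_index, [hydrogen indices])`` (the hydrogen list is empty for
    table-derived potential donors).
    """
    heavy_to_h: dict[int, list[int]] = {}
    for h, heavy in topology.h_attachment.items():
        heavy_to_h.setdefault(heavy, []).append(h)

    scope = range(topology.n_atoms) if restrict is None else [int(i) for i in restrict]
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    for i in scope:
        a = topology.atoms[i]
        if a.is_hydrogen or a.is_water or a.element not in ("N", "O", "S"):
            continue
        res = a.res_name.upper()
        name = a.atom_name if hasattr(a, "atom_name") else a.name
        is_backbone_n = name == "N"
        hydrogens = sorted(heavy_to_h.get(i, []))
        is_donor = bool(hydrogens) and not (is_backbone_n and res == "PRO")
        if not is_donor and include_potential_donors:
            if (is_backbone_n and res != "PRO") or (res, name) in _POTENTIAL_SIDECHAIN_DONORS:
                is_donor = True
        if is_donor:
            donors.append((i, hydrogens))
        if name in ("O", "OXT") or (res, name) in _SIDECHAIN_ACCEPTORS:
            acceptors.append(i)
    return donors, acceptors


# ---------------------------------------------------------------------------
# Per-frame detection
# ---------------------------------------------------------------------------

def _angle_at(p_center: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - p_center
    v2 = p2 - p_center
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbonds_in_frame(
    frame: np.ndarray,
    donors: Sequence[tuple[int, list[int]]],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
    distance_only: bool = False,
) -> set[tuple[int, Optional[int], int]]:
    """Hydrogen bonds present in one frame as ``(donor, hydrogen, acceptor)`` triples.

    A donor with no mapped hydrogen is skipped unless ``distance_only`` is
    set, in which case the angle criterion is waived and the hydrogen slot
    is ``None``.  Cutoff boundaries are inclusive (to 1e-9 numerical
    tolerance, so exactly-on-boundary geometries count as formed).
    """
    frame = np.asarray(frame, dtype=float)
    acceptors = list(acceptors)
    if not acceptors or not donors:
        return set()
    tree = cKDTree(frame[acceptors])
    found: set[tuple[int, Optional[int], int]] = set()
    for d_idx, h_list in donors:
        near = tree.query_ball_point(frame[d_idx], criteria.d_max + 1e-9)
        for j in near:
            a_idx = acceptors[j]
            if a_idx == d_idx:
                continue
            dist = float(np.linalg.norm(frame[a_idx] - frame[d_idx]))
            if dist > criteria.d_max + 1e-9:
                continue
            if distance_only and not h_list:
                found.add((d_idx, None, a_idx))
                continue
            for h_idx in h_list:
                theta = _angle_at(frame[h_idx], frame[d_idx], frame[a_idx])
                if theta >= criteria.theta_min - 1e-9:
                    found.add((d_idx, h_idx, a_idx))
                    break
    return found


def contacts_in_frame(
    frame: np.ndarray,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 4.0,
) -> dict[tuple, float]:
    """Residue pairs with any inter-group heavy-atom distance ≤ cutoff.

    Returns ``{(res_key_a, res_key_b): min_distance}`` over heavy atoms.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ga = [int(i) for i in group_a if not topology.atoms[int(i)].is_hydrogen]
    gb = [int(i) for i in group_b if not topology.atoms[int(i)].is_hydrogen]
    if not ga or not gb:
        return {}
    tree = cKDTree(frame[gb])
    out: dict[tuple, float] = {}
    for i in ga:
        for j_local in tree.query_ball_point(frame[i], cutoff):
            j = gb[j_local]
            d = float(np.linalg.norm(frame[i] - frame[j]))
            key = (topology.residue_of(i), topology.residue_of(j))
            if d <= cutoff and d < out.get(key, np.inf):
                out[key] = d
    return out


# ---------------------------------------------------------------------------
# Trajectory-level series
# ---------------------------------------------------------------------------

def _ref_for(topology: Topology, i: int) -> AtomRef:
    a = topology.atoms[i]
    return AtomRef(a.chain_id, a.res_seq, a.res_name, a.name, index=i)


def hbond_series(
    traj: Trajectory,
    group_a: Selection | np.ndarray,
    group_b: Selection | np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    merge_equivalent: bool = True,
    distance_only: bool = False,
) -> list[HBondSeries]:
    """All inter-group hydrogen bonds formed in at least one frame.

    Both directions (a→b and b→a) are scanned every frame.  With
    ``merge_equivalent`` (default, matching common interaction bookkeeping)
    chemically indistinguishable sites (Arg NH1/NH2, Asp OD1/OD2,
    Glu OE1/OE2) are merged into one series by per-frame logical OR and
    reported with a "1/2"-suffixed atom name.
    """
    top = traj.topology
    idx_a = group_a.resolve(top) if isinstance(group_a, Selection) else np.asarray(group_a, int)
    idx_b = group_b.resolve(top) if isinstance(group_b, Selection) else np.asarray(group_b, int)
    overlap = set(map(int, idx_a)) & set(map(int, idx_b))
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} atom(s); they must be disjoint")

    donors_a, acceptors_a = assign_donors_acceptors(
        top, idx_a, include_potential_donors=distance_only
    )
    donors_b, acceptors_b = assign_donors_acceptors(
        top, idx_b, include_potential_donors=distance_only
    )

    raw: dict[tuple[int, int], np.ndarray] = {}
    first_h: dict[tuple[int, int], Optional[int]] = {}
    F = traj.n_frames
    for f in range(F):
        frame = traj.coords[f]
        hits = hbonds_in_frame(frame, donors_a, acceptors_b, criteria, distance_only)
        hits |= hbonds_in_frame(frame, donors_b, acceptors_a, criteria, distance_only)
        for d_idx, h_idx, a_idx in hits:
            key = (d_idx, a_idx)
            if key not in raw:
                raw[key] = np.zeros(F, dtype=bool)
                first_h[key] = h_idx
            raw[key][f] = True

    if not merge_equivalent:
        series = [
            HBondSeries(
                donor=_ref_for(top, d),
                acceptor=_ref_for(top, a),
                formed=vec,
                hydrogen=_ref_for(top, first_h[(d, a)]) if first_h[(d, a)] is not None else None,
                distance_only=distance_only,
            )
            for (d, a), vec in raw.items()
        ]
        return _sorted_series(series)

    merged: dict[tuple, HBondSeries] = {}
    for (d, a), vec in raw.items():
        d_atom, a_atom = top.atoms[d], top.atoms[a]
        d_site = equivalent_site_name(d_atom.res_name, d_atom.name)
        a_site = equivalent_site_name(a_atom.res_name, a_atom.name)
        key = (
            d_atom.chain_id, d_atom.res_seq, d_atom.insertion_code, d_site,
            a_atom.chain_id, a_atom.res_seq, a_atom.insertion_code, a_site,
        )
        if key in merged:
            merged[key].formed = merged[key].formed | vec
        else:
            h = first_h[(d, a)]
            merged[key] = HBondSeries(
                donor=AtomRef(d_atom.chain_id, d_atom.res_seq, d_atom.res_name, d_site, index=d),
                acceptor=AtomRef(a_atom.chain_id, a_atom.res_seq, a_atom.res_name, a_site, index=a),
                formed=vec.copy(),
                hydrogen=_ref_for(top, h) if h is not None else None,
                distance_only=distance_only,
            )
    return _sorted_series(list(merged.values()))


def _sorted_series(series: list[HBondSeries]) -> list[HBondSeries]:
    return sorted(
        series,
        key=lambda s: (
            s.donor.chain_id, s.donor.res_seq, s.donor.atom_name,
            s.acceptor.chain_id, s.acceptor.res_seq, s.acceptor.atom_name,
        ),
    )


def contact_series(
    traj: Trajectory,
    group_a: Selection | np.ndarray,
    group_b: Selection | np.ndarray,
    cutoff: float = 4.0,
) -> list[ContactSeries]:
    """Residue-pair minimum-distance series over a trajectory."""
    top = traj.topology
    idx_a = group_a.resolve(top) if isinstance(group_a, Selection) else np.asarray(group_a, int)
    idx_b = group_b.resolve(top) if isinstance(group_b, Selection) else np.asarray(group_b, int)
    F = traj.n_frames
    dist: dict[tuple, np.ndarray] = {}
    for f in range(F):
        per_frame = contacts_in_frame(traj.coords[f], top, idx_a, idx_b, cutoff=np.inf
                                      if cutoff is None else max(cutoff, 12.0))
        for key, d in per_frame.items():
            if key not in dist:
                dist[key] = np.full(F, np.inf)
            dist[key][f] = d
    out = []
    for (ka, kb), vec in sorted(dist.items()):
        if (vec <= cutoff).any():
            vec = np.where(np.isfinite(vec), vec, 999.0)
            name_a = top.atoms[top.residues[ka][0]].res_name
            name_b = top.atoms[top.residues[kb][0]].res_name
            out.append(
                ContactSeries(
                    res_a=(ka[0], ka[1], name_a),
                    res_b=(kb[0], kb[1], name_b),
                    min_distance=vec,
                    cutoff=cutoff,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Salt bridges and export
# ---------------------------------------------------------------------------

_BASIC_SIDECHAIN_N = {"NE", "NH1", "NH2", "NH1/2", "NZ"}
_ACIDIC_CARBOXYLATE_O = {"OD1", "OD2", "OD1/2", "OE1", "OE2", "OE1/2"}


def _is_basic_site(res_name: str, atom_name: str) -> bool:
    return res_name.upper() in ("ARG", "LYS") and atom_name.upper() in _BASIC_SIDECHAIN_N


def _is_acidic_site(res_name: str, atom_name: str) -> bool:
    return res_name.upper() in ("ASP", "GLU") and atom_name.upper() in _ACIDIC_CARBOXYLATE_O


def salt_bridge_flag(series: HBondSeries) -> bool:
    """True when the bond links a basic side-chain N to an acidic carboxylate O."""
    d, a = series.donor, series.acceptor
    return (_is_basic_site(d.res_name, d.atom_name) and _is_acidic_site(a.res_name, a.atom_name)) or (
        _is_acidic_site(d.res_name, d.atom_name) and _is_basic_site(a.res_name, a.atom_name)
    )


def hbond_table(series_list: Sequence[HBondSeries]) -> pd.DataFrame:
    """Flat per-bond table (one row per series) for CSV export."""
    rows = []
    for s in series_list:
        rows.append(
            {
                "donor_chain": s.donor.chain_id,
                "donor_res": s.donor.res_seq,
                "donor_atom": s.donor.atom_name,
                "acceptor_chain": s.acceptor.chain_id,
                "acceptor_res": s.acceptor.res_seq,
                "acceptor_atom": s.acceptor.atom_name,
                "n_frames_formed": s.n_formed,
                "persistence_pct": round(100.0 * s.n_formed / s.n_frames),
                "salt_bridge": salt_bridge_flag(s),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "donor_chain", "donor_res", "donor_atom",
            "acceptor_chain", "acceptor_res", "acceptor_atom",
            "n_frames_formed", "persistence_pct", "salt_bridge",
        ],
    )


def write_hbond_csv(
    series_list: Sequence[HBondSeries],
    path: str | Path | io.TextIOBase,
    provenance: Optional[dict] = None,
) -> None:
    df = hbond_table(series_list)
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            _write_with_provenance(df, fh, provenance)
    else:
        _write_with_provenance(df, path, provenance)


def _write_with_provenance(df: pd.DataFrame, fh, provenance: Optional[dict]) -> None:
    if provenance:
        import json

        fh.write("# provenance: " + json.dumps(provenance, sort_keys=True) + "\n")
    df.to_csv(fh, index=False)
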