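"""Interface footprint bookkeeping: persistence, classification, comparison.

A footprint record couples one pMHC-side site (α1-helix / α2-helix / peptide)
with one TCR-side site (CDR loop + residue + atom), a crystal-presence flag
and per-complex persistence percentages, and classifies the interaction as

* ``crystal_and_md`` — present in the crystal structure and observed in
  at least one simulation,
* ``novel_long_lived`` — simulation-only, max persistence ≥ 50 %,
* ``novel_short_lived`` — simulation-only, max persistence < 50 %,
* ``crystal_only`` — crystal contact never observed in simulation.

The 50 % boundary is classified long-lived (the source convention leaves
exactly-50 unassigned; inclusive-upper keeps the classification monotone).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .interface import HBondSeries, greek_atom_label

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_LABELS",
    "FootprintRecord",
    "FootprintTable",
    "persistence",
    "classify",
    "build_footprint",
    "compare_footprints",
    "load_reference_footprint",
    "reference_footprint_path",
]

CLASS_LABELS = ("crystal_and_md", "novel_short_lived", "novel_long_lived", "crystal_only")

#: Boundary (percent) between short- and long-lived simulation-only contacts.
LONG_LIVED_THRESHOLD = 50.0

_GROUP_ORDER = {"alpha1": 0, "alpha2": 1, "peptide": 2, "other": 3}

# Default MHC class I helix limits (author numbering) used to group records.
ALPHA1_HELIX_RANGE = (50, 86)
ALPHA2_HELIX_RANGE = (138, 180)


def persistence(series: HBondSeries | Sequence[bool]) -> float:
    """Percent of frames in which the bond is formed (full precision)."""
    formed = series.formed if isinstance(series, HBondSeries) else series
    n = len(formed)
    if n < 1:
        raise ValueError("persistence needs at least one frame")
    return 100.0 * float(sum(bool(b) for b in formed)) / n


def classify(
    in_crystal: bool,
    persistences: Iterable[Optional[float]],
    threshold: float = LONG_LIVED_THRESHOLD,
) -> str:
    """Class label from crystal presence and per-complex persistence columns.

    ``None`` entries mean "not observed in that simulation".  At least one
    column must be supplied.
    """
    cols = list(persistences)
    if not cols:
        raise ValueError("classify needs at least one persistence column")
    present = [p for p in cols if p is not None]
    for p in present:
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"persistence {p} outside [0, 100]")
    if in_crystal:
        return "crystal_and_md" if present else "crystal_only"
    if not present:
        raise ValueError("a record must be in the crystal or observed in simulation")
    return "novel_long_lived" if max(present) >= threshold else "novel_short_lived"


@dataclass
class FootprintRecord:
    """One pMHC-side ↔ TCR-side interaction with persistence bookkeeping."""

    group: str  # alpha1 | alpha2 | peptide | other
    mhc_res: str  # e.g. "Arg62"
    mhc_atom: str  # display name, e.g. "Nη1/2"
    tcr_loop: str  # e.g. "CDR2β"
    tcr_res: str  # e.g. "Asp56"
    tcr_atom: str
    in_crystal: bool
    persistence: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.mhc_res, self.mhc_atom, self.tcr_loop, self.tcr_res, self.tcr_atom)

    @property
    def class_label(self) -> str:
        return classify(self.in_crystal, self.persistence.values())

    @property
    def mhc_res_seq(self) -> int:
        digits = "".join(c for c in self.mhc_res if c.isdigit())
        return int(digits) if digits else 0


@dataclass
class FootprintTable:
    records: list[FootprintRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.key in seen:
                raise ValueError(f"duplicate footprint key {r.key}; check equivalent-atom merging")
            seen.add(r.key)

    @property
    def complex_labels(self) -> list[str]:
        labels: dict[str, None] = {}
        for r in self.records:
            for c in r.persistence:
                labels.setdefault(c, None)
        return list(labels)

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in CLASS_LABELS}
        for r in self.records:
            counts[r.class_label] += 1
        return counts

    # -- serialisation ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = self.complex_labels
        rows = []
        for r in self.records:
            row = {
                "group": r.group,
                "mhc_residue": r.mhc_res,
                "mhc_atom": r.mhc_atom,
                "tcr_loop": r.tcr_loop,
                "tcr_residue": r.tcr_res,
                "tcr_atom": r.tcr_atom,
                "in_crystal": "Yes" if r.in_crystal else "No",
            }
            for c in cols:
                p = r.persistence.get(c)
                row[f"persistence_{c}"] = "" if p is None else str(int(round(p)))
            row["class"] = r.class_label
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, include_class: bool = True) -> None:
        df = self.to_frame()
        if not include_class:
            df = df.drop(columns=["class"])
        df.to_csv(path, index=False)

    def to_fixture_csv(self) -> str:
        """Serialise in the packaged-fixture layout (no class column)."""
        cols = self.complex_labels
        header = "group,mhc_residue,mhc_atom,tcr_loop,tcr_residue,tcr_atom,in_crystal," + ",".join(
            f"persistence_{c}" for c in cols
        )
        lines = [header]
        for r in self.records:
            vals = [
                r.group, r.mhc_res, r.mhc_atom, r.tcr_loop, r.tcr_res, r.tcr_atom,
                "Yes" if r.in_crystal else "No",
            ]
            for c in cols:
                p = r.persistence.get(c)
                vals.append("" if p is None else str(int(round(p))))
            lines.append(",".join(vals))
        return "\n".join(lines) + "\n"

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "provenance": self.provenance,
            "records": [
                {
                    "group": r.group,
                    "mhc_residue": r.mhc_res,
                    "mhc_atom": r.mhc_atom,
                    "tcr_loop": r.tcr_loop,
                    "tcr_residue": r.tcr_res,
                    "tcr_atom": r.tcr_atom,
                    "in_crystal": r.in_crystal,
                    "persistence": r.persistence,
                    "class": r.class_label,
                }
                for r in self.records
            ],
        }
        text = json.dumps(payload, indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "FootprintTable":
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
        pers_cols = [c for c in df.columns if c.startswith("persistence_")]
        records = []
        for _, row in df.iterrows():
            pers: dict[str, Optional[float]] = {}
            for c in pers_cols:
                label = c[len("persistence_"):]
                pers[label] = None if row[c] == "" else float(row[c])
            records.append(
                FootprintRecord(
                    group=row["group"],
                    mhc_res=row["mhc_residue"],
                    mhc_atom=row["mhc_atom"],
                    tcr_loop=row["tcr_loop"],
                    tcr_res=row["tcr_residue"],
                    tcr_atom=row["tcr_atom"],
                    in_crystal=row["in_crystal"].strip().lower() == "yes",
                    persistence=pers,
                )
            )
        return cls(records=records, provenance={"source": str(source)})


# ---------------------------------------------------------------------------
# Building from hydrogen-bond series
# ---------------------------------------------------------------------------

def default_mhc_group(chain_role: str, res_seq: int) -> str:
    if chain_role == "peptide":
        return "peptide"
    if ALPHA1_HELIX_RANGE[0] <= res_seq <= ALPHA1_HELIX_RANGE[1]:
        return "alpha1"
    if ALPHA2_HELIX_RANGE[0] <= res_seq <= ALPHA2_HELIX_RANGE[1]:
        return "alpha2"
    return "other"


def build_footprint(
    crystal_bonds: set[tuple],
    complex_series: Mapping[str, Sequence[HBondSeries]],
    mhc_side_of=None,
    tcr_loop_of=None,
    provenance: Optional[dict] = None,
) -> FootprintTable:
    """Union crystal and simulated bonds into a classified footprint table.

    Parameters
    ----------
    crystal_bonds:
        Set of record keys ``(mhc_res, mhc_atom, tcr_loop, tcr_res, tcr_atom)``
        present in the crystal reference (curated or computed in
        distance-only mode).
    complex_series:
        Map complex-label → hydrogen-bond series from that simulation.
    mhc_side_of:
        ``callable(series) -> bool`` deciding which end of a series is the
        pMHC side; default: the donor is pMHC-side iff its chain sorts
        first (suitable only for synthetic data — pass an explicit role
        map for real systems).
    tcr_loop_of:
        ``callable(AtomRef) -> str`` naming the CDR loop of a TCR-side
        residue; default "".
    """
    if mhc_side_of is None:
        mhc_side_of = lambda s: s.donor.chain_id <= s.acceptor.chain_id  # noqa: E731
    if tcr_loop_of is None:
        tcr_loop_of = lambda ref: ""  # noqa: E731

    acc: dict[tuple, dict] = {}

    def _ensure(key: tuple, group: str, in_crystal: bool) -> dict:
        if key not in acc:
            acc[key] = {
                "group": group,
                "in_crystal": in_crystal,
                "persistence": {label: None for label in complex_series},
            }
        return acc[key]

    for key in crystal_bonds:
        mhc_res = key[0]
        digits = "".join(c for c in mhc_res if c.isdigit())
        group = default_mhc_group("mhc", int(digits) if digits else 0)
        _ensure(key, group, True)

    for label, series_list in complex_series.items():
        for s in series_list:
            if mhc_side_of(s):
                mhc_ref, tcr_ref = s.donor, s.acceptor
            else:
                mhc_ref, tcr_ref = s.acceptor, s.donor
            key = (
                f"{mhc_ref.res_name.capitalize()}{mhc_ref.res_seq}",
                greek_atom_label(mhc_ref.atom_name),
                tcr_loop_of(tcr_ref),
                f"{tcr_ref.res_name.capitalize()}{tcr_ref.res_seq}",
                greek_atom_label(tcr_ref.atom_name),
            )
            group = default_mhc_group(
                "peptide" if mhc_ref.chain_id.upper() in ("C", "P") else "mhc",
                mhc_ref.res_seq,
            )
            entry = _ensure(key, group, key in crystal_bonds)
            entry["persistence"][label] = persistence(s)

    records = [
        FootprintRecord(
            group=v["group"],
            mhc_res=k[0],
            mhc_atom=k[1],
            tcr_loop=k[2],
            tcr_res=k[3],
            tcr_atom=k[4],
            in_crystal=v["in_crystal"],
            persistence=v["persistence"],
        )
        for k, v in acc.items()
    ]
    records.sort(key=lambda r: (_GROUP_ORDER.get(r.group, 9), r.mhc_res_seq, r.key))
    return FootprintTable(records=records, provenance=provenance or {})


# ---------------------------------------------------------------------------
# Cross-complex comparison
# ---------------------------------------------------------------------------

@dataclass
class ConservationReport:
    """Residue-level footprint agreement between two complexes."""

    conserved: list[str]
    a_only: list[str]
    b_only: list[str]
    classes: dict[str, dict[str, Optional[str]]]  # residue → complex → class

    def summary(self) -> str:
        lines = [
            f"conserved residues ({len(self.conserved)}): {', '.join(self.conserved) or '-'}",
            f"A-only residues ({len(self.a_only)}): {', '.join(self.a_only) or '-'}",
            f"B-only residues ({len(self.b_only)}): {', '.join(self.b_only) or '-'}",
        ]
        return "\n".join(lines)


def _contacted_residues(table: FootprintTable, label: Optional[str] = None) -> dict[str, str]:
    """MHC residues with ≥1 observed interaction, with their 'best' class."""
    out: dict[str, str] = {}
    for r in table.records:
        cols = r.persistence if label is None else {label: r.persistence.get(label)}
        if any(p is not None for p in cols.values()):
            prev = out.get(r.mhc_res)
            cls = classify(r.in_crystal, [p for p in cols.values()])
            # prefer crystal_and_md > novel_long > novel_short for reporting
            rank = {"crystal_and_md": 0, "novel_long_lived": 1, "novel_short_lived": 2}
            if prev is None or rank.get(cls, 3) < rank.get(prev, 3):
                out[r.mhc_res] = cls
    return out


def compare_footprints(a: FootprintTable, b: FootprintTable) -> ConservationReport:
    """Per-MHC-residue conservation between two complexes' footprints.

    ``a`` and ``b`` may be two single-complex tables, or the same
    two-column table passed twice (columns are then split by label order).
    """
    if a is b and len(a.complex_labels) >= 2:
        la, lb = a.complex_labels[:2]
        res_a = _contacted_residues(a, la)
        res_b = _contacted_residues(a, lb)
    else:
        res_a = _contacted_residues(a)
        res_b = _contacted_residues(b)

    def _order(residues: Iterable[str]) -> list[str]:
        def res_seq(r: str) -> int:
            digits = "".join(c for c in r if c.isdigit())
            return int(digits) if digits else 0

        return sorted(residues, key=res_seq)

    both = _order(set(res_a) & set(res_b))
    only_a = _order(set(res_a) - set(res_b))
    only_b = _order(set(res_b) - set(res_a))
    classes = {
        res: {"A": res_a.get(res), "B": res_b.get(res)}
        for res in _order(set(res_a) | set(res_b))
    }
    return ConservationReport(conserved=both, a_only=only_a, b_only=only_b, classes=classes)


# ---------------------------------------------------------------------------
# Packaged reference fixture
# ---------------------------------------------------------------------------

def reference_footprint_path() -> Path:
    """Path to the packaged reference footprint transcription."""
    return Path(resources.files("tcrdyn").joinpath("data/reference_footprint.csv"))


def load_reference_footprint() -> FootprintTable:
    """Load the packaged crystal + two-simulation reference footprint.

    Known internal inconsistencies of the source dataset (legend vs. table)
    are documented in ``data/reference_footprint_notes.md`` next to the
    fixture; they are deliberately NOT resolved in code.
    """
    table = FootprintTable.from_csv(reference_footprint_path())
    table.provenance["notes"] = "see data/reference_footprint_notes.md"
    return table
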