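"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately re-derive results with plain loops and no calls into the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np

from tcrdyn.model_io import AtomRecord, Selection, Topology, Trajectory, infer_h_attachment


def topology_from_specs(specs):
    """specs: list of (name, element, res_name, res_seq, chain)."""
    atoms = [
        AtomRecord(serial=i + 1, name=n, element=e, res_name=rn, res_seq=rs, chain_id=c)
        for i, (n, e, rn, rs, c) in enumerate(specs)
    ]
    return Topology(atoms=atoms)


def random_hbond_world(seed, n_heavy=40, n_frames=10):
    """Random two-chain box of N/O/C atoms; polar nitrogens get one H each."""
    rng = np.random.default_rng(seed)
    specs, coords = [], []
    res = 0
    for i in range(n_heavy):
        chain = "A" if i < n_heavy // 2 else "B"
        res += 1
        kind = rng.choice(["N", "O", "C"])
        pos = rng.uniform(0, 18, 3)
        specs.append((kind, kind, "GLY", res, chain))
        coords.append(pos)
        if kind == "N":
            specs.append(("H", "H", "GLY", res, chain))
            direction = rng.standard_normal(3)
            coords.append(pos + direction / np.linalg.norm(direction))
    top = topology_from_specs(specs)
    base = np.array(coords)
    frames = base[None] + rng.standard_normal((n_frames, len(coords), 3)) * 0.4
    traj = Trajectory(top, frames)
    top.h_attachment = infer_h_attachment(top, frames[0])
    return traj, Selection.make(chains=["A"]), Selection.make(chains=["B"])


def bruteforce_hbond_series(traj, sel_a, sel_b, d_max=3.5, theta_min=150.0):
    """Exhaustive all-pairs all-frames hydrogen-bond oracle."""
    top = traj.topology
    ia = set(map(int, sel_a.resolve(top)))
    ib = set(map(int, sel_b.resolve(top)))
    h_of = {}
    for h, heavy in top.h_attachment.items():
        h_of.setdefault(heavy, []).append(h)
    out = {}
    for f in range(traj.n_frames):
        X = traj.coords[f]
        for d_idx in range(top.n_atoms):
            a_d = top.atoms[d_idx]
            if a_d.element not in "NOS" or a_d.is_hydrogen or d_idx not in ia | ib:
                continue
            if a_d.res_name == "PRO" and a_d.name == "N":
                continue
            hydrogens = h_of.get(d_idx, [])
            if not hydrogens:
                continue
            for a_idx in range(top.n_atoms):
                a_a = top.atoms[a_idx]
                if a_a.name not in ("O", "OXT"):  # these worlds only have backbone-O acceptors
                    continue
                if (d_idx in ia) == (a_idx in ia):  # same group
                    continue
                if np.linalg.norm(X[d_idx] - X[a_idx]) > d_max:
                    continue
                for h in hydrogens:
                    v1, v2 = X[d_idx] - X[h], X[a_idx] - X[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= theta_min:
                        key = (d_idx, a_idx)
                        out.setdefault(key, np.zeros(traj.n_frames, dtype=bool))[f] = True
                        break
    return out
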